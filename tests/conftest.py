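import logging
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from cogslope.battery import PredictorEffect, TestSpec
from cogslope.simulate import GenerativeSpec, simulate_cohort, simulate_genotypes

warnings.filterwarnings("ignore", category=RuntimeWarning)
logging.getLogger("cogslope").setLevel(logging.ERROR)


def small_battery() -> list[TestSpec]:
    """Eight tests, two per domain, with varied raw scales."""
    return [
        TestSpec("puzzles", "visuospatial", 20.0, 5.0, -0.15),
        TestSpec("shapes", "visuospatial", 10.0, 2.0, -0.05),
        TestSpec("stories", "verbal_memory", 50.0, 12.0, -0.12),
        TestSpec("pairs", "verbal_memory", 25.0, 8.0, -0.10),
        TestSpec("vocab", "crystallized", 30.0, 7.0, 0.01),
        TestSpec("reading", "crystallized", 40.0, 6.0, -0.02),
        TestSpec("coding", "speed", 55.0, 12.0, -0.60),
        TestSpec("reaction", "speed", 60.0, 3.0, -0.05, reversed=True),
    ]


def small_spec(n: int = 400, seed: int = 0, **kwargs) -> GenerativeSpec:
    defaults = dict(
        n_individuals=n,
        test_battery=small_battery(),
        predictor_effects={
            "pgs_education": PredictorEffect(0.30, 0.0, 0.32),
            "pgs_noise": PredictorEffect(0.0, 0.0, 0.0),
            "apoe_e4": PredictorEffect(-0.15, -0.30, 0.0, binary=True),
        },
        retention_targets=(n, int(0.8 * n), int(0.65 * n), int(0.5 * n)),
        seed=seed,
    )
    defaults.update(kwargs)
    return GenerativeSpec(**defaults)


@pytest.fixture(scope="session")
def default_spec() -> GenerativeSpec:
    return GenerativeSpec(seed=42)


@pytest.fixture(scope="session")
def small_cohort() -> tuple[GenerativeSpec, pd.DataFrame]:
    spec = small_spec(n=500, seed=11)
    return spec, simulate_cohort(spec)


@pytest.fixture(scope="session")
def tiny_genotypes():
    return simulate_genotypes(300, 120, block_size=8, within_block_r=0.6, seed=5)
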