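"""Default cognitive battery and genetic-predictor effect tables.

The defaults describe a longitudinal ageing cohort measured on 13 cognitive
tests spanning four correlated domains (visuospatial ability, verbal memory,
crystallized ability, processing speed) at four triennial waves, together
with 14 trait polygenic scores and a binary APOE e4 carrier indicator.
Per-test baseline moments and mean raw slopes (score units per year) follow
the published descriptives of the cohort the generator emulates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

VISUOSPATIAL = "visuospatial"
VERBAL_MEMORY = "verbal_memory"
CRYSTALLIZED = "crystallized"
SPEED = "speed"

DOMAINS = (VISUOSPATIAL, VERBAL_MEMORY, CRYSTALLIZED, SPEED)


@dataclass(frozen=True)
class TestSpec:
    """One cognitive test: its domain, raw-scale moments and mean slope.

    ``slope_mean`` is on the analysis scale (higher = better performance),
    in raw score units per year.  ``reversed`` marks a timed test whose
    stored column is time-like (higher = worse); analyses sign-flip it first.
    """

    name: str
    domain: str
    baseline_mean: float
    baseline_sd: float
    slope_mean: float
    reversed: bool = False


@dataclass(frozen=True)
class PredictorEffect:
    """Standardized generative effects of one genetic predictor.

    beta_level:  marginal effect on the general cognitive level factor.
    beta_slope:  effect on the general cognitive slope factor.
    beta_age11:  marginal effect on the age-11 cognitive score.
    binary:      0/1 predictor; effects are standardized only with respect
                 to the outcome.
    """

    beta_level: float = 0.0
    beta_slope: float = 0.0
    beta_age11: float = 0.0
    binary: bool = False


def default_battery() -> list[TestSpec]:
    return [
        TestSpec("matrix_reasoning", VISUOSPATIAL, 13.49, 5.13, -0.133),
        TestSpec("block_design", VISUOSPATIAL, 33.79, 10.32, -0.423),
        TestSpec("spatial_span", VISUOSPATIAL, 7.36, 1.42, -0.038),
        TestSpec("logical_memory", VERBAL_MEMORY, 71.46, 17.96, -0.150),
        TestSpec("verbal_paired_associates", VERBAL_MEMORY, 26.44, 9.13, -0.156),
        TestSpec("digit_span_backwards", VERBAL_MEMORY, 7.73, 2.26, -0.038),
        TestSpec("nart", CRYSTALLIZED, 34.48, 8.15, 0.012),
        TestSpec("wtar", CRYSTALLIZED, 41.02, 7.17, -0.034),
        TestSpec("verbal_fluency", CRYSTALLIZED, 42.42, 12.54, -0.032),
        TestSpec("digit_symbol", SPEED, 56.60, 12.93, -0.833),
        TestSpec("symbol_search", SPEED, 24.71, 6.39, -0.258),
        TestSpec("inspection_time", SPEED, 112.14, 11.00, -0.595),
        TestSpec("choice_reaction_time", SPEED, 64.21, 0.09, -0.008, reversed=True),
    ]


def default_predictor_effects() -> dict[str, PredictorEffect]:
    """Fourteen trait PGSs plus APOE e4, with small standardized effects.

    Level effects span roughly |0.02|-|0.30|; only the APOE indicator
    carries a slope effect (-0.30, outcome-standardized).  The education
    PGS's level effect is realised through the mediation structure of the
    generative spec (direct + via years of education), marginally 0.300.
    """
    return {
        "pgs_education": PredictorEffect(0.300, 0.0, 0.321),
        "pgs_neuroticism": PredictorEffect(-0.077, 0.0, 0.0),
        "pgs_conscientiousness": PredictorEffect(-0.017, 0.0, 0.0),
        "pgs_alzheimers": PredictorEffect(-0.017, 0.0, 0.0),
        "pgs_schizophrenia": PredictorEffect(-0.148, 0.0, -0.136),
        "pgs_mdd": PredictorEffect(-0.037, 0.0, 0.0),
        "pgs_cad": PredictorEffect(-0.108, 0.0, -0.098),
        "pgs_stroke": PredictorEffect(-0.056, 0.0, -0.075),
        "pgs_t2d": PredictorEffect(-0.089, 0.0, -0.079),
        "pgs_smoking": PredictorEffect(-0.178, 0.0, -0.187),
        "pgs_height": PredictorEffect(0.093, 0.0, 0.063),
        "pgs_bmi": PredictorEffect(-0.135, 0.0, -0.164),
        "pgs_fev1": PredictorEffect(0.074, 0.0, 0.055),
        "pgs_grip": PredictorEffect(-0.041, 0.0, 0.0),
        "apoe_e4": PredictorEffect(-0.15, -0.30, 0.0, binary=True),
    }


@dataclass(frozen=True)
class ValidationPhenotype:
    """A phenotype generated as a (generalized) linear function of its own PGS.

    ``coef`` is the standardized generating coefficient for continuous and
    ordinal phenotypes (partial R^2 = coef^2) and the per-SD log-odds for
    binary ones.  Sex/age effects are nuisance structure removed by the
    validation models' covariates.
    """

    name: str
    kind: str  # "continuous" | "binary" | "ordinal"
    source: str
    coef: float
    mean: float = 0.0
    sd: float = 1.0
    prevalence: float = 0.0
    sex_effect: float = 0.0
    cut_probs: tuple[float, ...] = field(default_factory=tuple)


def default_validation_phenotypes() -> list[ValidationPhenotype]:
    return [
        ValidationPhenotype("neuroticism", "continuous", "pgs_neuroticism", 0.176, 17.8, 7.0),
        ValidationPhenotype("conscientiousness", "continuous", "pgs_conscientiousness", 0.083, 31.0, 6.0),
        ValidationPhenotype("mmse", "continuous", "pgs_alzheimers", -0.061, 28.8, 1.4),
        ValidationPhenotype("hads_depression", "continuous", "pgs_mdd", 0.002, 2.7, 2.2),
        ValidationPhenotype("height", "continuous", "pgs_height", 0.365, 172.0, 8.5, sex_effect=-12.0),
        ValidationPhenotype("bmi", "continuous", "pgs_bmi", 0.359, 27.8, 4.3),
        ValidationPhenotype("fev1", "continuous", "pgs_fev1", 0.191, 2.9, 0.7, sex_effect=-0.8),
        ValidationPhenotype("grip_strength", "continuous", "pgs_grip", 0.065, 35.0, 9.0, sex_effect=-14.0),
        ValidationPhenotype("cad_diag", "binary", "pgs_cad", 0.267, prevalence=0.245),
        ValidationPhenotype("stroke_diag", "binary", "pgs_stroke", 0.169, prevalence=0.050),
        ValidationPhenotype("diabetes_diag", "binary", "pgs_t2d", 0.608, prevalence=0.086),
        ValidationPhenotype(
            "smoking_status", "ordinal", "pgs_smoking", 0.147, cut_probs=(0.45, 0.43, 0.12)
        ),
    ]


#: Phenotype each PGS is validated against (Table-1-shaped preliminary check).
OWN_PHENOTYPE = {
    "pgs_education": ("years_education", "continuous"),
    "pgs_neuroticism": ("neuroticism", "continuous"),
    "pgs_conscientiousness": ("conscientiousness", "continuous"),
    "pgs_alzheimers": ("mmse", "continuous"),
    "pgs_schizophrenia": ("block_design_w1", "continuous"),
    "pgs_mdd": ("hads_depression", "continuous"),
    "pgs_cad": ("cad_diag", "binary"),
    "pgs_stroke": ("stroke_diag", "binary"),
    "pgs_t2d": ("diabetes_diag", "binary"),
    "pgs_smoking": ("smoking_status", "ordinal"),
    "pgs_height": ("height", "continuous"),
    "pgs_bmi": ("bmi", "continuous"),
    "pgs_fev1": ("fev1", "continuous"),
    "pgs_grip": ("grip_strength", "continuous"),
}

#: Default sex effects on test scores, in baseline-SD units (female minus male).
DEFAULT_SEX_EFFECTS = {
    "logical_memory": 0.15,
    "verbal_paired_associates": 0.20,
    "block_design": -0.12,
    "matrix_reasoning": -0.10,
    "digit_symbol": 0.25,
}
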