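"""End-to-end synthetic study: simulate, score, fit, associate, validate.

``run_pipeline`` executes the preregistered-style ordering — preliminary
own-phenotype validation, PGS correlation matrix and parallel analysis,
the factors-of-curves baseline model, per-predictor association models,
APOE-adjusted and simultaneous models, lifetime-change models, and the
education mediation model — writing table-shaped CSVs with provenance
headers.  Identical config + seed gives byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .association import (
    DEFAULT_COVARIATES,
    apoe_adjusted_association,
    attach_fdr,
    lifetime_change_association,
    mediation_education,
    simultaneous_association,
    single_predictor_association,
    williams_test,
)
from .battery import OWN_PHENOTYPE
from .errors import CogslopeError, ParameterError
from .pgs import build_pgs
from .sem.foc import FoCModelSpec, factor_scores, fit_foc, residualize_scores, variance_decomposition
from .sem.indices import fit_indices
from .sem.univariate import fit_univariate_lgc
from .simulate import (
    DEFAULT_RETENTION,
    GenerativeSpec,
    analysis_scale,
    simulate_cohort,
    simulate_genotypes,
    simulate_summary_stats,
    simulate_trait_architecture,
)
from .validation import parallel_analysis, pgs_correlation_matrix, validate_own_phenotype

log = logging.getLogger(__name__)

def stage_seed(root: int, stage: str) -> int:
    """Deterministic per-stage substream of the root seed (below 2**31)."""
    h = np.frombuffer(stage.encode(), dtype=np.uint8).astype(np.uint64)
    mix = int((np.uint64(root) * np.uint64(2654435761) + (h * np.arange(1, len(h) + 1)).sum()) % (2**31 - 1))
    return mix


@dataclass
class PipelineConfig:
    """One structured description of a full synthetic study run."""

    n_individuals: int = 1091
    m_snps: int = 2000
    block_size: int = 20
    within_block_r: float = 0.35
    maf_range: tuple[float, float] = (0.05, 0.5)
    gwas_n: int = 300_000
    h2: float = 0.25
    causal_fraction: float = 0.2
    p_threshold: float = 1.0
    clump_r2: float = 0.25
    window_kb: float = 250.0
    strict_threshold: float = 0.01  # secondary threshold (Alzheimer's score)
    out_dir: str = "cogslope_run"
    seed: int = 1
    genotypes_path: str | None = None
    cohort_path: str | None = None
    run_validation: bool = True
    run_parallel: bool = True
    run_apoe_adjusted: bool = True
    run_simultaneous: bool = True
    run_lifetime: bool = True
    run_mediation: bool = True
    write_vcf: bool = False
    association_n_starts: int = 2

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        if "maf_range" in raw:
            raw["maf_range"] = tuple(raw["maf_range"])
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)

    def validate(self) -> None:
        if self.n_individuals < 50:
            raise ParameterError("cohort too small for the growth model")
        for p in (self.genotypes_path, self.cohort_path):
            if p is not None and not Path(p).exists():
                raise ParameterError(f"referenced input does not exist: {p}")


def scaled_retention(n: int) -> tuple[int, ...]:
    """Retention targets proportional to the study's 1091/866/697/550."""
    base = np.asarray(DEFAULT_RETENTION, dtype=float)
    if n == base[0]:
        return DEFAULT_RETENTION
    scaled = np.maximum(np.round(base * n / base[0]).astype(int), 10)
    scaled[0] = n
    return tuple(int(v) for v in scaled)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns the in-memory artifacts it wrote."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    # hash the scientific configuration only: the output location must not
    # change any result byte
    chash = cio.config_hash({k: v for k, v in config.to_dict().items() if k != "out_dir"})
    prov = {"config_hash": chash, "seed": config.seed, "package": "cogslope"}
    run_log: list[dict] = []

    def record(stage: str, **info) -> None:
        run_log.append({"stage": stage, **info})

    gspec = GenerativeSpec(
        n_individuals=config.n_individuals,
        retention_targets=scaled_retention(config.n_individuals),
        seed=stage_seed(config.seed, "cohort"),
    )
    trait_names = [n for n, e in gspec.predictor_effects.items() if not e.binary]

    # ---- genotypes --------------------------------------------------------
    if config.genotypes_path:
        genotypes, person_ids = cio.read_dosage_tsv(config.genotypes_path)
    else:
        genotypes = simulate_genotypes(
            config.n_individuals,
            config.m_snps,
            block_size=config.block_size,
            within_block_r=config.within_block_r,
            maf_range=config.maf_range,
            seed=stage_seed(config.seed, "genotypes"),
        )
    record("genotypes", n=genotypes.n, m=genotypes.m)

    # ---- discovery traits and summary statistics --------------------------
    sumstats = {}
    truths = {}
    for k, trait in enumerate(trait_names):
        beta, truth = simulate_trait_architecture(
            genotypes,
            h2=config.h2,
            causal_fraction=config.causal_fraction,
            seed=stage_seed(config.seed, f"trait_{trait}"),
        )
        truths[trait] = truth
        sumstats[trait] = simulate_summary_stats(
            genotypes, beta, config.gwas_n, seed=stage_seed(config.seed, f"gwas_{trait}")
        )
        cio.write_sumstats(sumstats[trait], out_dir / "sumstats" / f"{trait}.tsv")
    record("traits", n_traits=len(trait_names), gwas_n=config.gwas_n)

    # ---- cohort ------------------------------------------------------------
    if config.cohort_path:
        cohort = cio.read_cohort(config.cohort_path)
    else:
        cohort = simulate_cohort(gspec, genotypes, pgs_truth=truths)
    cio.write_cohort(cohort, out_dir / "cohort.csv", prov)
    if config.write_vcf and not config.genotypes_path:
        cio.write_vcf(genotypes, out_dir / "genotypes.vcf", cohort["person_id"])
    cio.write_dosage_tsv(genotypes, out_dir / "genotypes_dosage.tsv", cohort["person_id"])
    wave_ns = [int(cohort[f"{gspec.tests[0]}_w{w + 1}"].notna().sum()) for w in range(4)]
    record("cohort", n=len(cohort), wave_ns=wave_ns)

    # ---- polygenic scores --------------------------------------------------
    score_cols = {}
    provenance_pgs = {}
    for trait in trait_names:
        vec = build_pgs(
            genotypes,
            sumstats[trait],
            p_threshold=config.p_threshold,
            r2_max=config.clump_r2,
            window_kb=config.window_kb,
            name=trait,
            person_ids=cohort["person_id"],
        )
        score_cols[trait] = vec.standardized().to_numpy()
        provenance_pgs[trait] = vec.provenance
    strict = build_pgs(
        genotypes,
        sumstats["pgs_alzheimers"],
        p_threshold=config.strict_threshold,
        r2_max=config.clump_r2,
        window_kb=config.window_kb,
        name="pgs_alzheimers_strict",
        person_ids=cohort["person_id"],
    )
    score_cols["pgs_alzheimers_strict"] = strict.standardized().to_numpy()
    provenance_pgs["pgs_alzheimers_strict"] = strict.provenance
    scores = pd.DataFrame(score_cols)
    scores.insert(0, "person_id", cohort["person_id"].to_numpy())
    cio.write_table(scores, out_dir / "pgs_scores.csv", prov)
    with open(out_dir / "pgs_provenance.json", "w") as fh:
        json.dump(provenance_pgs, fh, indent=2, sort_keys=True)
    record("pgs", n_scores=len(score_cols))

    # analysis frame: measured scores replace the generator's true scores
    analysis = cohort.drop(columns=[c for c in trait_names if c in cohort.columns])
    for trait in trait_names:
        analysis[trait] = score_cols[trait]
    analysis["age_years"] = analysis["age_days_w1"] / 365.25

    results: dict = {
        "config": config,
        "genotypes": genotypes,
        "cohort": cohort,
        "scores": scores,
        "gspec": gspec,
    }

    # ---- preliminary validation -------------------------------------------
    if config.run_validation:
        rows = []
        for trait, (pheno, kind) in OWN_PHENOTYPE.items():
            if pheno not in analysis.columns:
                continue
            covs = analysis[[c for c in ("age_years", "sex", "mds1", "mds2", "mds3", "mds4")]]
            res = validate_own_phenotype(
                analysis[trait],
                analysis[pheno],
                kind,
                covariates=covs,
                score_name=trait,
                outcome_name=pheno,
            )
            rows.append(
                {
                    "score": trait,
                    "outcome": pheno,
                    "type": kind,
                    "beta": res.beta,
                    "se": res.se,
                    "p": res.p,
                    "variance_explained_pct": 100 * res.variance_explained,
                    "n": res.n,
                }
            )
        table1 = pd.DataFrame(rows)
        cio.write_table(table1, out_dir / "table1_validation.csv", prov)
        results["table1"] = table1
        record("validation", n_rows=len(table1))

    # ---- correlation matrix and parallel analysis ---------------------------
    if config.run_parallel:
        corr, corr_p = pgs_correlation_matrix(scores[trait_names])
        cio.write_table(corr.round(6), out_dir / "pgs_correlations.csv", prov, index=True)
        pa = parallel_analysis(
            scores[trait_names], n_simulations=100, seed=stage_seed(config.seed, "parallel")
        )
        results["parallel"] = pa
        results["pgs_corr"] = corr
        record("parallel", n_retained=pa.n_retained)

    # ---- per-test growth curves (raw scale) ---------------------------------
    raw = analysis_scale(cohort, gspec.test_battery)
    tb = gspec.time_basis
    rows = []
    for t in gspec.test_battery:
        block = raw[[f"{t.name}_w{w + 1}" for w in range(len(tb))]].to_numpy()
        g = fit_univariate_lgc(block, tb, seed=stage_seed(config.seed, f"lgc_{t.name}"))
        rows.append(
            {
                "test": t.name,
                "domain": t.domain,
                "baseline_mean": float(np.nanmean(block[:, 0])),
                "baseline_sd": float(np.nanstd(block[:, 0])),
                "raw_change_per_year": g.mean_slope,
                "se": g.slope_se,
                "sd_change_per_year": g.sd_scaled_slope,
                "converged": g.converged,
            }
        )
    table2 = pd.DataFrame(rows)
    cio.write_table(table2, out_dir / "table2_growth.csv", prov)
    results["table2"] = table2

    # ---- baseline factors-of-curves model -----------------------------------
    resid = residualize_scores(analysis, gspec.test_battery)
    frame = pd.concat([resid, analysis.drop(columns=resid.columns)], axis=1)
    foc_spec = FoCModelSpec.from_generative(gspec)
    baseline = fit_foc(frame, foc_spec, seed=stage_seed(config.seed, "foc"))
    indices = fit_indices(baseline.fit)
    decomp = variance_decomposition(baseline)
    cio.write_table(decomp, out_dir / "variance_decomposition.csv", prov)
    layer_means = decomp.groupby("outcome")[["general_share", "domain_share", "unique_share"]].mean()
    model_json = {
        "estimates": {k: float(v) for k, v in baseline.fit.estimates.items()},
        "se": {k: float(v) for k, v in baseline.fit.se.items()},
        "loglik": baseline.fit.loglik,
        "converged": baseline.fit.converged,
        "n": baseline.fit.n_obs,
        "indices": {
            "chisq": indices.chisq,
            "df": indices.df,
            "p": indices.p,
            "rmsea": indices.rmsea,
            "cfi": indices.cfi,
            "tli": indices.tli,
            "srmr": indices.srmr,
        },
        "variance_share_means": {
            out: {k: float(v) for k, v in row.items()} for out, row in layer_means.iterrows()
        },
        "provenance": prov,
    }
    with open(out_dir / "foc_model.json", "w") as fh:
        json.dump(model_json, fh, indent=2, sort_keys=True)
    results["baseline"] = baseline
    results["indices"] = indices
    results["decomposition"] = decomp
    record("growth", loglik=baseline.fit.loglik, rmsea=indices.rmsea, cfi=indices.cfi)

    predictors = trait_names + ["apoe_e4"]

    # ---- single-predictor associations (level and slope) --------------------
    assoc = []
    for pred in predictors:
        assoc.extend(
            single_predictor_association(
                frame,
                foc_spec,
                pred,
                seed=stage_seed(config.seed, f"assoc_{pred}"),
                baseline=baseline,
            )
        )
    attach_fdr(assoc)
    table3 = pd.DataFrame([r.as_dict() for r in assoc])
    cio.write_table(table3, out_dir / "table3_associations.csv", prov)
    results["table3"] = table3
    record("association", n_rows=len(table3))

    # ---- APOE-adjusted models (level-significant scores) ---------------------
    if config.run_apoe_adjusted:
        sig = table3[
            (table3["outcome"] == "level")
            & (table3["q"] <= 0.05)
            & (table3["predictor"] != "apoe_e4")
        ]["predictor"].tolist()
        rows = []
        for pred in sig:
            rows.extend(
                r.as_dict()
                for r in apoe_adjusted_association(
                    frame,
                    foc_spec,
                    pred,
                    seed=stage_seed(config.seed, f"apoeadj_{pred}"),
                    baseline=baseline,
                )
            )
        apoe_table = pd.DataFrame(rows)
        cio.write_table(apoe_table, out_dir / "apoe_adjusted.csv", prov)
        results["apoe_adjusted"] = apoe_table

    # ---- simultaneous model --------------------------------------------------
    if config.run_simultaneous:
        sim = simultaneous_association(
            frame,
            foc_spec,
            trait_names,
            seed=stage_seed(config.seed, "simultaneous"),
            baseline=baseline,
        )
        sim_table = pd.DataFrame([r.as_dict() for r in sim])
        cio.write_table(sim_table, out_dir / "simultaneous.csv", prov)
        results["simultaneous"] = sim_table

    # ---- lifetime change -----------------------------------------------------
    if config.run_lifetime:
        rows = []
        for pred in predictors:
            rows.extend(
                r
                for r in lifetime_change_association(
                    frame,
                    foc_spec,
                    pred,
                    seed=stage_seed(config.seed, f"lifetime_{pred}"),
                    baseline=baseline,
                )
            )
        attach_fdr(rows)
        table4 = pd.DataFrame([r.as_dict() for r in rows])
        cio.write_table(table4, out_dir / "table4_lifetime.csv", prov)
        results["table4"] = table4
        record("lifetime", n_rows=len(table4))

    # ---- education mediation -------------------------------------------------
    if config.run_mediation:
        med = mediation_education(
            frame, foc_spec, seed=stage_seed(config.seed, "mediation")
        )
        med_dict = {
            k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
            for k, v in asdict(med).items()
        }
        med_dict["provenance"] = prov
        with open(out_dir / "mediation.json", "w") as fh:
            json.dump(med_dict, fh, indent=2, sort_keys=True)
        results["mediation"] = med
        record("mediation", proportion=med.proportion_mediated, stable=med.stable)

    # ---- phenotype vs genotype prediction comparison (Williams's test) -------
    fscores = factor_scores(baseline, frame)
    wrows = []
    for trait, (pheno, kind) in OWN_PHENOTYPE.items():
        if kind == "binary" or pheno not in analysis.columns:
            continue
        sub = pd.DataFrame(
            {
                "slope": fscores["g_slope_score"],
                "pheno": analysis[pheno],
                "pgs": analysis[trait],
            }
        ).dropna()
        if len(sub) < 10:
            continue
        r12 = sub["slope"].corr(sub["pheno"])
        r13 = sub["slope"].corr(sub["pgs"])
        r23 = sub["pheno"].corr(sub["pgs"])
        try:
            t, df, p = williams_test(r12, r13, r23, len(sub))
        except CogslopeError:
            continue
        wrows.append(
            {
                "trait": trait,
                "phenotype": pheno,
                "r_slope_phenotype": r12,
                "r_slope_pgs": r13,
                "r_phenotype_pgs": r23,
                "t": t,
                "df": df,
                "p": p,
            }
        )
    williams = pd.DataFrame(wrows)
    cio.write_table(williams, out_dir / "williams_comparison.csv", prov)
    results["williams"] = williams

    with open(out_dir / "run_log.json", "w") as fh:
        json.dump({"provenance": prov, "stages": run_log}, fh, indent=2, sort_keys=True)
    results["run_log"] = run_log
    return results
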