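"""Own-phenotype validation of polygenic scores and the PGS factor structure.

Each PGS is checked against the phenotype it was built for: linear models
for continuous outcomes (variance explained as an R-squared increment over
the covariates), logistic models for binary outcomes (Nagelkerke
difference analogue), and a documented 0/1/2 linear coding for the ordinal
smoking status.  The battery-level structure is summarized by a pairwise
correlation matrix and Horn-style parallel analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import ParameterError, StructuralError

DEFAULT_COVARIATES = ("age_years", "sex", "mds1", "mds2", "mds3", "mds4")


@dataclass
class ValidationResult:
    score: str
    outcome: str
    outcome_type: str  # "continuous" | "binary" | "ordinal"
    beta: float  # standardized (continuous/ordinal) or per-SD log-odds (binary)
    se: float
    p: float
    variance_explained: float  # partial R^2 or Nagelkerke difference
    n: int


def _design(frame: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    return sm.add_constant(frame[cols], has_constant="add")


def nagelkerke_r2(ll_null: float, ll_full: float, n: int) -> float:
    """Nagelkerke's R^2 from two log-likelihoods."""
    cox_snell = 1.0 - np.exp(2.0 * (ll_null - ll_full) / n)
    max_r2 = 1.0 - np.exp(2.0 * ll_null / n)
    return float(cox_snell / max_r2) if max_r2 > 0 else 0.0


def validate_own_phenotype(
    score: pd.Series,
    phenotype: pd.Series,
    outcome_type: str,
    covariates: pd.DataFrame | None = None,
    score_name: str = "pgs",
    outcome_name: str = "phenotype",
) -> ValidationResult:
    """Association of one PGS with its own phenotype, beyond covariates.

    Continuous (and ordinal, coded 0/1/2) outcomes: OLS with both score and
    outcome standardized; variance explained is the full-model R^2 minus
    the covariate-only R^2.  Binary outcomes: logistic regression with the
    score standardized; variance explained is the difference of Nagelkerke
    R^2 between the full and covariate-only models.
    """
    if outcome_type not in {"continuous", "binary", "ordinal"}:
        raise ParameterError(f"unknown outcome type {outcome_type!r}")
    frame = pd.DataFrame({"score": score, "y": phenotype})
    cov_cols: list[str] = []
    if covariates is not None:
        for c in covariates.columns:
            frame[c] = covariates[c].to_numpy()
            cov_cols.append(c)
    frame = frame.dropna()
    n = len(frame)
    if n < len(cov_cols) + 3:
        raise ParameterError("too few complete cases")
    frame["score"] = (frame["score"] - frame["score"].mean()) / frame["score"].std()

    if outcome_type == "binary":
        uniq = set(np.unique(frame["y"]))
        if not uniq <= {0, 1, 0.0, 1.0}:
            raise ParameterError(f"binary phenotype has levels {sorted(uniq)}")
        full = sm.Logit(frame["y"], _design(frame, ["score"] + cov_cols)).fit(disp=0)
        if cov_cols:
            null = sm.Logit(frame["y"], _design(frame, cov_cols)).fit(disp=0)
        else:
            null = sm.Logit(frame["y"], np.ones((n, 1))).fit(disp=0)
        r2 = nagelkerke_r2(null.llf, full.llf, n) - 0.0
        r2_cov = 0.0
        if cov_cols:
            base = sm.Logit(frame["y"], np.ones((n, 1))).fit(disp=0)
            r2 = nagelkerke_r2(base.llf, full.llf, n)
            r2_cov = nagelkerke_r2(base.llf, null.llf, n)
        ve = max(r2 - r2_cov, 0.0)
        return ValidationResult(
            score=score_name,
            outcome=outcome_name,
            outcome_type="binary",
            beta=float(full.params["score"]),
            se=float(full.bse["score"]),
            p=float(full.pvalues["score"]),
            variance_explained=min(ve, 1.0),
            n=n,
        )

    y = frame["y"].astype(float)
    sd = y.std()
    if sd == 0:
        raise ParameterError("phenotype is constant")
    y = (y - y.mean()) / sd
    full = sm.OLS(y, _design(frame, ["score"] + cov_cols)).fit()
    if cov_cols:
        null = sm.OLS(y, _design(frame, cov_cols)).fit()
        r2_cov = null.rsquared
    else:
        r2_cov = 0.0
    ve = float(np.clip(full.rsquared - r2_cov, 0.0, 1.0))
    return ValidationResult(
        score=score_name,
        outcome=outcome_name,
        outcome_type=outcome_type,
        beta=float(full.params["score"]),
        se=float(full.bse["score"]),
        p=float(full.pvalues["score"]),
        variance_explained=ve,
        n=n,
    )


def pgs_correlation_matrix(score_table: pd.DataFrame):
    """Pairwise-complete Pearson correlations among PGSs, with p-values.

    p-values come from the t transform with the per-pair complete-case n;
    a constant column yields NaN correlations (flagged by the caller).
    """
    cols = list(score_table.columns)
    if len(cols) < 2:
        raise ParameterError("need at least two scores")
    k = len(cols)
    corr = np.full((k, k), np.nan)
    pmat = np.full((k, k), np.nan)
    for i in range(k):
        corr[i, i] = 1.0
        pmat[i, i] = 0.0
        for j in range(i):
            pair = score_table[[cols[i], cols[j]]].dropna()
            n = len(pair)
            if n < 3 or pair[cols[i]].std() == 0 or pair[cols[j]].std() == 0:
                continue
            r = float(pair[cols[i]].corr(pair[cols[j]]))
            corr[i, j] = corr[j, i] = r
            if abs(r) >= 1:
                p = 0.0
            else:
                t = abs(r) * np.sqrt((n - 2) / (1 - r**2))
                p = float(2 * stats.t.sf(t, n - 2))
            pmat[i, j] = pmat[j, i] = p
    return (
        pd.DataFrame(corr, index=cols, columns=cols),
        pd.DataFrame(pmat, index=cols, columns=cols),
    )


@dataclass
class ParallelAnalysisResult:
    observed_eigenvalues: np.ndarray
    reference_eigenvalues: np.ndarray
    n_retained: int
    n_simulations: int
    criterion: str
    seed: int


def parallel_analysis(
    score_table: pd.DataFrame,
    n_simulations: int = 100,
    criterion: str = "mean",
    quantile: float = 0.95,
    seed: int = 0,
) -> ParallelAnalysisResult:
    """Horn-style parallel analysis of the score battery.

    Correlation-matrix (principal-component) eigenvalues of the observed
    battery are compared rank-wise with eigenvalues of simulated
    uncorrelated standard-normal data of the same shape; the retained
    count is the number of leading ranks whose observed eigenvalue exceeds
    the reference (the mean of the simulated eigenvalues at that rank, or
    the chosen quantile), stopping at the first failure.
    """
    if n_simulations < 1:
        raise ParameterError("n_simulations must be at least 1")
    if criterion not in {"mean", "quantile"}:
        raise ParameterError("criterion must be 'mean' or 'quantile'")
    clean = score_table.dropna()
    n, k = clean.shape
    if n < k + 2:
        raise ParameterError("too few complete rows for parallel analysis")
    obs = np.sort(np.linalg.eigvalsh(np.corrcoef(clean.to_numpy(), rowvar=False)))[::-1]
    rng = np.random.default_rng(seed)
    sims = np.empty((n_simulations, k))
    for s in range(n_simulations):
        z = rng.standard_normal((n, k))
        sims[s] = np.sort(np.linalg.eigvalsh(np.corrcoef(z, rowvar=False)))[::-1]
    ref = sims.mean(axis=0) if criterion == "mean" else np.quantile(sims, quantile, axis=0)
    exceeds = obs > ref
    retained = int(np.argmin(exceeds)) if not exceeds.all() else len(obs)
    return ParallelAnalysisResult(
        observed_eigenvalues=obs,
        reference_eigenvalues=ref,
        n_retained=retained,
        n_simulations=n_simulations,
        criterion=criterion,
        seed=seed,
    )
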