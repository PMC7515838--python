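"""Hierarchical "factors of curves" latent growth model.

Each cognitive test gets a latent growth curve (intercept + slope with
loadings fixed to the study's time basis); the per-test intercepts load on
four domain level factors and the slopes on four domain slope factors,
which in turn load on a general level and a general slope factor.  The
general factors are scaled by fixing their (residual) variance to 1, so
all hierarchical loadings are free and directly interpretable.

Genetic predictors and covariates enter as exogenous regressors on the
general factors (conditional maximum likelihood), matching a
complete-case policy for non-cognitive variables while FIML covers the
cognitive indicators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..battery import TestSpec
from ..errors import ConvergenceError, IdentificationError, StructuralError
from ..simulate import GenerativeSpec, analysis_scale
from .fiml import FittedSEM, PatternData, fit_sem
from .model import ModelBuilder, SEMModel


@dataclass
class FoCModelSpec:
    """Structure of the factors-of-curves model.

    ``domains`` maps each test to its domain; slope-factor loadings on the
    observations are fixed to ``time_basis`` and intercept loadings to 1.
    ``level_predictors`` / ``slope_predictors`` are exogenous columns
    regressed onto the general level / slope factor (the general factors'
    residual variances are then fixed to 1 for identification).
    """

    tests: list[str]
    domains: dict[str, str]
    time_basis: tuple[float, ...] = (0.0, 2.98, 6.71, 9.78)
    level_slope_cov: bool = True
    test_is_cov: bool = True
    level_predictors: list[str] = field(default_factory=list)
    slope_predictors: list[str] = field(default_factory=list)
    #: observed endogenous mediator regressed on the exogenous set, with a
    #: path into the general level factor (used by the mediation analysis)
    mediator: str | None = None
    mediator_predictors: list[str] = field(default_factory=list)

    @classmethod
    def from_generative(cls, gspec: GenerativeSpec, **kwargs) -> "FoCModelSpec":
        return cls(
            tests=gspec.tests,
            domains={t.name: t.domain for t in gspec.test_battery},
            time_basis=tuple(gspec.time_basis),
            **kwargs,
        )

    @property
    def domain_names(self) -> list[str]:
        seen: list[str] = []
        for t in self.tests:
            d = self.domains[t]
            if d not in seen:
                seen.append(d)
        return seen

    @property
    def exogenous(self) -> list[str]:
        out = list(self.level_predictors)
        for x in self.slope_predictors + self.mediator_predictors:
            if x not in out:
                out.append(x)
        return out

    @property
    def observed_columns(self) -> list[str]:
        return [
            f"{t}_w{w + 1}" for t in self.tests for w in range(len(self.time_basis))
        ]

    def validate(self) -> None:
        if len(self.time_basis) < 3:
            raise IdentificationError("a growth curve needs at least 3 waves")
        counts: dict[str, int] = {}
        for t in self.tests:
            if t not in self.domains:
                raise IdentificationError(f"test {t!r} has no domain")
            counts[self.domains[t]] = counts.get(self.domains[t], 0) + 1
        for d, c in counts.items():
            if c < 2:
                raise IdentificationError(f"domain {d!r} has fewer than 2 tests")


def build_foc_model(spec: FoCModelSpec) -> SEMModel:
    """Materialize the spec as RAM matrices with free/fixed masks."""
    spec.validate()
    b = ModelBuilder()
    tb = spec.time_basis
    has_exo = bool(spec.exogenous)

    b.add_variable("gL", latent=True)
    b.add_variable("gS", latent=True)
    for d in spec.domain_names:
        b.add_variable(f"DL_{d}", latent=True)
        b.add_variable(f"DS_{d}", latent=True)
    for t in spec.tests:
        b.add_variable(f"I_{t}", latent=True)
        b.add_variable(f"S_{t}", latent=True)
    for t in spec.tests:
        for w in range(len(tb)):
            b.add_variable(f"{t}_w{w + 1}")
    if spec.mediator:
        b.add_variable(spec.mediator)
    for x in spec.exogenous:
        b.add_exogenous(x)

    # general factors: (residual) variance fixed to 1, covariance free
    b.fix_cov("gL", "gL", 1.0)
    b.fix_cov("gS", "gS", 1.0)
    if spec.level_slope_cov:
        b.free_cov("gL", "gS", "c_gLS", start=0.2)
    else:
        b.fix_cov("gL", "gS", 0.0)

    for d in spec.domain_names:
        b.free_path("gL", f"DL_{d}", f"lDL_{d}", start=0.8)
        b.free_path("gS", f"DS_{d}", f"lDS_{d}", start=0.9)
        b.free_var(f"DL_{d}", f"vDL_{d}", start=0.36)
        b.free_var(f"DS_{d}", f"vDS_{d}", start=0.19)

    for t in spec.tests:
        d = spec.domains[t]
        b.free_path(f"DL_{d}", f"I_{t}", f"lI_{t}", start=0.7)
        b.free_path(f"DS_{d}", f"S_{t}", f"lS_{t}", start=0.7)
        b.free_var(f"I_{t}", f"vI_{t}", start=0.5)
        b.free_var(f"S_{t}", f"vS_{t}", start=0.4)
        if spec.test_is_cov:
            b.free_cov(f"I_{t}", f"S_{t}", f"cIS_{t}", start=0.0)
        b.free_mean(f"I_{t}", f"mI_{t}", start=0.0)
        b.free_mean(f"S_{t}", f"mS_{t}", start=0.0)
        for w, tw in enumerate(tb):
            yname = f"{t}_w{w + 1}"
            b.fix_path(f"I_{t}", yname, 1.0)
            b.fix_path(f"S_{t}", yname, tw)
            b.free_var(yname, f"occ_{t}", start=0.3)

    for x in spec.level_predictors:
        b.free_exo_path(x, "gL", f"b_{x}_gL", start=0.0)
    for x in spec.slope_predictors:
        b.free_exo_path(x, "gS", f"b_{x}_gS", start=0.0)

    if spec.mediator:
        b.free_mean(spec.mediator, f"m_{spec.mediator}", start=0.0)
        b.free_var(spec.mediator, f"v_{spec.mediator}", start=1.0)
        b.free_path(spec.mediator, "gL", f"b_{spec.mediator}_gL", start=0.0)
        for x in spec.mediator_predictors:
            b.free_exo_path(x, spec.mediator, f"a_{x}_{spec.mediator}", start=0.0)

    model = b.build()
    model.labels = {
        "tests": spec.tests,
        "domains": spec.domains,
        "domain_names": spec.domain_names,
        "time_basis": tuple(tb),
        "has_exo": has_exo,
    }
    return model


def count_free_parameters(spec: FoCModelSpec) -> int:
    """Free-parameter count implied by the spec (used as an invariant check)."""
    nt = len(spec.tests)
    nd = len(spec.domain_names)
    n = 1  # general level-slope covariance
    n += 2 * nd  # domain loadings on the general factors
    n += 2 * nd  # domain residual variances
    n += 2 * nt  # test loadings on domain factors
    n += 2 * nt  # test-factor residual variances
    if spec.test_is_cov:
        n += nt
    n += 2 * nt  # intercept and slope means
    n += nt  # occasion residual variances (constant over waves)
    if not spec.level_slope_cov:
        n -= 1
    n += len(spec.level_predictors) + len(spec.slope_predictors)
    if spec.mediator:
        n += 3 + len(spec.mediator_predictors)  # mean, variance, b path, a paths
    return n


# ---------------------------------------------------------------------------
# Pre-residualization
# ---------------------------------------------------------------------------


def residualize_scores(cohort: pd.DataFrame, battery: list[TestSpec]) -> pd.DataFrame:
    """Sign-correct timed tests, then regress out age-in-days and sex.

    Reversed (time-like) tests are flipped to a higher-is-better scale
    first.  Then, per test and wave, observed scores are replaced by OLS
    residuals on age in days at that wave and sex, using available cases;
    missing entries stay missing.
    """
    frame = analysis_scale(cohort, battery)
    nw = sum(1 for c in cohort.columns if c.startswith("age_days_w"))
    out = {}
    for t in battery:
        for w in range(1, nw + 1):
            col = f"{t.name}_w{w}"
            if col not in frame.columns:
                continue
            y = frame[col].to_numpy(dtype=float)
            ok = ~np.isnan(y)
            if not ok.any():
                raise StructuralError(f"column {col} is entirely missing")
            age = frame[f"age_days_w{w}"].to_numpy(dtype=float)
            sex = frame["sex"].to_numpy(dtype=float)
            X = np.column_stack([np.ones(ok.sum()), age[ok], sex[ok]])
            coef, *_ = np.linalg.lstsq(X, y[ok], rcond=None)
            resid = np.full_like(y, np.nan)
            resid[ok] = y[ok] - X @ coef
            out[col] = resid
    return pd.DataFrame(out, index=cohort.index)


# ---------------------------------------------------------------------------
# Starting values from the data
# ---------------------------------------------------------------------------


def _univariate_moment_fit(y: np.ndarray, tb: np.ndarray):
    """Moment-based (intercept, slope) estimates for one test's wave block.

    Pairwise-complete covariances regressed on the growth structure
    Cov(y_w, y_w') = psi_II + (t_w + t_w') psi_IS + t_w t_w' psi_SS + [w=w'] theta.
    """
    nw = len(tb)
    means = np.nanmean(y, axis=0)
    X = np.column_stack([np.ones(nw), tb])
    mi, ms = np.linalg.lstsq(X, means, rcond=None)[0]
    rows, rhs = [], []
    for a in range(nw):
        for b_ in range(a, nw):
            ok = ~np.isnan(y[:, a]) & ~np.isnan(y[:, b_])
            if ok.sum() < 3:
                continue
            ya = y[ok, a] - y[ok, a].mean()
            yb = y[ok, b_] - y[ok, b_].mean()
            rows.append([1.0, tb[a] + tb[b_], tb[a] * tb[b_], 1.0 if a == b_ else 0.0])
            rhs.append((ya * yb).mean())
    sol, *_ = np.linalg.lstsq(np.asarray(rows), np.asarray(rhs), rcond=None)
    psi_ii, psi_is, psi_ss, theta = sol
    base_var = max(psi_ii + theta, 1e-8)
    psi_ii = max(psi_ii, 0.05 * base_var)
    psi_ss = max(psi_ss, 1e-4 * base_var)
    theta = max(theta, 0.05 * base_var)
    return mi, ms, psi_ii, psi_is, psi_ss, theta


def foc_start_values(model: SEMModel, spec: FoCModelSpec, y: np.ndarray) -> np.ndarray:
    """Data-driven starting vector: per-test growth moments split over layers."""
    tb = np.asarray(spec.time_basis)
    nw = len(tb)
    theta = model.start.copy()

    def set_(name: str, value: float, log: bool = False) -> None:
        j = model.param_index(name)
        theta[j] = np.log(max(value, 1e-8)) if log else value

    for t_i, t in enumerate(spec.tests):
        block = y[:, t_i * nw : (t_i + 1) * nw]
        mi, ms, psi_ii, psi_is, psi_ss, occ = _univariate_moment_fit(block, tb)
        set_(f"mI_{t}", mi)
        set_(f"mS_{t}", ms)
        set_(f"occ_{t}", occ, log=True)
        # split intercept variance: half via the hierarchy, half unique
        set_(f"lI_{t}", np.sqrt(0.5 * psi_ii))
        set_(f"vI_{t}", 0.5 * psi_ii, log=True)
        set_(f"lS_{t}", np.sqrt(0.6 * psi_ss))
        set_(f"vS_{t}", 0.4 * psi_ss, log=True)
        if spec.test_is_cov:
            set_(f"cIS_{t}", 0.5 * psi_is)
    for d in spec.domain_names:
        set_(f"lDL_{d}", 0.8)
        set_(f"vDL_{d}", 0.36, log=True)
        set_(f"lDS_{d}", 0.9)
        set_(f"vDS_{d}", 0.19, log=True)
    if spec.level_slope_cov:
        set_("c_gLS", 0.2)
    return theta


# ---------------------------------------------------------------------------
# Fitting wrapper
# ---------------------------------------------------------------------------


@dataclass
class FittedFoC:
    """A fitted factors-of-curves model plus the context needed downstream."""

    spec: FoCModelSpec
    model: SEMModel
    fit: FittedSEM
    scale: dict[str, float]  # per-test divisor applied before fitting
    columns: list[str]
    exo_columns: list[str]
    row_index: pd.Index
    x: np.ndarray | None = None

    @property
    def converged(self) -> bool:
        return self.fit.converged

    @property
    def loglik(self) -> float:
        return self.fit.loglik

    def latent_sd(self, name: str) -> float:
        imp = self.model.implied(self.fit.theta, full=True)
        i = self.model.var_names.index(name)
        return float(np.sqrt(imp.sigma_v[i, i]))


def prepare_matrices(
    data: pd.DataFrame, spec: FoCModelSpec, scale: dict[str, float] | None = None
) -> tuple[np.ndarray, np.ndarray | None, dict[str, float], pd.Index]:
    """Extract (scaled) score and exogenous matrices for fitting.

    Each test's columns are divided by its wave-1 available-case SD (or the
    supplied ``scale``, to score new data on a fitted model's metric) so
    all parameters are O(1) regardless of the tests' raw units; rows with
    any missing exogenous value are dropped (complete-case policy for
    predictors), as are rows with no observed score.
    """
    cols = spec.observed_columns
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise StructuralError(f"data lack score columns: {missing[:4]}...")
    y = data[cols].to_numpy(dtype=float)
    nw = len(spec.time_basis)
    fixed = scale
    scale = {}
    for t_i, t in enumerate(spec.tests):
        if fixed is not None:
            sd = fixed[t]
        else:
            sd = np.nanstd(y[:, t_i * nw])
            if not np.isfinite(sd) or sd == 0:
                sd = 1.0
        scale[t] = float(sd)
        y[:, t_i * nw : (t_i + 1) * nw] /= sd
    keep = ~np.all(np.isnan(y), axis=1)
    x = None
    exo = spec.exogenous
    if exo:
        missing_x = [c for c in exo if c not in data.columns]
        if missing_x:
            raise StructuralError(f"data lack predictor columns: {missing_x}")
        x = data[exo].to_numpy(dtype=float)
        keep &= np.isfinite(x).all(axis=1)
        x = x[keep]
    y = y[keep]
    if spec.mediator:
        med = data.loc[keep, spec.mediator].to_numpy(dtype=float)
        y = np.column_stack([y, med])
    return y, x, scale, data.index[keep]


def fit_foc(
    data: pd.DataFrame,
    spec: FoCModelSpec,
    n_starts: int = 5,
    tol: float = 1e-9,
    compute_se: bool = True,
    seed: int = 0,
    warm_start: FittedFoC | None = None,
) -> FittedFoC:
    """Fit the factors-of-curves model by FIML.

    ``warm_start`` reuses a previous fit's parameter values for the shared
    parameters (e.g. the baseline model when adding predictors).
    """
    model = build_foc_model(spec)
    y, x, scale, rows = prepare_matrices(data, spec)
    start = foc_start_values(model, spec, y if spec.mediator is None else y[:, :-1])
    if spec.mediator:
        med = y[:, -1]
        start[model.param_index(f"m_{spec.mediator}")] = np.nanmean(med)
        start[model.param_index(f"v_{spec.mediator}")] = np.log(max(np.nanvar(med), 1e-8))
    if warm_start is not None:
        for j, name in enumerate(model.param_names):
            if name in warm_start.model.param_names:
                start[j] = warm_start.fit.theta[warm_start.model.param_index(name)]
    fit = fit_sem(
        model,
        y,
        x,
        start=start,
        n_starts=n_starts,
        tol=tol,
        compute_se=compute_se,
        seed=seed,
    )
    return FittedFoC(
        spec=spec,
        model=model,
        fit=fit,
        scale=scale,
        columns=spec.observed_columns,
        exo_columns=spec.exogenous,
        row_index=rows,
        x=x,
    )


# ---------------------------------------------------------------------------
# Standardized solution, decomposition, factor scores
# ---------------------------------------------------------------------------


def standardized_loadings(fitted: FittedFoC) -> pd.DataFrame:
    """Standardized test-on-domain and domain-on-general loadings.

    Standardization divides each path by the ratio of the downstream to the
    upstream latent SD, conditional on any exogenous regressors.
    """
    model, fit, spec = fitted.model, fitted.fit, fitted.spec
    imp = model.implied(fit.theta, full=True)
    sd = {name: np.sqrt(imp.sigma_v[i, i]) for i, name in enumerate(model.var_names)}
    est = fit.estimates
    rows = []
    for t in spec.tests:
        d = spec.domains[t]
        rows.append(
            {
                "test": t,
                "domain": d,
                "level_test_loading": est[f"lI_{t}"] * sd[f"DL_{d}"] / sd[f"I_{t}"],
                "level_domain_loading": est[f"lDL_{d}"] * sd["gL"] / sd[f"DL_{d}"],
                "slope_test_loading": est[f"lS_{t}"] * sd[f"DS_{d}"] / sd[f"S_{t}"],
                "slope_domain_loading": est[f"lDS_{d}"] * sd["gS"] / sd[f"DS_{d}"],
            }
        )
    return pd.DataFrame(rows)


def variance_decomposition(fitted: FittedFoC) -> pd.DataFrame:
    """Per-test shares of level/slope variance at each layer of the hierarchy.

    The general share is the squared product of the standardized test-on-
    domain and domain-on-general loadings; the domain share is the residual
    systematic part; the unique share completes the standardized variance.
    Shares sum to one per test and outcome by construction.
    """
    if not fitted.converged:
        raise ConvergenceError("refusing to decompose a non-converged fit")
    lo = standardized_loadings(fitted)
    rows = []
    for _, r in lo.iterrows():
        for kind in ("level", "slope"):
            lt = r[f"{kind}_test_loading"]
            ld = r[f"{kind}_domain_loading"]
            rows.append(
                {
                    "test": r["test"],
                    "domain": r["domain"],
                    "outcome": kind,
                    "general_share": (lt * ld) ** 2,
                    "domain_share": lt**2 * (1 - ld**2),
                    "unique_share": 1 - lt**2,
                }
            )
    return pd.DataFrame(rows)


def factor_scores(fitted: FittedFoC, data: pd.DataFrame) -> pd.DataFrame:
    """Regression-method scores for the general level and slope factors.

    Computed per missingness pattern from the joint latent-observed implied
    moments, conditioning on exogenous regressors where present; persons
    with no observed score (or incomplete predictors) get missing scores.
    """
    model, fit, spec = fitted.model, fitted.fit, fitted.spec
    y, x, _, rows = prepare_matrices(data, spec, scale=fitted.scale)
    pat = PatternData.from_arrays(y, x)
    imp = model.implied(fit.theta, full=True)
    lat = [model.var_names.index("gL"), model.var_names.index("gS")]
    obs_v = model.obs  # indices of observed variables within v
    B = imp.B
    mu_lat = (B @ imp.m)[lat]
    M_lat = (B @ imp.G)[lat] if model.q else np.zeros((2, 0))
    cross = imp.sigma_v[np.ix_(lat, obs_v)]

    out = np.full((len(data), 2), np.nan)
    for pt in pat.patterns:
        c = pt.cols
        K = np.linalg.solve(imp.sigma_y[np.ix_(c, c)], cross[:, c].T).T
        mu_c = imp.mu_y[c]
        resid = pt.y - mu_c
        pred_lat = np.tile(mu_lat, (pt.n, 1))
        if model.q:
            resid = resid - pt.x @ imp.M_y[c].T
            pred_lat = pred_lat + pt.x @ M_lat.T
        scores = pred_lat + resid @ K.T
        for r_local, r_global in enumerate(pt.rows):
            out[data.index.get_loc(rows[r_global])] = scores[r_local]
    return pd.DataFrame(out, index=data.index, columns=["g_level_score", "g_slope_score"])
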