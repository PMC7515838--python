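"""Associations of genetic predictors with cognitive level, slope and change.

Predictors (polygenic scores, an APOE-like carrier indicator) and ancestry
covariates are regressed onto the general level and slope factors inside
the factors-of-curves SEM; when an SEM fit fails to converge the analysis
automatically falls back to factor-score regression, and every result
records which path produced it.  Continuous predictors are standardized
before entry; binary predictors stay 0/1 and their effects are
standardized only with respect to the outcome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import ParameterError, StructuralError
from .sem.fiml import fit_sem
from .sem.foc import FittedFoC, FoCModelSpec, factor_scores, fit_foc

log = logging.getLogger(__name__)

DEFAULT_COVARIATES = ("mds1", "mds2", "mds3", "mds4")


@dataclass
class AssociationResult:
    predictor: str
    outcome: str  # "level" | "slope" | "lifetime_change" | "age11"
    beta: float  # standardized with respect to the outcome (and the
    # predictor, when continuous)
    se: float
    p: float
    q: float | None = None
    method: str = "sem"  # "sem" | "factor_score_regression"
    covariates: tuple[str, ...] = ()
    n: int = 0

    def as_dict(self) -> dict:
        return {
            "predictor": self.predictor,
            "outcome": self.outcome,
            "beta": self.beta,
            "se": self.se,
            "p": self.p,
            "q": self.q,
            "method": self.method,
            "n": self.n,
        }


def _is_binary(x: pd.Series) -> bool:
    vals = set(np.unique(x.dropna()))
    return vals <= {0, 1, 0.0, 1.0}


def _prepare_predictors(data: pd.DataFrame, names: list[str]) -> pd.DataFrame:
    """Standardize continuous predictors in place; keep binary ones 0/1."""
    out = data.copy()
    for name in names:
        if name not in out.columns:
            raise StructuralError(f"predictor column {name!r} missing")
        col = out[name]
        if col.std() == 0 or col.dropna().nunique() < 2:
            raise ParameterError(f"predictor {name!r} is constant")
        if not _is_binary(col):
            out[name] = (col - col.mean()) / col.std()
    return out


def _std_beta_fn(fitted: FittedFoC, x_name: str, factor: str, sigma_x: np.ndarray):
    """Closure computing the outcome-standardized beta as a function of theta.

    The factor's total SD combines its residual (co)variance system with
    the variance contributed by the exogenous design, whose empirical
    covariance is held fixed.
    """
    model = fitted.model
    x_j = fitted.exo_columns.index(x_name)
    f_i = model.var_names.index(factor)
    pname = f"b_{x_name}_{factor}"
    k = model.param_index(pname)

    def fn(theta: np.ndarray) -> float:
        imp = model.implied(theta, full=True)
        total = (imp.B @ imp.G)[f_i]
        var_f = imp.sigma_v[f_i, f_i] + total @ sigma_x @ total
        gamma = model.values(theta)[k]
        return float(gamma / np.sqrt(var_f))

    return fn


def _sem_results(
    fitted: FittedFoC,
    data: pd.DataFrame,
    predictors: list[str],
    covariates: tuple[str, ...],
    outcomes=(("gL", "level"), ("gS", "slope")),
) -> list[AssociationResult]:
    sigma_x = np.atleast_2d(np.cov(fitted.x, rowvar=False))
    out = []
    for pred in predictors:
        for factor, outcome in outcomes:
            pname = f"b_{pred}_{factor}"
            if pname not in fitted.model.param_names:
                continue
            fn = _std_beta_fn(fitted, pred, factor, sigma_x)
            beta = fn(fitted.fit.theta)
            se = fitted.fit.delta_se(fn)
            z = beta / se if se > 0 else np.nan
            out.append(
                AssociationResult(
                    predictor=pred,
                    outcome="lifetime_change" if outcome == "lifetime" else outcome,
                    beta=beta,
                    se=se,
                    p=float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else np.nan,
                    method="sem",
                    covariates=covariates,
                    n=fitted.fit.n_obs,
                )
            )
    return out


def _factor_score_results(
    baseline: FittedFoC,
    data: pd.DataFrame,
    predictors: list[str],
    covariates: tuple[str, ...],
    outcomes=("level", "slope"),
) -> list[AssociationResult]:
    """Fallback: regress extracted general factor scores on the predictors."""
    scores = factor_scores(baseline, data)
    frame = pd.concat([data, scores], axis=1)
    col = {"level": "g_level_score", "slope": "g_slope_score"}
    out = []
    for outcome in outcomes:
        y = frame[col[outcome]]
        y = (y - y.mean()) / y.std()
        X = frame[predictors + list(covariates)]
        ok = y.notna() & X.notna().all(axis=1)
        design = sm.add_constant(X[ok])
        res = sm.OLS(y[ok], design).fit()
        for pred in predictors:
            out.append(
                AssociationResult(
                    predictor=pred,
                    outcome=outcome,
                    beta=float(res.params[pred]),
                    se=float(res.bse[pred]),
                    p=float(res.pvalues[pred]),
                    method="factor_score_regression",
                    covariates=covariates,
                    n=int(ok.sum()),
                )
            )
    return out


def _fit_predictor_model(
    data: pd.DataFrame,
    base_spec: FoCModelSpec,
    predictors: list[str],
    covariates: tuple[str, ...],
    level_only: bool = False,
    seed: int = 0,
    warm_start: FittedFoC | None = None,
    n_starts: int = 3,
):
    exo = predictors + [c for c in covariates if c not in predictors]
    spec = FoCModelSpec(
        tests=base_spec.tests,
        domains=base_spec.domains,
        time_basis=base_spec.time_basis,
        level_slope_cov=base_spec.level_slope_cov,
        test_is_cov=base_spec.test_is_cov,
        level_predictors=exo,
        slope_predictors=[] if level_only else exo,
    )
    return fit_foc(data, spec, n_starts=n_starts, seed=seed, warm_start=warm_start)


def single_predictor_association(
    data: pd.DataFrame,
    base_spec: FoCModelSpec,
    predictor: str,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    seed: int = 0,
    baseline: FittedFoC | None = None,
) -> list[AssociationResult]:
    """One predictor (plus ancestry covariates) against level and slope.

    Fits the factors-of-curves model with the predictor attached to both
    general factors; on non-convergence, falls back to factor-score
    regression against a baseline fit (the fallback is recorded in the
    result's ``method`` field).
    """
    covariates = tuple(c for c in covariates if c in data.columns)
    frame = _prepare_predictors(data, [predictor] + list(covariates))
    fitted = _fit_predictor_model(
        frame, base_spec, [predictor], covariates, seed=seed, warm_start=baseline
    )
    if fitted.converged:
        return _sem_results(fitted, frame, [predictor], covariates)
    log.warning("SEM for %s did not converge; using factor-score regression", predictor)
    if baseline is None:
        baseline = fit_foc(frame, base_spec, seed=seed)
    return _factor_score_results(baseline, frame, [predictor], covariates)


def apoe_adjusted_association(
    data: pd.DataFrame,
    base_spec: FoCModelSpec,
    predictor: str,
    apoe_col: str = "apoe_e4",
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    seed: int = 0,
    baseline: FittedFoC | None = None,
) -> list[AssociationResult]:
    """Predictor and APOE carrier status as simultaneous predictors."""
    if apoe_col not in data.columns:
        raise StructuralError(f"APOE column {apoe_col!r} missing")
    covariates = tuple(c for c in covariates if c in data.columns)
    frame = _prepare_predictors(data, [predictor, apoe_col] + list(covariates))
    fitted = _fit_predictor_model(
        frame, base_spec, [predictor, apoe_col], covariates, seed=seed, warm_start=baseline
    )
    if fitted.converged:
        return _sem_results(fitted, frame, [predictor, apoe_col], covariates)
    if baseline is None:
        baseline = fit_foc(frame, base_spec, seed=seed)
    return _factor_score_results(baseline, frame, [predictor, apoe_col], covariates)


def simultaneous_association(
    data: pd.DataFrame,
    base_spec: FoCModelSpec,
    predictors: list[str],
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    seed: int = 0,
    baseline: FittedFoC | None = None,
) -> list[AssociationResult]:
    """All predictors entered jointly; per-predictor conditional effects."""
    if len(predictors) < 2:
        raise ParameterError("simultaneous model needs at least two predictors")
    covariates = tuple(c for c in covariates if c in data.columns)
    frame = _prepare_predictors(data, list(predictors) + list(covariates))
    X = frame[list(predictors) + list(covariates)].dropna().to_numpy()
    rank = np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), X]))
    if rank < X.shape[1] + 1:
        corr = np.corrcoef(X, rowvar=False)
        pairs = [
            (predictors + list(covariates))[i]
            for i in range(len(corr))
            for j in range(i)
            if abs(corr[i, j]) > 1 - 1e-10
        ]
        raise ParameterError(f"collinear predictor set: {sorted(set(pairs))}")
    fitted = _fit_predictor_model(
        frame, base_spec, list(predictors), covariates, seed=seed, warm_start=baseline
    )
    if fitted.converged:
        return _sem_results(fitted, frame, list(predictors), covariates)
    if baseline is None:
        baseline = fit_foc(frame, base_spec, seed=seed)
    return _factor_score_results(baseline, frame, list(predictors), covariates)


def lifetime_change_association(
    data: pd.DataFrame,
    base_spec: FoCModelSpec,
    predictor: str,
    age11_col: str = "age11",
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    seed: int = 0,
    baseline: FittedFoC | None = None,
) -> list[AssociationResult]:
    """Predictor vs the general level adjusted for the age-11 score.

    The level factor is regressed simultaneously on the age-11 score and
    the predictor; the predictor's conditional coefficient indexes
    lifetime cognitive change.  The predictor's marginal association with
    the age-11 score itself is also reported (outcome ``age11``).
    """
    if age11_col not in data.columns:
        raise StructuralError(f"age-11 column {age11_col!r} missing")
    covariates = tuple(c for c in covariates if c in data.columns)
    frame = _prepare_predictors(data, [predictor, age11_col] + list(covariates))
    exo = [age11_col, predictor]
    fitted = _fit_predictor_model(
        frame, base_spec, exo, covariates, level_only=True, seed=seed, warm_start=baseline
    )
    if fitted.converged:
        results = _sem_results(
            fitted, frame, [predictor], covariates, outcomes=(("gL", "lifetime_change"),)
        )
    else:
        if baseline is None:
            baseline = fit_foc(frame, base_spec, seed=seed)
        scores = factor_scores(baseline, frame)
        y = scores["g_level_score"]
        y = (y - y.mean()) / y.std()
        X = frame[[age11_col, predictor] + list(covariates)]
        ok = y.notna() & X.notna().all(axis=1)
        res = sm.OLS(y[ok], sm.add_constant(X[ok])).fit()
        results = [
            AssociationResult(
                predictor=predictor,
                outcome="lifetime_change",
                beta=float(res.params[predictor]),
                se=float(res.bse[predictor]),
                p=float(res.pvalues[predictor]),
                method="factor_score_regression",
                covariates=covariates,
                n=int(ok.sum()),
            )
        ]

    # marginal association of the predictor with the age-11 score (OLS)
    y11 = frame[age11_col]
    y11 = (y11 - y11.mean()) / y11.std()
    X11 = frame[[predictor] + list(covariates)]
    ok = y11.notna() & X11.notna().all(axis=1)
    res11 = sm.OLS(y11[ok], sm.add_constant(X11[ok])).fit()
    results.append(
        AssociationResult(
            predictor=predictor,
            outcome="age11",
            beta=float(res11.params[predictor]),
            se=float(res11.bse[predictor]),
            p=float(res11.pvalues[predictor]),
            method="factor_score_regression",
            covariates=covariates,
            n=int(ok.sum()),
        )
    )
    return results


# ---------------------------------------------------------------------------
# Mediation
# ---------------------------------------------------------------------------


@dataclass
class MediationResult:
    """Paths of the predictor -> mediator -> outcome decomposition."""

    a: float
    b: float
    c_prime: float
    a_se: float
    b_se: float
    c_prime_se: float
    indirect: float
    indirect_se: float
    total: float
    total_se: float
    proportion_mediated: float
    stable: bool
    method: str = "sem"
    n: int = 0


def mediation_education(
    data: pd.DataFrame,
    base_spec: FoCModelSpec,
    pgs: str = "pgs_education",
    mediator: str = "years_education",
    age11_col: str = "age11",
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    adjust_age11: bool = True,
    seed: int = 0,
) -> MediationResult:
    """Joint SEM estimate of direct and education-mediated paths to level.

    The mediator enters the model as an observed endogenous variable:
    mediator <- predictor (+ covariates) gives ``a``; general level <-
    mediator gives ``b``; general level <- predictor gives the direct path
    ``c'``.  The outcome is the age-11-adjusted level factor when
    ``adjust_age11``.  Indirect-effect and total-effect SEs use the delta
    method.
    """
    if mediator not in data.columns:
        raise StructuralError(f"mediator column {mediator!r} missing")
    covariates = tuple(c for c in covariates if c in data.columns)
    frame = _prepare_predictors(data, [pgs] + list(covariates))
    med_std = (frame[mediator] - frame[mediator].mean()) / frame[mediator].std()
    frame = frame.assign(**{mediator: med_std})
    level_preds = [pgs] + list(covariates)
    med_preds = [pgs] + list(covariates)
    if adjust_age11:
        if age11_col not in frame.columns:
            raise StructuralError(f"age-11 column {age11_col!r} missing")
        frame[age11_col] = (frame[age11_col] - frame[age11_col].mean()) / frame[age11_col].std()
        level_preds = [age11_col] + level_preds
    spec = FoCModelSpec(
        tests=base_spec.tests,
        domains=base_spec.domains,
        time_basis=base_spec.time_basis,
        level_slope_cov=base_spec.level_slope_cov,
        test_is_cov=base_spec.test_is_cov,
        level_predictors=level_preds,
        slope_predictors=[],
        mediator=mediator,
        mediator_predictors=med_preds,
    )
    fitted = fit_foc(frame, spec, n_starts=3, seed=seed)
    fit = fitted.fit
    model = fitted.model
    a_name = f"a_{pgs}_{mediator}"
    b_name = f"b_{mediator}_gL"
    c_name = f"b_{pgs}_gL"
    ia, ib, ic = (model.param_index(nm) for nm in (a_name, b_name, c_name))
    sigma_x = np.atleast_2d(np.cov(fitted.x, rowvar=False))
    f_i = model.var_names.index("gL")

    def sd_g(theta: np.ndarray) -> float:
        # total SD of the level factor: residual system + exogenous channel
        imp = model.implied(theta, full=True)
        total = (imp.B @ imp.G)[f_i]
        return float(np.sqrt(imp.sigma_v[f_i, f_i] + total @ sigma_x @ total))

    def path(i, standardize=True):
        if standardize:
            return lambda t: model.values(t)[i] / sd_g(t)
        return lambda t: model.values(t)[i]

    a_fn = path(ia, standardize=False)  # mediator and predictor are standardized
    b_fn, c_fn = path(ib), path(ic)
    indirect_fn = lambda t: a_fn(t) * b_fn(t)
    total_fn = lambda t: a_fn(t) * b_fn(t) + c_fn(t)
    theta = fit.theta
    a, b, c_prime = a_fn(theta), b_fn(theta), c_fn(theta)
    indirect = a * b
    total = indirect + c_prime
    total_se = fit.delta_se(total_fn)
    stable = bool(abs(total) >= 10 * total_se) if np.isfinite(total_se) else False
    if not stable:
        log.warning("mediation: total effect near zero; proportion mediated is unstable")
    return MediationResult(
        a=a,
        b=b,
        c_prime=c_prime,
        a_se=fit.se.get(a_name, np.nan),
        b_se=fit.delta_se(b_fn),
        c_prime_se=fit.delta_se(c_fn),
        indirect=indirect,
        indirect_se=fit.delta_se(indirect_fn),
        total=total,
        total_se=total_se,
        proportion_mediated=indirect / total if total != 0 else np.nan,
        stable=stable,
        method="sem" if fit.converged else "sem_nonconverged",
        n=fit.n_obs,
    )


def regression_from_moments(cov: np.ndarray, y: int, xs: list[int]) -> np.ndarray:
    """Population regression coefficients of variable y on variables xs."""
    cov = np.asarray(cov, dtype=float)
    Sxx = cov[np.ix_(xs, xs)]
    sxy = cov[np.ix_(xs, [y])][:, 0]
    return np.linalg.solve(Sxx, sxy)


def mediation_from_moments(cov: np.ndarray, x: int, m: int, y: int) -> MediationResult:
    """Exact mediation decomposition from a population covariance matrix.

    The n -> infinity limit: ``a`` from the regression of the mediator on
    the predictor, ``b`` and ``c'`` from the regression of the outcome on
    mediator and predictor jointly; proportion mediated is a*b/(a*b + c').
    """
    a = regression_from_moments(cov, m, [x])[0]
    b, c_prime = regression_from_moments(cov, y, [m, x])
    indirect = a * b
    total = indirect + c_prime
    return MediationResult(
        a=a, b=b, c_prime=c_prime,
        a_se=0.0, b_se=0.0, c_prime_se=0.0,
        indirect=indirect, indirect_se=0.0,
        total=total, total_se=0.0,
        proportion_mediated=indirect / total if total != 0 else np.nan,
        stable=total != 0,
        method="population_moments",
        n=0,
    )


# ---------------------------------------------------------------------------
# Multiple testing and correlation comparison
# ---------------------------------------------------------------------------


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1).

    q_(i) = min_{j >= i} min(p_(j) * m / j, 1), evaluated exactly as
    written so the result agrees bit-for-bit with the step-up definition.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ParameterError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    terms = p[order] * m / np.arange(1, m + 1)
    stepped = np.minimum.accumulate(terms[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(stepped, 1.0)
    return q


def attach_fdr(results: list[AssociationResult]) -> list[AssociationResult]:
    """Attach FDR q-values per outcome column across the predictor family."""
    by_outcome: dict[str, list[AssociationResult]] = {}
    for r in results:
        by_outcome.setdefault(r.outcome, []).append(r)
    for rows in by_outcome.values():
        q = fdr_adjust([r.p for r in rows])
        for r, qv in zip(rows, q):
            r.q = float(qv)
    return results


def williams_test(r12: float, r13: float, r23: float, n: int):
    """Williams's t (Steiger modification) for two dependent correlations.

    Compares r12 and r13, which share variable 1, given r23 and sample size
    n; returns (t, df, two-sided p) with df = n - 3.  The determinant
    |R| = 1 - r12^2 - r13^2 - r23^2 + 2 r12 r13 r23 must be positive
    (a non-positive-definite triple is rejected).
    """
    for r in (r12, r13, r23):
        if not -1 < r < 1:
            raise ParameterError("correlations must lie in (-1, 1)")
    if n <= 3:
        raise ParameterError("n must exceed 3")
    det = 1 - r12**2 - r13**2 - r23**2 + 2 * r12 * r13 * r23
    if det <= 0:
        raise ParameterError("correlation triple is not positive definite")
    rbar = 0.5 * (r12 + r13)
    denom = 2 * det * (n - 1) / (n - 3) + rbar**2 * (1 - r23) ** 3
    t = (r12 - r13) * np.sqrt((n - 1) * (1 + r23) / denom)
    df = n - 3
    p = float(2 * stats.t.sf(abs(t), df))
    return float(t), int(df), p
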