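"""Likelihood-based fit indices for FIML models.

The model chi-square is twice the gap between the FIML-saturated
log-likelihood (unrestricted mean/covariance, estimated by EM over the
missingness patterns) and the fitted model's; the independence baseline
(diagonal covariance) has a closed-form FIML solution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from ..errors import ConvergenceError
from .fiml import FittedSEM, independence_moments, saturated_moments


@dataclass
class FitIndices:
    chisq: float
    df: int
    p: float
    rmsea: float
    cfi: float
    tli: float
    srmr: float
    chisq_baseline: float
    df_baseline: int
    loglik_model: float
    loglik_saturated: float
    loglik_baseline: float
    defined: bool = True


def fit_indices(fitted: FittedSEM, rmsea_n_minus_1: bool = False) -> FitIndices:
    """Chi-square, RMSEA, CFI, TLI and SRMR for a fitted FIML model.

    RMSEA uses N in the denominator by default (``rmsea_n_minus_1`` switches
    dialect).  SRMR compares the FIML-saturated and model-implied
    covariances on the correlation scale (covariance residuals only).
    """
    if not fitted.converged:
        raise ConvergenceError("fit indices require a converged model")
    if fitted.data is None or fitted.data.q:
        raise ConvergenceError("fit indices are defined for models without exogenous regressors")
    data = fitted.data
    n = data.n_total
    p = data.p

    mu_s, sigma_s, ll_sat = saturated_moments(data)
    _, _, ll_base = independence_moments(data)
    ll_m = fitted.loglik

    moments = p * (p + 3) // 2
    df_m = moments - fitted.n_params
    df_b = moments - 2 * p

    chisq_m = max(2.0 * (ll_sat - ll_m), 0.0)
    chisq_b = max(2.0 * (ll_sat - ll_base), 0.0)
    p_val = float(stats.chi2.sf(chisq_m, df_m)) if df_m > 0 else np.nan

    denom = (n - 1) if rmsea_n_minus_1 else n
    if df_m > 0:
        rmsea = float(np.sqrt(max(chisq_m - df_m, 0.0) / (df_m * denom)))
    else:
        rmsea = 0.0 if chisq_m < 1e-6 else np.nan

    num = max(chisq_m - df_m, 0.0)
    den = max(chisq_b - df_b, chisq_m - df_m, 0.0)
    cfi = 1.0 - (num / den if den > 0 else 0.0)
    if df_m > 0 and df_b > 0 and chisq_b > df_b:
        tli = ((chisq_b / df_b) - (chisq_m / df_m)) / ((chisq_b / df_b) - 1.0)
    else:
        tli = np.nan

    imp = fitted.model.implied(fitted.theta)
    d_s = np.sqrt(np.diag(sigma_s))
    resid = (sigma_s - imp.sigma_y) / np.outer(d_s, d_s)
    iu = np.triu_indices(p)
    srmr = float(np.sqrt(np.mean(resid[iu] ** 2)))

    return FitIndices(
        chisq=float(chisq_m),
        df=int(df_m),
        p=p_val,
        rmsea=rmsea,
        cfi=float(cfi),
        tli=float(tli),
        srmr=srmr,
        chisq_baseline=float(chisq_b),
        df_baseline=int(df_b),
        loglik_model=float(ll_m),
        loglik_saturated=float(ll_sat),
        loglik_baseline=float(ll_base),
    )
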