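"""Per-test univariate latent growth curves (raw-score change per year)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import IdentificationError
from .fiml import FittedSEM, fit_sem
from .model import ModelBuilder


@dataclass
class UnivariateGrowth:
    """Mean intercept / slope of one test, with the SD-scaled slope.

    ``sd_scaled_slope`` divides the mean raw slope by the model-implied
    baseline SD, giving change per year in baseline-SD units.
    """

    mean_intercept: float
    mean_slope: float
    slope_se: float
    sd_scaled_slope: float
    baseline_sd: float
    loglik: float
    converged: bool
    fit: FittedSEM


def build_lgc_model(time_basis) -> "ModelBuilder":
    tb = np.asarray(time_basis, dtype=float)
    b = ModelBuilder()
    b.add_variable("I", latent=True)
    b.add_variable("S", latent=True)
    for w, t in enumerate(tb):
        y = f"y_w{w + 1}"
        b.add_variable(y)
        b.fix_path("I", y, 1.0)
        b.fix_path("S", y, t)
        b.free_var(y, "occ", start=0.3)
    b.free_var("I", "vI", start=1.0)
    b.free_var("S", "vS", start=0.05)
    b.free_cov("I", "S", "cIS", start=0.0)
    b.free_mean("I", "mI", start=0.0)
    b.free_mean("S", "mS", start=0.0)
    return b


def fit_univariate_lgc(
    scores: np.ndarray,
    time_basis,
    n_starts: int = 3,
    compute_se: bool = True,
    seed: int = 0,
    listwise: bool = False,
) -> UnivariateGrowth:
    """Fit a two-latent (intercept, slope) growth model to one test by FIML.

    ``scores`` is an n x n_waves matrix with NaN for unattended waves.
    With ``listwise=True`` only complete rows are used (for comparisons of
    FIML against listwise deletion under score-dependent dropout).
    """
    y = np.asarray(scores, dtype=float)
    tb = np.asarray(time_basis, dtype=float)
    if y.ndim != 2 or y.shape[1] != len(tb):
        raise IdentificationError("scores must be n x n_waves, matching time_basis")
    waves_with_data = (~np.isnan(y)).any(axis=0).sum()
    if waves_with_data < 3:
        raise IdentificationError("a growth curve needs data at >= 3 waves")
    if listwise:
        y = y[~np.isnan(y).any(axis=1)]

    model = build_lgc_model(tb).build()
    # moment starts
    means = np.nanmean(y, axis=0)
    X = np.column_stack([np.ones(len(tb)), tb])
    mi, ms = np.linalg.lstsq(X, means, rcond=None)[0]
    v0 = np.nanvar(y[:, 0])
    start = model.start.copy()
    start[model.param_index("mI")] = mi
    start[model.param_index("mS")] = ms
    start[model.param_index("vI")] = np.log(max(0.7 * v0, 1e-8))
    start[model.param_index("occ")] = np.log(max(0.3 * v0, 1e-8))
    start[model.param_index("vS")] = np.log(max(2e-3 * v0, 1e-10))

    fit = fit_sem(
        model, y, start=start, n_starts=n_starts, compute_se=compute_se, seed=seed
    )
    est = fit.estimates
    baseline_sd = float(np.sqrt(est["vI"] + est["occ"]))
    return UnivariateGrowth(
        mean_intercept=float(est["mI"]),
        mean_slope=float(est["mS"]),
        slope_se=float(fit.se.get("mS", np.nan)),
        sd_scaled_slope=float(est["mS"] / baseline_sd),
        baseline_sd=baseline_sd,
        loglik=fit.loglik,
        converged=fit.converged,
        fit=fit,
    )
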