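"""Full-information maximum likelihood over missingness patterns.

Rows are grouped by their pattern of observed entries; each pattern
contributes a multivariate-normal likelihood over its observed sub-vector,
with sufficient statistics (cross-moments with the exogenous design) held
fixed, so one likelihood evaluation costs a Cholesky factorization per
pattern regardless of sample size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize

from ..errors import ConvergenceError, ParameterError
from .model import ImpliedMoments, SEMModel

LOG_2PI = np.log(2 * np.pi)
PENALTY = -1e12


@dataclass
class Pattern:
    cols: np.ndarray  # observed column indices
    rows: np.ndarray  # row indices into the original data
    n: int
    syy: np.ndarray  # sum over rows of y y'
    syw: np.ndarray  # sum of y w', w = (1, x)
    sww: np.ndarray  # sum of w w'
    y: np.ndarray  # raw observed block (n, k), for EM / factor scores
    x: np.ndarray  # exogenous block (n, q)


@dataclass
class PatternData:
    """Missingness-pattern-grouped sufficient statistics."""

    patterns: list[Pattern]
    n_total: int
    p: int
    q: int
    pattern_counts: dict[str, int] = field(default_factory=dict)

    @classmethod
    def from_arrays(cls, y: np.ndarray, x: np.ndarray | None = None) -> "PatternData":
        y = np.asarray(y, dtype=float)
        if y.ndim != 2:
            raise ParameterError("data must be 2-dimensional")
        n, p = y.shape
        x = np.zeros((n, 0)) if x is None else np.asarray(x, dtype=float)
        if len(x) != n:
            raise ParameterError("exogenous design and data differ in length")
        if x.size and not np.isfinite(x).all():
            raise ParameterError("exogenous design must be complete (no missing values)")
        mask = ~np.isnan(y)
        keep = mask.any(axis=1)
        y, x, mask = y[keep], x[keep], mask[keep]
        rows_all = np.flatnonzero(keep)
        codes = np.packbits(mask, axis=1).view()
        keys = [c.tobytes() for c in codes]
        groups: dict[bytes, list[int]] = {}
        for i, key in enumerate(keys):
            groups.setdefault(key, []).append(i)
        patterns = []
        counts = {}
        for idx in groups.values():
            idx = np.asarray(idx)
            cols = np.flatnonzero(mask[idx[0]])
            yb = y[np.ix_(idx, cols)]
            xb = x[idx]
            w = np.column_stack([np.ones(len(idx)), xb])
            patterns.append(
                Pattern(
                    cols=cols,
                    rows=rows_all[idx],
                    n=len(idx),
                    syy=yb.T @ yb,
                    syw=yb.T @ w,
                    sww=w.T @ w,
                    y=yb,
                    x=xb,
                )
            )
            counts["".join("1" if mask[idx[0], j] else "0" for j in range(p))] = len(idx)
        patterns.sort(key=lambda pt: -pt.n)
        return cls(patterns=patterns, n_total=int(len(y)), p=p, q=x.shape[1], pattern_counts=counts)


def loglik_and_grad_moments(
    mu: np.ndarray,
    sigma: np.ndarray,
    M: np.ndarray,
    data: PatternData,
    want_grad: bool = True,
):
    """FIML log-likelihood and its gradient w.r.t. the implied moments.

    Returns ``(ll, dL_dSigma, dL_dmu, dL_dM)``; on a non-positive-definite
    sub-covariance returns a large negative penalty (optimizer-safe) with
    ``None`` gradients.
    """
    p, q = data.p, data.q
    finite = np.isfinite(sigma).all() and np.isfinite(mu).all() and np.isfinite(M).all()
    if not finite:
        return 2 * PENALTY, None, None, None
    ll = 0.0
    dSig = np.zeros((p, p)) if want_grad else None
    dmu = np.zeros(p) if want_grad else None
    dM = np.zeros((p, q)) if want_grad else None
    for pt in data.patterns:
        c = pt.cols
        k = len(c)
        sig = sigma[np.ix_(c, c)]
        theta = np.column_stack([mu[c], M[c]]) if q else mu[c][:, None]
        try:
            cf = linalg.cho_factor(sig, lower=True, check_finite=False)
        except linalg.LinAlgError:
            deficit = float(-np.linalg.eigvalsh(sig).min())
            return PENALTY * (1.0 + deficit), None, None, None
        logdet = 2.0 * np.log(np.diag(cf[0])).sum()
        cmat = (
            pt.syy
            - theta @ pt.syw.T
            - pt.syw @ theta.T
            + theta @ pt.sww @ theta.T
        )
        sic = linalg.cho_solve(cf, cmat, check_finite=False)
        ll += -0.5 * (pt.n * (k * LOG_2PI + logdet) + np.trace(sic))
        if want_grad:
            si = linalg.cho_solve(cf, np.eye(k), check_finite=False)
            u_block = -0.5 * (pt.n * si - si @ cmat @ si)
            dSig[np.ix_(c, c)] += 0.5 * (u_block + u_block.T)
            dtheta = -si @ (theta @ pt.sww - pt.syw)
            dmu[c] += dtheta[:, 0]
            if q:
                dM[c] += dtheta[:, 1:]
    return ll, dSig, dmu, dM


def fiml_loglik(model: SEMModel, theta: np.ndarray, data: PatternData) -> float:
    imp = model.implied(theta)
    ll, *_ = loglik_and_grad_moments(imp.mu_y, imp.sigma_y, imp.M_y, data, want_grad=False)
    return ll


def fiml_loglik_grad(model: SEMModel, theta: np.ndarray, data: PatternData):
    imp = model.implied(theta)
    ll, dSig, dmu, dM = loglik_and_grad_moments(imp.mu_y, imp.sigma_y, imp.M_y, data)
    if dSig is None:
        return ll, None
    return ll, model.backprop(theta, imp, dSig, dmu, dM)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


@dataclass
class FittedSEM:
    """Estimates, uncertainty and diagnostics for one FIML fit."""

    model: SEMModel
    theta: np.ndarray  # optimizer-scale parameters
    estimates: dict[str, float]  # natural-scale values by parameter name
    se: dict[str, float]  # natural-scale standard errors (delta method)
    loglik: float
    converged: bool
    grad_norm: float
    n_obs: int
    n_params: int
    pattern_counts: dict[str, int]
    n_starts_used: int = 1
    trace: list[str] = field(default_factory=list)
    vcov: np.ndarray | None = None  # covariance of theta (optimizer scale)
    data: PatternData | None = None

    @property
    def df(self) -> int:
        """Degrees of freedom: observed moments minus free parameters."""
        p, q = self.model.ny, self.model.q
        moments = p * (p + 1) // 2 + p + p * q
        return moments - self.n_params

    def param_se(self, name: str) -> float:
        return self.se.get(name, np.nan)

    def delta_se(self, fn) -> float:
        """Delta-method SE of a scalar function of the parameter vector."""
        if self.vcov is None:
            return np.nan
        g = _num_grad(fn, self.theta)
        return float(np.sqrt(max(g @ self.vcov @ g, 0.0)))


def _num_grad(fn, theta: np.ndarray, h: float = 1e-5) -> np.ndarray:
    g = np.zeros(len(theta))
    for j in range(len(theta)):
        step = h * max(1.0, abs(theta[j]))
        tp = theta.copy()
        tp[j] += step
        tm = theta.copy()
        tm[j] -= step
        g[j] = (fn(tp) - fn(tm)) / (2 * step)
    return g


def _hessian_from_grad(grad_fn, theta: np.ndarray, h: float = 1e-5) -> np.ndarray:
    """Jacobian of an analytic gradient by central differences (symmetrized)."""
    k = len(theta)
    H = np.zeros((k, k))
    for j in range(k):
        step = h * max(1.0, abs(theta[j]))
        tp = theta.copy()
        tp[j] += step
        tm = theta.copy()
        tm[j] -= step
        H[:, j] = (grad_fn(tp) - grad_fn(tm)) / (2 * step)
    return 0.5 * (H + H.T)


def _newton_polish(objective, hess_fn, theta, f, g, n, gtol, max_outer=10, max_inner=60):
    """Damped Newton refinement with Hessian reuse across inner steps.

    L-BFGS approaches the optimum but crawls on the ill-conditioned tail of
    the FIML surface; a few Levenberg-damped Newton steps (recomputing the
    Hessian only when progress with the current one stalls) finish the job.
    Returns (theta, f, g, H) with H the last Hessian of the scaled objective.
    """
    lam = 1e-9
    H = None
    for _ in range(max_outer):
        H = hess_fn(theta)
        improved = False
        for _ in range(max_inner):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")  # near-singular H handled by damping
                    step = linalg.solve(H + lam * np.eye(len(theta)), -g, assume_a="sym")
            except (linalg.LinAlgError, ValueError):
                lam = max(lam, 1e-10) * 10
                continue
            f_new, g_new = objective(theta + step)
            if f_new < f:
                theta = theta + step
                f, g = f_new, g_new
                lam = max(lam / 3, 1e-11)
                improved = True
            else:
                lam *= 10
                if lam > 1e6:
                    break
                continue
            if np.linalg.norm(g) * n < 0.1 * gtol:
                return theta, f, g, H
        if not improved:
            break
    return theta, f, g, H


def fit_sem(
    model: SEMModel,
    y: np.ndarray,
    x: np.ndarray | None = None,
    start: np.ndarray | None = None,
    n_starts: int = 5,
    tol: float = 1e-8,
    gtol: float = 1e-4,
    maxiter: int = 1000,
    compute_se: bool = True,
    seed: int = 0,
    data: PatternData | None = None,
) -> FittedSEM:
    """Maximize the FIML log-likelihood: L-BFGS-B warmup + Newton polish.

    The first start is the supplied (or model default) vector; additional
    jittered starts are attempted only while the best solution so far has
    not converged, up to ``n_starts``.  Standard errors come from the
    inverse observed information (numerical Jacobian of the analytic
    gradient), with the delta method applied to log-scale variance
    parameters.  The convergence flag is honest: a per-observation
    gradient-norm check at the returned solution.
    """
    if data is None:
        data = PatternData.from_arrays(y, x)
    if data.n_total == 0:
        raise ParameterError("no rows with at least one observed entry")
    n = data.n_total
    theta0 = np.asarray(start, dtype=float) if start is not None else model.start.copy()
    if len(theta0) != model.n_free:
        raise ParameterError("start vector has wrong length")

    def objective(theta):
        ll, grad = fiml_loglik_grad(model, theta, data)
        if grad is None:
            return -ll / n, np.zeros_like(theta)
        return -ll / n, -grad / n

    def hess_fn(theta):
        grad_fn = lambda t: objective(t)[1]
        return _hessian_from_grad(grad_fn, theta)

    def newton_decrement(g, H):
        """Expected log-likelihood gain of a full (regularized) Newton step.

        Scale-invariant stopping measure: steep but flat-in-likelihood
        directions (huge curvature) do not block convergence the way a raw
        gradient norm would.
        """
        w, V = np.linalg.eigh(H)
        w = np.maximum(w, max(1e-8, 1e-10 * w.max()))
        gv = V.T @ g
        return float(0.5 * np.sum(gv**2 / w) * n)

    rng = np.random.default_rng(seed)
    best = None
    trace: list[str] = []
    starts_used = 0
    for s in range(max(n_starts, 1)):
        theta_s = theta0
        if s > 0:
            jitter = 0.1
            for _ in range(8):  # keep jittered starts out of the penalty region
                theta_s = theta0 + rng.normal(scale=jitter, size=len(theta0))
                if objective(theta_s)[0] < -PENALTY / n:
                    break
                jitter /= 2
        res = optimize.minimize(
            objective,
            theta_s,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": maxiter, "ftol": tol * 0.01, "gtol": 1e-9, "maxcor": 30},
        )
        starts_used = s + 1
        theta_hat, f_hat, g_hat, H = _newton_polish(
            objective, hess_fn, res.x, res.fun, res.jac, n, gtol
        )
        gnorm = float(np.linalg.norm(g_hat) * n)
        in_bounds = f_hat < -PENALTY / n
        dec = newton_decrement(g_hat, H) if in_bounds else np.inf
        # converged when the gradient is small per observation, or when a
        # full Newton step could improve the log-likelihood only by a
        # negligible relative amount (sharp-ridge surfaces defeat raw
        # gradient norms)
        ok = bool(in_bounds and (gnorm / n < gtol or dec < 1e-8 * max(1.0, abs(f_hat * n))))
        trace.append(f"start {s}: ll={-f_hat * n:.6f} gnorm={gnorm:.3e} decrement={dec:.2e} ok={ok}")
        if best is None or f_hat < best[0] - 1e-12:
            best = (f_hat, theta_hat, g_hat, H, ok, gnorm)
        if best[4]:
            break

    f_hat, theta_hat, g_hat, H, converged, gnorm = best
    ll_hat = float(-f_hat * n)

    estimates = dict(zip(model.param_names, model.values(theta_hat)))
    se: dict[str, float] = {}
    vcov = None
    if compute_se and converged:
        info = n * hess_fn(theta_hat)  # observed information for -loglik
        try:
            vcov = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            vcov = np.linalg.pinv(info)
        dvar = np.diag(vcov).copy()
        dvar[dvar < 0] = np.nan
        sd = np.sqrt(dvar)
        vals = model.values(theta_hat)
        for j, name in enumerate(model.param_names):
            # chain rule for log-scale parameters: SE(v) = v * SE(log v)
            se[name] = float(sd[j] * (vals[j] if model.log_scale[j] else 1.0))

    return FittedSEM(
        model=model,
        theta=theta_hat,
        estimates=estimates,
        se=se,
        loglik=ll_hat,
        converged=converged,
        grad_norm=gnorm,
        n_obs=n,
        n_params=model.n_free,
        pattern_counts=data.pattern_counts,
        n_starts_used=starts_used,
        trace=trace,
        vcov=vcov,
        data=data,
    )


# ---------------------------------------------------------------------------
# Saturated and independence reference models
# ---------------------------------------------------------------------------


def saturated_moments(
    data: PatternData, tol: float = 1e-9, maxiter: int = 2000
) -> tuple[np.ndarray, np.ndarray, float]:
    """FIML estimates of an unrestricted mean vector and covariance via EM.

    Standard multivariate-normal EM over missingness patterns; returns
    (mu, sigma, loglik).  Only defined for models without exogenous
    regressors (q = 0).
    """
    if data.q:
        raise ParameterError("saturated moments are defined for q = 0 only")
    p = data.p
    n = data.n_total
    # start: available-case means and variances, zero covariances off-diagonal
    count = np.zeros(p)
    total = np.zeros(p)
    sq = np.zeros(p)
    for pt in data.patterns:
        count[pt.cols] += pt.n
        total[pt.cols] += pt.y.sum(axis=0)
        sq[pt.cols] += (pt.y**2).sum(axis=0)
    mu = total / np.maximum(count, 1)
    var = sq / np.maximum(count, 1) - mu**2
    sigma = np.diag(np.maximum(var, 1e-8))

    ll_old = -np.inf
    for _ in range(maxiter):
        sum_x = np.zeros(p)
        sum_xx = np.zeros((p, p))
        for pt in data.patterns:
            o = pt.cols
            mis = np.setdiff1d(np.arange(p), o, assume_unique=True)
            yo = pt.y
            sum_x[o] += yo.sum(axis=0)
            sum_xx[np.ix_(o, o)] += yo.T @ yo
            if len(mis):
                soo = sigma[np.ix_(o, o)]
                smo = sigma[np.ix_(mis, o)]
                ks = np.linalg.solve(soo, smo.T).T  # regression of mis on obs
                resid_cov = sigma[np.ix_(mis, mis)] - ks @ smo.T
                em = mu[mis] + (yo - mu[o]) @ ks.T
                sum_x[mis] += em.sum(axis=0)
                sum_xx[np.ix_(mis, o)] += em.T @ yo
                sum_xx[np.ix_(o, mis)] += yo.T @ em
                sum_xx[np.ix_(mis, mis)] += em.T @ em + pt.n * resid_cov
        mu = sum_x / n
        sigma = sum_xx / n - np.outer(mu, mu)
        sigma = 0.5 * (sigma + sigma.T)
        ll, *_ = loglik_and_grad_moments(mu, sigma, np.zeros((p, 0)), data, want_grad=False)
        if abs(ll - ll_old) < tol * (abs(ll_old) + 1.0):
            break
        ll_old = ll
    return mu, sigma, float(ll)


def independence_moments(data: PatternData) -> tuple[np.ndarray, np.ndarray, float]:
    """Closed-form FIML fit of the independence (diagonal) baseline.

    With mutually independent variables the likelihood factorizes, so the
    MLE per variable is the available-case mean and (biased) variance.
    """
    if data.q:
        raise ParameterError("independence baseline is defined for q = 0 only")
    p = data.p
    count = np.zeros(p)
    total = np.zeros(p)
    sq = np.zeros(p)
    for pt in data.patterns:
        count[pt.cols] += pt.n
        total[pt.cols] += pt.y.sum(axis=0)
        sq[pt.cols] += (pt.y**2).sum(axis=0)
    mu = total / np.maximum(count, 1)
    var = np.maximum(sq / np.maximum(count, 1) - mu**2, 1e-12)
    sigma = np.diag(var)
    ll, *_ = loglik_and_grad_moments(mu, sigma, np.zeros((p, 0)), data, want_grad=False)
    return mu, sigma, float(ll)
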