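"""RAM-parameterized structural equation models with exogenous regressors.

A model over variables v (latent + endogenous observed) is

    v = A v + G x + m + residual,   Cov(residual) = S,

so conditional on exogenous x the observed sub-vector y is multivariate
normal with mean  F B m + F B G x  and covariance  F B S B' F', where
B = (I - A)^{-1} and F selects the observed rows.  Exogenous regressors are
conditioned on rather than modelled, which keeps binary predictors exact
and adds no nuisance parameters.

Free parameters live in a flat vector theta; variance-type entries are
optimized on the log scale.  ``backprop`` converts gradients with respect
to the implied moments into gradients with respect to theta, which gives
FIML an analytic gradient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..errors import IdentificationError, ParameterError


@dataclass
class ImpliedMoments:
    """Implied moments plus the intermediates needed for gradients."""

    mu_y: np.ndarray  # (ny,)
    sigma_y: np.ndarray  # (ny, ny)
    M_y: np.ndarray  # (ny, q) effect of exogenous x on y
    B: np.ndarray
    Bo: np.ndarray  # observed rows of B
    S: np.ndarray
    m: np.ndarray
    G: np.ndarray
    sigma_v: np.ndarray | None = None


@dataclass
class SEMModel:
    """Matrix-form SEM with free/fixed masks over A, S, m and G."""

    var_names: list[str]
    obs_names: list[str]
    exo_names: list[str]
    A0: np.ndarray
    S0: np.ndarray
    m0: np.ndarray
    G0: np.ndarray
    free_A: np.ndarray  # (nA, 3) rows (i, j, param)
    free_S: np.ndarray  # (nS, 3) rows (i, j, param), i <= j, both cells set
    free_m: np.ndarray  # (nm, 2) rows (i, param)
    free_G: np.ndarray  # (nG, 3)
    param_names: list[str]
    log_scale: np.ndarray  # bool per param
    start: np.ndarray
    labels: dict = field(default_factory=dict)  # semantic annotations

    def __post_init__(self) -> None:
        self.obs = np.array([self.var_names.index(n) for n in self.obs_names])

    @property
    def nv(self) -> int:
        return len(self.var_names)

    @property
    def ny(self) -> int:
        return len(self.obs_names)

    @property
    def q(self) -> int:
        return len(self.exo_names)

    @property
    def n_free(self) -> int:
        return len(self.param_names)

    def param_index(self, name: str) -> int:
        return self.param_names.index(name)

    # -- materialization ----------------------------------------------------

    def values(self, theta: np.ndarray) -> np.ndarray:
        """Natural-scale parameter values (exp of log-scale entries)."""
        vals = np.asarray(theta, dtype=float).copy()
        vals[self.log_scale] = np.exp(vals[self.log_scale])
        return vals

    def matrices(self, theta: np.ndarray):
        vals = self.values(theta)
        A = self.A0.copy()
        S = self.S0.copy()
        m = self.m0.copy()
        G = self.G0.copy()
        if len(self.free_A):
            A[self.free_A[:, 0], self.free_A[:, 1]] = vals[self.free_A[:, 2]]
        if len(self.free_S):
            S[self.free_S[:, 0], self.free_S[:, 1]] = vals[self.free_S[:, 2]]
            S[self.free_S[:, 1], self.free_S[:, 0]] = vals[self.free_S[:, 2]]
        if len(self.free_m):
            m[self.free_m[:, 0]] = vals[self.free_m[:, 1]]
        if len(self.free_G):
            G[self.free_G[:, 0], self.free_G[:, 1]] = vals[self.free_G[:, 2]]
        return A, S, m, G

    def implied(self, theta: np.ndarray, full: bool = False) -> ImpliedMoments:
        """Model-implied mean, covariance and exogenous-effect matrix of y."""
        A, S, m, G = self.matrices(theta)
        eye = np.eye(self.nv)
        with np.errstate(invalid="ignore", over="ignore"):  # penalty handles non-finite
            B = np.linalg.solve(eye - A, eye)
            Bo = B[self.obs]
            sigma_y = Bo @ S @ Bo.T
            mu_y = Bo @ m
            M_y = Bo @ G if self.q else np.zeros((self.ny, 0))
            sigma_v = B @ S @ B.T if full else None
        return ImpliedMoments(mu_y, sigma_y, M_y, B, Bo, S, m, G, sigma_v)

    # -- gradient backpropagation -------------------------------------------

    def backprop(
        self,
        theta: np.ndarray,
        imp: ImpliedMoments,
        dL_dSigma: np.ndarray,
        dL_dmu: np.ndarray,
        dL_dM: np.ndarray | None,
    ) -> np.ndarray:
        """Chain d(loglik)/d(implied moments) back to d(loglik)/d(theta).

        ``dL_dSigma`` must be symmetric.  Uses the identities
        Sigma_y = Bo S Bo', mu_y = Bo m, M_y = Bo G with dB = B dA B.
        """
        B, Bo, S, m, G = imp.B, imp.Bo, imp.S, imp.m, imp.G
        UBo = dL_dSigma @ Bo  # (ny, nv)
        T = Bo.T @ UBo  # dL/dS (full matrix form)
        dA = 2.0 * (B @ (S @ (Bo.T @ UBo))).T  # covariance channel
        Bm = B @ m
        Btu = Bo.T @ dL_dmu
        dA += np.outer(Btu, Bm)
        dm = Btu
        if self.q and dL_dM is not None and dL_dM.size:
            BG = B @ G
            BtV = Bo.T @ dL_dM
            dA += BtV @ BG.T
            dG = BtV
        else:
            dG = None

        grad = np.zeros(self.n_free)
        if len(self.free_A):
            np.add.at(grad, self.free_A[:, 2], dA[self.free_A[:, 0], self.free_A[:, 1]])
        if len(self.free_S):
            i, j, k = self.free_S[:, 0], self.free_S[:, 1], self.free_S[:, 2]
            contrib = np.where(i == j, T[i, j], T[i, j] + T[j, i])
            np.add.at(grad, k, contrib)
        if len(self.free_m):
            np.add.at(grad, self.free_m[:, 1], dm[self.free_m[:, 0]])
        if dG is not None and len(self.free_G):
            np.add.at(grad, self.free_G[:, 2], dG[self.free_G[:, 0], self.free_G[:, 1]])

        # log-scale chain rule: d/d(log v) = v * d/dv
        vals = self.values(theta)
        grad[self.log_scale] *= vals[self.log_scale]
        return grad


class ModelBuilder:
    """Incremental construction of an :class:`SEMModel`."""

    def __init__(self) -> None:
        self._vars: list[str] = []
        self._latent: set[str] = set()
        self._exo: list[str] = []
        self._A: dict[tuple[str, str], float | str] = {}
        self._S: dict[tuple[str, str], float | str] = {}
        self._m: dict[str, float | str] = {}
        self._G: dict[tuple[str, str], float | str] = {}
        self._params: dict[str, dict] = {}
        self.labels: dict = {}

    def add_variable(self, name: str, latent: bool = False) -> None:
        if name in self._vars:
            raise ParameterError(f"duplicate variable {name!r}")
        self._vars.append(name)
        if latent:
            self._latent.add(name)

    def add_exogenous(self, name: str) -> None:
        if name in self._exo:
            raise ParameterError(f"duplicate exogenous variable {name!r}")
        self._exo.append(name)

    def _register(self, pname: str, start: float, log_scale: bool) -> str:
        if pname not in self._params:
            self._params[pname] = {"start": start, "log": log_scale}
        return pname

    def fix_path(self, src: str, dst: str, value: float) -> None:
        self._A[(dst, src)] = float(value)

    def free_path(self, src: str, dst: str, name: str, start: float = 0.5) -> None:
        self._A[(dst, src)] = self._register(name, start, False)

    def fix_cov(self, a: str, b: str, value: float) -> None:
        self._S[(a, b)] = float(value)

    def free_var(self, a: str, name: str, start: float = 1.0) -> None:
        self._S[(a, a)] = self._register(name, np.log(max(start, 1e-8)), True)

    def free_cov(self, a: str, b: str, name: str, start: float = 0.0) -> None:
        self._S[(a, b)] = self._register(name, start, False)

    def fix_mean(self, a: str, value: float) -> None:
        self._m[a] = float(value)

    def free_mean(self, a: str, name: str, start: float = 0.0) -> None:
        self._m[a] = self._register(name, start, False)

    def free_exo_path(self, x: str, dst: str, name: str, start: float = 0.0) -> None:
        self._G[(dst, x)] = self._register(name, start, False)

    def build(self) -> SEMModel:
        nv = len(self._vars)
        q = len(self._exo)
        vi = {n: i for i, n in enumerate(self._vars)}
        xi = {n: i for i, n in enumerate(self._exo)}
        pnames = list(self._params)
        pidx = {n: i for i, n in enumerate(pnames)}

        A0 = np.zeros((nv, nv))
        S0 = np.zeros((nv, nv))
        m0 = np.zeros(nv)
        G0 = np.zeros((nv, q))
        fA, fS, fm, fG = [], [], [], []
        for (dst, src), v in self._A.items():
            i, j = vi[dst], vi[src]
            if isinstance(v, str):
                fA.append((i, j, pidx[v]))
            else:
                A0[i, j] = v
        for (a, b), v in self._S.items():
            i, j = sorted((vi[a], vi[b]))
            if isinstance(v, str):
                fS.append((i, j, pidx[v]))
            else:
                S0[i, j] = S0[j, i] = v
        for a, v in self._m.items():
            if isinstance(v, str):
                fm.append((vi[a], pidx[v]))
            else:
                m0[vi[a]] = v
        for (dst, x), v in self._G.items():
            if isinstance(v, str):
                fG.append((vi[dst], xi[x], pidx[v]))
            else:
                G0[vi[dst], xi[x]] = v

        obs_names = [n for n in self._vars if n not in self._latent]
        if not obs_names:
            raise IdentificationError("model has no observed variables")
        model = SEMModel(
            var_names=self._vars,
            obs_names=obs_names,
            exo_names=list(self._exo),
            A0=A0,
            S0=S0,
            m0=m0,
            G0=G0,
            free_A=np.array(fA, dtype=int).reshape(-1, 3),
            free_S=np.array(fS, dtype=int).reshape(-1, 3),
            free_m=np.array(fm, dtype=int).reshape(-1, 2),
            free_G=np.array(fG, dtype=int).reshape(-1, 3),
            param_names=pnames,
            log_scale=np.array([self._params[n]["log"] for n in pnames], dtype=bool),
            start=np.array([self._params[n]["start"] for n in pnames], dtype=float),
            labels=dict(self.labels),
        )
        return model
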