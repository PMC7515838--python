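"""Synthetic cohort, genotype and GWAS summary-statistic generation.

The generator emulates a longitudinal ageing study: 13 cognitive tests in
four correlated domains measured at four waves roughly three years apart,
a hierarchical factor structure over latent growth intercepts (levels) and
slopes, score-dependent monotone dropout, a childhood (age-11) cognitive
score, genetic predictors with small standardized effects, and validation
phenotypes for each polygenic score.

Observed test scores are an explicit linear map over independent base
variables (predictors, latent residuals at each layer of the hierarchy,
sex, baseline age) plus independent occasion noise.  Because the simulator
and :meth:`GenerativeSpec.implied_moments` share that map, the population
mean and covariance of complete data are available in closed form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .battery import (
    DEFAULT_SEX_EFFECTS,
    DOMAINS,
    PredictorEffect,
    TestSpec,
    ValidationPhenotype,
    default_battery,
    default_predictor_effects,
    default_validation_phenotypes,
)
from .errors import AlignmentError, ParameterError, SpecError

BASES = "ACGT"
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

DEFAULT_TIME_BASIS = (0.0, 2.98, 6.71, 9.78)
DEFAULT_RETENTION = (1091, 866, 697, 550)


# ---------------------------------------------------------------------------
# Genotypes and summary statistics
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Dosage matrix (n persons x m SNPs) with per-SNP metadata.

    ``snps`` has columns ``snp, chrom, pos, a1, a2, maf`` where ``a1`` is the
    dosage-counted (effect) allele.  Positions are 1-based and sorted within
    chromosome; dosages lie in [0, 2].
    """

    dosage: np.ndarray
    snps: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.ndim != 2:
            raise ParameterError("dosage must be 2-dimensional")
        if self.dosage.shape[1] != len(self.snps):
            raise AlignmentError("dosage columns and SNP metadata differ in length")
        if not self.snps["snp"].is_unique:
            raise ParameterError("SNP ids must be unique")
        if self.dosage.size and (self.dosage.min() < 0 or self.dosage.max() > 2):
            raise ParameterError("dosages must lie in [0, 2]")
        for _, grp in self.snps.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing:
                raise ParameterError("positions must be sorted within chromosome")

    @property
    def n(self) -> int:
        return self.dosage.shape[0]

    @property
    def m(self) -> int:
        return self.dosage.shape[1]


@dataclass
class SummaryStats:
    """Per-SNP GWAS effect sizes: ``snp, chrom, pos, a1, a2, beta, se, p``."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"snp", "chrom", "pos", "a1", "a2", "beta", "se", "p"}
        missing = required - set(self.table.columns)
        if missing:
            raise ParameterError(f"summary statistics missing columns: {sorted(missing)}")
        if not self.table["snp"].is_unique:
            raise ParameterError("SNP ids must be unique")
        p = self.table["p"].to_numpy()
        if len(p) and (np.nanmin(p) <= 0 or np.nanmax(p) > 1):
            raise ParameterError("p-values must lie in (0, 1]")
        alleles = set(self.table["a1"]) | set(self.table["a2"])
        if len(self.table) and not alleles <= set(BASES):
            raise ParameterError("alleles must be A/C/G/T")

    def __len__(self) -> int:
        return len(self.table)


def simulate_genotypes(
    n: int,
    m: int,
    block_size: int = 20,
    within_block_r: float = 0.35,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
) -> GenotypeMatrix:
    """Simulate LD-blocked biallelic dosages under Hardy-Weinberg equilibrium.

    Each haplotype copy carries a latent Gaussian liability with exchangeable
    correlation ``within_block_r`` inside blocks of ``block_size`` adjacent
    SNPs; an allele is present when the liability falls below the
    minor-allele-frequency threshold, and the dosage is the sum over the two
    independent copies.  Block positions are laid out so each block spans
    well under 250 kb while distinct blocks are separated by larger gaps.
    """
    if n < 0 or m < 0:
        raise ParameterError("n and m must be non-negative")
    if not 0 <= within_block_r < 1:
        raise ParameterError("within_block_r must lie in [0, 1)")
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ParameterError("maf_range must be a sub-interval of (0, 0.5]")
    if block_size < 1:
        raise ParameterError("block_size must be positive")

    rng = np.random.default_rng(seed)
    maf = rng.uniform(lo, hi, size=m)
    thresholds = stats.norm.ppf(maf)

    dosage = np.empty((n, m))
    start = 0
    block_id = 0
    chroms = np.empty(m, dtype=int)
    positions = np.empty(m, dtype=int)
    cursor = dict.fromkeys(range(1, 23), 10_000)
    while start < m:
        stop = min(start + block_size, m)
        bs = stop - start
        chrom = (block_id % 22) + 1
        spacing = rng.integers(2_000, 8_000, size=bs)
        pos = cursor[chrom] + np.cumsum(spacing)
        cursor[chrom] = int(pos[-1]) + 400_000
        chroms[start:stop] = chrom
        positions[start:stop] = pos
        if n:
            # two independent haplotype copies, exchangeable within-block corr
            common = rng.standard_normal((n, 2, 1))
            own = rng.standard_normal((n, 2, bs))
            z = np.sqrt(within_block_r) * common + np.sqrt(1 - within_block_r) * own
            alleles = z < thresholds[start:stop]
            dosage[:, start:stop] = alleles.sum(axis=1)
        start = stop
        block_id += 1

    pairs = [(a, b) for a in BASES for b in BASES if a != b]
    idx = rng.integers(0, len(pairs), size=m)
    a1 = np.array([pairs[i][0] for i in idx])
    a2 = np.array([pairs[i][1] for i in idx])
    snps = pd.DataFrame(
        {
            "snp": [f"rs{i + 1}" for i in range(m)],
            "chrom": chroms[:m] if m else np.array([], dtype=int),
            "pos": positions[:m] if m else np.array([], dtype=int),
            "a1": a1,
            "a2": a2,
            "maf": maf,
        }
    )
    order = np.lexsort((snps["pos"], snps["chrom"])) if m else np.array([], dtype=int)
    snps = snps.iloc[order].reset_index(drop=True)
    return GenotypeMatrix(dosage[:, order] if m else dosage, snps)


def simulate_summary_stats(
    genotypes: GenotypeMatrix,
    true_betas: np.ndarray,
    gwas_n: int,
    seed: int = 0,
) -> SummaryStats:
    """Noisy discovery-GWAS marginal effects for a standardized phenotype.

    Sampling error uses the large-sample standard error of a per-allele
    regression coefficient, SE = 1 / sqrt(N * 2 p (1-p)); two-sided normal
    p-values.
    """
    true_betas = np.asarray(true_betas, dtype=float)
    if len(true_betas) != genotypes.m:
        raise AlignmentError("true_betas must align with the genotype SNPs")
    if gwas_n <= 0:
        raise ParameterError("gwas_n must be positive")
    rng = np.random.default_rng(seed)
    maf = genotypes.snps["maf"].to_numpy()
    se = 1.0 / np.sqrt(gwas_n * 2 * maf * (1 - maf))
    beta = true_betas + rng.standard_normal(genotypes.m) * se
    z = np.abs(beta / se)
    p = np.clip(2 * stats.norm.sf(z), 1e-300, 1.0)
    table = genotypes.snps[["snp", "chrom", "pos", "a1", "a2"]].copy()
    table["beta"] = beta
    table["se"] = se
    table["p"] = p
    return SummaryStats(table)


def simulate_trait_architecture(
    genotypes: GenotypeMatrix,
    h2: float = 0.25,
    causal_fraction: float = 0.2,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw per-allele true effects and the implied standardized true score.

    Effects are normal on the standardized-genotype scale for a random
    causal subset, rescaled so the causal variants jointly explain ``h2``
    of a unit-variance phenotype; the returned per-person score is the
    dosage-weighted sum, standardized in-sample.
    """
    if genotypes.m == 0:
        raise ParameterError("cannot draw an architecture over zero SNPs")
    rng = np.random.default_rng(seed)
    maf = genotypes.snps["maf"].to_numpy()
    causal = rng.random(genotypes.m) < causal_fraction
    if not causal.any():
        causal[rng.integers(genotypes.m)] = True
    u = np.where(causal, rng.standard_normal(genotypes.m), 0.0)
    var_unit = 2 * maf * (1 - maf)
    beta = u / np.sqrt(var_unit)  # per-allele effects
    raw_var = float(np.sum(var_unit * beta**2))
    beta *= np.sqrt(h2 / raw_var)
    score = genotypes.dosage @ beta
    sd = score.std()
    score = (score - score.mean()) / (sd if sd > 0 else 1.0)
    return beta, score


# ---------------------------------------------------------------------------
# Generative specification
# ---------------------------------------------------------------------------


@dataclass
class MediationSpec:
    """Education-mediation structure: predictor -> mediator -> general level.

    ``a`` is the predictor's standardized effect on the mediator (years of
    education), ``b`` the mediator's conditional effect on the general level
    factor, ``c_prime`` the direct path.  The predictor's marginal level
    effect is a*b + c_prime; with the defaults that is 0.300 and the
    proportion mediated a*b/(a*b + c_prime) is 6.4%.
    """

    predictor: str = "pgs_education"
    a: float = 0.30
    b: float = 0.064
    c_prime: float = 0.2808
    phenotype_mean: float = 10.7
    phenotype_sd: float = 1.1

    @property
    def marginal(self) -> float:
        return self.a * self.b + self.c_prime

    @property
    def proportion_mediated(self) -> float:
        total = self.marginal
        return self.a * self.b / total if total else float("nan")


@dataclass
class GenerativeSpec:
    """Parameters of the synthetic longitudinal cohort.

    Latent structure (standardized metric): a general level factor and a
    general slope factor sit above four domain factors each, which sit above
    per-test latent intercepts/slopes.  Observed score of test *t* at wave
    *w* is intercept + slope * time_basis[w] + occasion noise, mapped to the
    test's raw scale.  Defaults reproduce the emulated study's wave spacing,
    battery moments, retention counts and predictor effect sizes.
    """

    n_individuals: int = 1091
    test_battery: list[TestSpec] = field(default_factory=default_battery)
    time_basis: tuple[float, ...] = DEFAULT_TIME_BASIS
    #: standardized loading of each domain's level / slope factor on the
    #: general factors; (0.76 * 0.8415)^2 = 0.409 and (0.92 * 0.9075)^2 =
    #: 0.697 of per-test variance sit at the general level/slope.
    general_level_loadings: dict[str, float] = field(
        default_factory=lambda: dict.fromkeys(DOMAINS, 0.8415)
    )
    general_slope_loadings: dict[str, float] = field(
        default_factory=lambda: dict.fromkeys(DOMAINS, 0.9075)
    )
    domain_level_loadings: dict[str, float] = field(default_factory=dict)  # per test
    domain_slope_loadings: dict[str, float] = field(default_factory=dict)
    default_level_loading: float = 0.76
    default_slope_loading: float = 0.92
    #: latent slope SD per test = slope_sd_ratio * baseline SD (per year)
    slope_sd_ratio: float = 0.045
    #: share of baseline raw variance carried by the latent intercept
    level_reliability: float = 0.85
    level_slope_corr: float = 0.30
    test_is_resid_corr: float = 0.0
    predictor_effects: dict[str, PredictorEffect] = field(
        default_factory=default_predictor_effects
    )
    mediation: MediationSpec | None = field(default_factory=MediationSpec)
    age11_loading: float = 0.814
    apoe_frequency: float = 0.30
    retention_targets: tuple[int, ...] = DEFAULT_RETENTION
    mar_strength: float = 0.6
    baseline_age_mean: float = 69.54
    baseline_age_sd: float = 0.83
    age_jitter_sd: float = 0.25
    sex_effects: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SEX_EFFECTS))
    validation_phenotypes: list[ValidationPhenotype] = field(
        default_factory=default_validation_phenotypes
    )
    seed: int = 0

    # -- derived tables ----------------------------------------------------

    @property
    def tests(self) -> list[str]:
        return [t.name for t in self.test_battery]

    @property
    def domains(self) -> list[str]:
        seen: list[str] = []
        for t in self.test_battery:
            if t.domain not in seen:
                seen.append(t.domain)
        return seen

    @property
    def fixed_slope_means(self) -> dict[str, float]:
        return {t.name: t.slope_mean for t in self.test_battery}

    @property
    def occasion_residual_sd(self) -> dict[str, float]:
        return {
            t.name: np.sqrt(1 - self.level_reliability) * t.baseline_sd
            for t in self.test_battery
        }

    def level_loading(self, test: str) -> float:
        return self.domain_level_loadings.get(test, self.default_level_loading)

    def slope_loading(self, test: str) -> float:
        return self.domain_slope_loadings.get(test, self.default_slope_loading)

    def validate(self) -> None:
        tb = np.asarray(self.time_basis, dtype=float)
        if len(tb) < 2 or tb[0] != 0 or np.any(np.diff(tb) <= 0):
            raise SpecError("time_basis must start at 0 and be strictly increasing")
        names = self.tests
        if len(set(names)) != len(names):
            raise SpecError("test names must be unique")
        for t in self.test_battery:
            if t.baseline_sd <= 0:
                raise SpecError(f"{t.name}: baseline SD must be positive")
        if not 0 < self.level_reliability <= 1:
            raise SpecError("level_reliability must lie in (0, 1]")
        if self.slope_sd_ratio < 0:
            raise SpecError("slope_sd_ratio must be non-negative")
        rt = np.asarray(self.retention_targets)
        if len(rt) != len(tb):
            raise SpecError("retention_targets must have one entry per wave")
        if np.any(np.diff(rt) > 0):
            raise SpecError("retention_targets must be non-increasing")
        if rt[0] > self.n_individuals:
            raise SpecError("first retention target exceeds cohort size")
        if not 0 < self.apoe_frequency < 1:
            raise SpecError("apoe_frequency must lie in (0, 1)")
        for d in self.domains:
            if d not in self.general_level_loadings or d not in self.general_slope_loadings:
                raise SpecError(f"missing general-factor loading for domain {d!r}")
        for name, lam in list(self.general_level_loadings.items()) + list(
            self.general_slope_loadings.items()
        ):
            if not np.isfinite(lam) or abs(lam) > 1:
                raise SpecError(f"standardized loading for {name!r} must lie in [-1, 1]")
        for t in names:
            for lam in (self.level_loading(t), self.slope_loading(t)):
                if not np.isfinite(lam) or abs(lam) > 1:
                    raise SpecError(f"standardized loading for test {t!r} out of range")
        if self.mediation is not None and self.mediation.predictor not in self.predictor_effects:
            raise SpecError(
                f"mediation predictor {self.mediation.predictor!r} not in predictor_effects"
            )
        self._factor_coefficients()  # raises SpecError on infeasible budgets

    # -- linear-map construction -------------------------------------------

    def _predictor_items(self) -> list[tuple[str, PredictorEffect]]:
        return list(self.predictor_effects.items())

    def _predictor_var(self, eff: PredictorEffect) -> float:
        if eff.binary:
            return self.apoe_frequency * (1 - self.apoe_frequency)
        return 1.0

    def _factor_coefficients(self) -> dict[str, np.ndarray]:
        """Coefficient rows of age-11, education, gL and gS over base variables.

        Base order: predictors (centered), then zeta_a, zeta_e, zeta_g,
        zeta_s.  All residual scalings are solved so each construct has unit
        variance and the target correlations (age-11 with gL; gL with gS)
        hold exactly under independent unit-variance predictors.
        """
        items = self._predictor_items()
        k = len(items)
        w = np.array([self._predictor_var(e) for _, e in items])
        ia, ie, ig, isl = k, k + 1, k + 2, k + 3
        nb = k + 4

        med = self.mediation
        beta_a = np.array([e.beta_age11 for _, e in items])
        s_a2 = 1 - float(np.sum(beta_a**2 * w))
        if s_a2 <= 0:
            raise SpecError("age-11 predictor effects exceed unit variance")
        s_a = np.sqrt(s_a2)
        age11 = np.zeros(nb)
        age11[:k] = beta_a
        age11[ia] = s_a

        edu = np.zeros(nb)
        if med is not None:
            j_med = [i for i, (n, _) in enumerate(items) if n == med.predictor][0]
            s_e2 = 1 - med.a**2 * w[j_med]
            if s_e2 <= 0:
                raise SpecError("mediation path a exceeds unit variance")
            edu[j_med] = med.a
            edu[ie] = np.sqrt(s_e2)

        marg = np.array([e.beta_level for _, e in items])
        if med is not None:
            marg[j_med] = med.marginal
        gl = np.zeros(nb)
        gl[:k] = marg
        if med is not None:
            # replace the mediated predictor's direct coefficient and add the
            # mediator channel; total on the predictor stays c' + a*b = marginal
            gl[ie] = med.b * edu[ie]
        cov_gl_a = float(np.sum(marg * beta_a * w))
        phi = (self.age11_loading - cov_gl_a) / s_a2
        gl[ia] = phi * s_a
        used = float(np.sum(marg**2 * w)) + gl[ie] ** 2 + gl[ia] ** 2
        if used >= 1:
            raise SpecError("general-level effect budget exceeds unit variance")
        gl[ig] = np.sqrt(1 - used)

        beta_s = np.array([e.beta_slope for _, e in items])
        s_s2 = 1 - float(np.sum(beta_s**2 * w))
        if s_s2 <= 0:
            raise SpecError("general-slope predictor effects exceed unit variance")
        s_s = np.sqrt(s_s2)
        cov_ls = float(np.sum(marg * beta_s * w))
        rho = (self.level_slope_corr - cov_ls) / (gl[ig] * s_s)
        if abs(rho) >= 1:
            raise SpecError("level-slope correlation target infeasible")
        gs = np.zeros(nb)
        gs[:k] = beta_s
        gs[ig] = s_s * rho
        gs[isl] = s_s * np.sqrt(1 - rho**2)
        return {"age11": age11, "edu": edu, "g_level": gl, "g_slope": gs, "weights": w}

    def _linear_map(self) -> dict:
        """Full coefficient system of the observed scores over base variables.

        Base order: predictors, zeta_a, zeta_e, zeta_g, zeta_s, u_d (level
        domain residuals), v_d (slope domain residuals), e_t (level test
        residuals), f_t (slope test residuals), sex (centered), baseline age
        (centered).  Occasion noise and age jitter stay diagonal.
        """
        core = self._factor_coefficients()
        items = self._predictor_items()
        k = len(items)
        domains = self.domains
        nd = len(domains)
        tests = self.test_battery
        nt = len(tests)
        n_core = k + 4
        iu = n_core
        iv = iu + nd
        ie_t = iv + nd
        if_t = ie_t + nt
        isex = if_t + nt
        iage = isex + 1
        nb = iage + 1

        base_var = np.ones(nb)
        base_var[:k] = core["weights"]
        base_var[isex] = 0.25
        base_var[iage] = self.baseline_age_sd**2

        def pad(row: np.ndarray) -> np.ndarray:
            out = np.zeros(nb)
            out[:n_core] = row
            return out

        g_level = pad(core["g_level"])
        g_slope = pad(core["g_slope"])

        dom_level = {}
        dom_slope = {}
        for d_i, d in enumerate(domains):
            lam = self.general_level_loadings[d]
            row = lam * g_level
            row[iu + d_i] = np.sqrt(1 - lam**2)
            dom_level[d] = row
            lam_s = self.general_slope_loadings[d]
            row_s = lam_s * g_slope
            row_s[iv + d_i] = np.sqrt(1 - lam_s**2)
            dom_slope[d] = row_s

        c = self.test_is_resid_corr
        intercept_rows = np.zeros((nt, nb))
        slope_rows = np.zeros((nt, nb))
        for t_i, t in enumerate(tests):
            a_l = self.level_loading(t.name)
            a_s = self.slope_loading(t.name)
            row_i = a_l * dom_level[t.domain]
            row_i[ie_t + t_i] = np.sqrt(1 - a_l**2)
            row_s = a_s * dom_slope[t.domain]
            res = np.sqrt(1 - a_s**2)
            row_s[ie_t + t_i] = res * c
            row_s[if_t + t_i] = res * np.sqrt(1 - c**2)
            sd_i = np.sqrt(self.level_reliability) * t.baseline_sd
            sd_s = self.slope_sd_ratio * t.baseline_sd
            intercept_rows[t_i] = sd_i * row_i
            slope_rows[t_i] = sd_s * row_s

        tb = np.asarray(self.time_basis)
        nw = len(tb)
        obs_rows = np.zeros((nt * nw, nb))
        obs_mean = np.zeros(nt * nw)
        obs_diag = np.zeros(nt * nw)
        names = []
        occ = self.occasion_residual_sd
        for t_i, t in enumerate(tests):
            sex_eff = self.sex_effects.get(t.name, 0.0) * t.baseline_sd
            for w_i in range(nw):
                r = t_i * nw + w_i
                row = intercept_rows[t_i] + tb[w_i] * slope_rows[t_i]
                row[isex] += sex_eff
                row[iage] += t.slope_mean  # cross-sectional entry-age effect
                obs_rows[r] = row
                obs_mean[r] = t.baseline_mean + t.slope_mean * tb[w_i] + 0.5 * sex_eff
                obs_diag[r] = occ[t.name] ** 2 + (t.slope_mean * self.age_jitter_sd) ** 2
                names.append(f"{t.name}_w{w_i + 1}")
        return {
            "core": core,
            "obs_rows": obs_rows,
            "obs_mean": obs_mean,
            "obs_diag": obs_diag,
            "obs_names": names,
            "base_var": base_var,
            "index": {
                "k": k,
                "ia": k,
                "ie": k + 1,
                "ig": k + 2,
                "is": k + 3,
                "iu": iu,
                "iv": iv,
                "ie_t": ie_t,
                "if_t": if_t,
                "isex": isex,
                "iage": iage,
                "nb": nb,
            },
            "intercept_rows": intercept_rows,
            "slope_rows": slope_rows,
            "dom_level": dom_level,
            "dom_slope": dom_slope,
        }

    def implied_moments(self) -> tuple[np.ndarray, np.ndarray, list[str]]:
        """Population mean and covariance of complete data (analysis scale).

        Exact under the idealized base distribution (independent
        unit-variance predictor scores); in-sample standardization of
        supplied true scores makes generated data match to O(1/sqrt(n)).
        """
        lm = self._linear_map()
        C = lm["obs_rows"]
        w = lm["base_var"]
        cov = (C * w) @ C.T + np.diag(lm["obs_diag"])
        return lm["obs_mean"].copy(), cov, list(lm["obs_names"])


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------


def simulate_cohort(
    spec: GenerativeSpec,
    genotypes: GenotypeMatrix | None = None,
    pgs_truth: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Generate one complete-then-thinned longitudinal cohort.

    ``pgs_truth`` maps continuous predictor names to per-person true genetic
    scores (e.g. from :func:`simulate_trait_architecture`); predictors not
    supplied are drawn as independent standard normals.  Binary predictors
    (the APOE-like indicator) are always drawn as Bernoulli.  True latent
    factor values are retained in ``true_*`` columns for recovery testing.
    Dropout is applied according to the spec's retention targets.
    """
    spec.validate()
    n = spec.n_individuals
    rng = np.random.default_rng(spec.seed)
    lm = spec._linear_map()
    idx = lm["index"]
    k = idx["k"]
    items = spec._predictor_items()

    base = np.empty((n, idx["nb"]))
    predictor_cols: dict[str, np.ndarray] = {}
    for j, (name, eff) in enumerate(items):
        if eff.binary:
            x = (rng.random(n) < spec.apoe_frequency).astype(float)
            base[:, j] = x - spec.apoe_frequency
        else:
            if pgs_truth is not None and name in pgs_truth:
                x = np.asarray(pgs_truth[name], dtype=float)
                if len(x) != n:
                    raise SpecError(f"pgs_truth[{name!r}] has wrong length")
                sd = x.std()
                x = (x - x.mean()) / (sd if sd > 0 else 1.0)
            else:
                x = rng.standard_normal(n)
            base[:, j] = x
        predictor_cols[name] = x
    if pgs_truth is not None:
        unknown = set(pgs_truth) - {name for name, _ in items}
        if unknown:
            raise SpecError(f"pgs_truth names not in predictor_effects: {sorted(unknown)}")

    base[:, k:] = rng.standard_normal((n, idx["nb"] - k))
    sex = (rng.random(n) < 0.5).astype(float)  # 1 = female
    base[:, idx["isex"]] = sex - 0.5
    age_base = spec.baseline_age_mean + spec.baseline_age_sd * rng.standard_normal(n)
    base[:, idx["iage"]] = age_base - spec.baseline_age_mean

    core = lm["core"]
    g_level = base[:, : k + 4] @ core["g_level"][: k + 4]
    # pad core rows onto the full base (they only use the first k+4 slots)
    g_slope = base[:, : k + 4] @ core["g_slope"][: k + 4]
    age11 = base[:, : k + 4] @ core["age11"][: k + 4]
    edu_std = base[:, : k + 4] @ core["edu"][: k + 4]

    scores = lm["obs_mean"] + base @ lm["obs_rows"].T
    scores += rng.standard_normal(scores.shape) * np.sqrt(lm["obs_diag"])

    tb = np.asarray(spec.time_basis)
    nw = len(tb)
    data: dict[str, np.ndarray] = {
        "person_id": np.array([f"P{i + 1:05d}" for i in range(n)]),
        "sex": sex,
    }
    # ancestry (multidimensional-scaling) components: supplied as covariates
    # only; no stratification structure is simulated
    for j in range(4):
        data[f"mds{j + 1}"] = rng.standard_normal(n)
    for w_i in range(nw):
        jitter = spec.age_jitter_sd * rng.standard_normal(n) if w_i else np.zeros(n)
        age_years = age_base + tb[w_i] + jitter
        data[f"age_days_w{w_i + 1}"] = np.round(age_years * 365.25)

    for t_i, t in enumerate(spec.test_battery):
        for w_i in range(nw):
            col = scores[:, t_i * nw + w_i]
            if t.reversed:
                col = 2 * t.baseline_mean - col
            data[f"{t.name}_w{w_i + 1}"] = col

    data["age11"] = age11
    med = spec.mediation
    if med is not None:
        data["years_education"] = med.phenotype_mean + med.phenotype_sd * edu_std

    for name, x in predictor_cols.items():
        data[name] = x

    data["true_g_level"] = g_level
    data["true_g_slope"] = g_slope
    dl = lm["dom_level"]
    ds = lm["dom_slope"]
    for d in spec.domains:
        data[f"true_level_{d}"] = base[:, : idx["nb"]] @ dl[d]
        data[f"true_slope_{d}"] = base[:, : idx["nb"]] @ ds[d]

    _add_validation_phenotypes(data, spec, predictor_cols, sex, age_base, rng)
    cohort = pd.DataFrame(data)
    cohort = apply_dropout(
        cohort,
        spec.retention_targets,
        spec.mar_strength,
        seed=int(rng.integers(2**31 - 1)),
        battery=spec.test_battery,
    )
    return cohort


def _add_validation_phenotypes(data, spec, predictor_cols, sex, age_base, rng):
    for ph in spec.validation_phenotypes:
        if ph.source not in predictor_cols:
            continue
        z = predictor_cols[ph.source]
        zc = z - z.mean()
        if ph.kind == "continuous":
            latent = ph.coef * zc + np.sqrt(max(1 - ph.coef**2, 0)) * rng.standard_normal(len(z))
            data[ph.name] = ph.mean + ph.sd * latent + ph.sex_effect * sex
        elif ph.kind == "binary":
            intercept = np.log(ph.prevalence / (1 - ph.prevalence))
            eta = intercept + ph.coef * zc
            data[ph.name] = (rng.random(len(z)) < 1 / (1 + np.exp(-eta))).astype(float)
        elif ph.kind == "ordinal":
            latent = ph.coef * zc + np.sqrt(max(1 - ph.coef**2, 0)) * rng.standard_normal(len(z))
            cuts = stats.norm.ppf(np.cumsum(ph.cut_probs)[:-1])
            data[ph.name] = np.searchsorted(cuts, latent).astype(float)
        else:  # pragma: no cover - guarded by dataclass construction
            raise SpecError(f"unknown validation phenotype kind {ph.kind!r}")


# ---------------------------------------------------------------------------
# Dropout
# ---------------------------------------------------------------------------


def analysis_scale(cohort: pd.DataFrame, battery: list[TestSpec]) -> pd.DataFrame:
    """Return a copy with reversed (time-like) tests flipped to higher=better.

    The flip mirrors the stored value around the test's baseline mean, so
    raw units and means stay interpretable; a second application undoes it.
    """
    out = cohort.copy()
    for t in battery:
        if not t.reversed:
            continue
        for col in out.columns:
            if col.startswith(f"{t.name}_w"):
                out[col] = 2 * t.baseline_mean - out[col]
    return out


def general_composite(
    cohort: pd.DataFrame, battery: list[TestSpec], wave: int
) -> pd.Series:
    """Mean of the battery's standardized scores at one wave (analysis scale).

    Each test is standardized by its observed wave-1 mean and SD, so the
    composite is on a baseline-SD metric and comparable across waves.
    """
    frame = analysis_scale(cohort, battery)
    cols = []
    for t in battery:
        base = frame[f"{t.name}_w1"]
        mu, sd = base.mean(), base.std()
        cols.append((frame[f"{t.name}_w{wave}"] - mu) / (sd if sd > 0 else 1.0))
    return pd.concat(cols, axis=1).mean(axis=1)


def apply_dropout(
    cohort: pd.DataFrame,
    retention_targets: tuple[int, ...],
    mar_strength: float,
    seed: int,
    battery: list[TestSpec] | None = None,
) -> pd.DataFrame:
    """Impose monotone, score-dependent (MAR) dropout with exact wave counts.

    At each wave after the first, the retained subset is drawn without
    replacement from the previous wave's attendees with selection weights
    exp(mar_strength * z), where z is the person's standardized
    previous-wave general composite — attrition depends only on *observed*
    scores, so FIML's missing-at-random assumption holds by construction.
    Scores and ages at unattended waves are set to missing; nobody re-enters.
    """
    targets = np.asarray(retention_targets, dtype=int)
    if np.any(np.diff(targets) > 0):
        raise ParameterError("retention_targets must be non-increasing")
    n = len(cohort)
    if targets[0] > n:
        raise ParameterError("first retention target exceeds cohort size")
    if battery is None:
        battery = default_battery()
    rng = np.random.default_rng(seed)
    out = cohort.copy()
    tests = [t.name for t in battery]
    nw = len(targets)

    attending = np.zeros((n, nw), dtype=bool)
    current = rng.choice(n, size=targets[0], replace=False) if targets[0] < n else np.arange(n)
    attending[current, 0] = True
    for w in range(1, nw):
        comp = general_composite(out, battery, w).to_numpy()
        z = comp[current]
        z = (z - np.nanmean(z)) / (np.nanstd(z) or 1.0)
        weights = np.exp(mar_strength * z)
        weights /= weights.sum()
        keep = rng.choice(len(current), size=targets[w], replace=False, p=weights)
        current = np.sort(current[keep])
        attending[current, w] = True

    for w in range(nw):
        gone = ~attending[:, w]
        for t in tests:
            out.loc[gone, f"{t}_w{w + 1}"] = np.nan
        out.loc[gone, f"age_days_w{w + 1}"] = np.nan
    return out


# ---------------------------------------------------------------------------
# PGS battery with factor structure (for parallel-analysis experiments)
# ---------------------------------------------------------------------------


def simulate_pgs_battery(
    n: int,
    n_scores: int = 14,
    n_factors: int = 4,
    loading: float = 0.6,
    seed: int = 0,
) -> pd.DataFrame:
    """Score battery whose columns load on a few orthogonal factors.

    Scores are assigned to factors round-robin; each equals ``loading`` times
    its factor plus independent noise, giving within-cluster correlations of
    ``loading**2``.  Used to probe factor-retention behaviour.
    """
    if n_factors < 1 or n_scores < n_factors:
        raise ParameterError("need at least one score per factor")
    rng = np.random.default_rng(seed)
    factors = rng.standard_normal((n, n_factors))
    resid = np.sqrt(1 - loading**2)
    cols = {}
    for j in range(n_scores):
        f = j % n_factors
        cols[f"score_{j + 1}"] = loading * factors[:, f] + resid * rng.standard_normal(n)
    return pd.DataFrame(cols)
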