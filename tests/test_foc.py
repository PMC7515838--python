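"""Factors-of-curves model: structure, fitting, decomposition, scores."""

import numpy as np
import pandas as pd
import pytest

from cogslope.errors import ConvergenceError, IdentificationError, StructuralError
from cogslope.sem.fiml import PatternData, fit_sem, saturated_moments
from cogslope.sem.foc import (
    FoCModelSpec,
    build_foc_model,
    count_free_parameters,
    factor_scores,
    fit_foc,
    prepare_matrices,
    residualize_scores,
    standardized_loadings,
    variance_decomposition,
)
from cogslope.sem.indices import fit_indices
from cogslope.sem.univariate import fit_univariate_lgc
from cogslope.simulate import analysis_scale, simulate_cohort

from conftest import small_spec


@pytest.fixture(scope="module")
def fitted_small(small_cohort_mod):
    spec, coh, frame = small_cohort_mod
    fspec = FoCModelSpec.from_generative(spec)
    fitted = fit_foc(frame, fspec, n_starts=2, seed=0)
    assert fitted.converged
    return spec, frame, fspec, fitted


@pytest.fixture(scope="module")
def small_cohort_mod():
    spec = small_spec(n=600, seed=23)
    coh = simulate_cohort(spec)
    resid = residualize_scores(coh, spec.test_battery)
    frame = pd.concat([resid, coh.drop(columns=resid.columns)], axis=1)
    return spec, coh, frame


class TestBuildFocModel:
    def test_slope_loadings_fixed_to_time_basis(self):
        spec = FoCModelSpec.from_generative(small_spec())
        model = build_foc_model(spec)
        tb = spec.time_basis
        for t in spec.tests:
            i_s = model.var_names.index(f"S_{t}")
            i_i = model.var_names.index(f"I_{t}")
            for w, tw in enumerate(tb):
                i_y = model.var_names.index(f"{t}_w{w + 1}")
                assert model.A0[i_y, i_s] == tw
                assert model.A0[i_y, i_i] == 1.0

    def test_default_time_basis_matches_wave_spacing(self):
        spec = FoCModelSpec.from_generative(small_spec())
        assert spec.time_basis == (0.0, 2.98, 6.71, 9.78)

    def test_free_parameter_count_matches_enumeration_oracle(self):
        for kwargs in (
            {},
            {"test_is_cov": False},
            {"level_slope_cov": False},
            {"level_predictors": ["x1", "x2"], "slope_predictors": ["x1"]},
        ):
            spec = FoCModelSpec.from_generative(small_spec(), **kwargs)
            model = build_foc_model(spec)
            assert model.n_free == count_free_parameters(spec)

    def test_observed_moment_count_identity(self, fitted_small):
        *_, fitted = fitted_small
        p = fitted.model.ny
        assert p == len(fitted.spec.tests) * 4
        # df = p(p+3)/2 - free parameters
        assert fitted.fit.df == p * (p + 3) // 2 - fitted.model.n_free

    def test_single_test_domain_rejected(self):
        spec = FoCModelSpec(
            tests=["a", "b", "c"],
            domains={"a": "d1", "b": "d1", "c": "d2"},
        )
        with pytest.raises(IdentificationError):
            build_foc_model(spec)


class TestResidualize:
    def test_residuals_orthogonal_to_age_and_sex(self, small_cohort_mod):
        spec, coh, frame = small_cohort_mod
        for col in ("puzzles_w1", "coding_w3"):
            w = col.split("_w")[1]
            sub = pd.DataFrame(
                {
                    "r": frame[col],
                    "age": coh[f"age_days_w{w}"],
                    "sex": coh["sex"],
                }
            ).dropna()
            assert abs(np.corrcoef(sub["r"], sub["age"])[0, 1]) < 1e-10
            assert abs(np.corrcoef(sub["r"], sub["sex"])[0, 1]) < 1e-10

    def test_orthogonal_covariates_give_centred_scores(self):
        rng = np.random.default_rng(0)
        n = 400
        spec = small_spec(n=n, seed=31, retention_targets=(n,) * 4)
        coh = simulate_cohort(spec)
        # overwrite one score column with data exactly orthogonal to age and sex
        z = rng.standard_normal(n) * 3
        X = np.column_stack([np.ones(n), coh["age_days_w2"], coh["sex"]])
        z -= X @ np.linalg.lstsq(X, z, rcond=None)[0]
        coh["vocab_w2"] = z + 10
        resid = residualize_scores(coh, spec.test_battery)
        assert np.allclose(resid["vocab_w2"], z, atol=1e-8)
        assert abs(resid["vocab_w2"].mean()) < 1e-8

    def test_reversed_test_declines_after_reversal(self):
        spec = small_spec(n=800, seed=37, retention_targets=(800,) * 4)
        coh = simulate_cohort(spec)
        # raw reaction times worsen (rise); the reversed analysis scale falls
        raw_means = [coh[f"reaction_w{w}"].mean() for w in (1, 4)]
        assert raw_means[1] > raw_means[0]
        ana = analysis_scale(coh, spec.test_battery)
        ana_means = [ana[f"reaction_w{w}"].mean() for w in (1, 4)]
        assert ana_means[1] < ana_means[0]

    def test_missing_stays_missing(self, small_cohort_mod):
        spec, coh, frame = small_cohort_mod
        assert frame["puzzles_w4"].isna().equals(coh["puzzles_w4"].isna())

    def test_entirely_missing_column_rejected(self, small_cohort_mod):
        spec, coh, _ = small_cohort_mod
        broken = coh.copy()
        broken["vocab_w3"] = np.nan
        with pytest.raises(StructuralError):
            residualize_scores(broken, spec.test_battery)


class TestFitFoc:
    def test_refit_from_solution_is_stationary(self, fitted_small):
        spec, frame, fspec, fitted = fitted_small
        y, x, _, _ = prepare_matrices(frame, fspec)
        refit = fit_sem(
            fitted.model, y, x, start=fitted.fit.theta, n_starts=1, compute_se=False
        )
        assert refit.loglik == pytest.approx(fitted.fit.loglik, abs=1e-6)

    def test_model_loglik_below_saturated(self, fitted_small):
        *_, fitted = fitted_small
        _, _, ll_sat = saturated_moments(fitted.fit.data)
        assert fitted.fit.loglik <= ll_sat + 1e-6

    def test_standardized_loadings_near_truth(self, fitted_small):
        spec, _, _, fitted = fitted_small
        lo = standardized_loadings(fitted)
        assert lo["level_test_loading"].mean() == pytest.approx(0.76, abs=0.06)
        assert lo["slope_test_loading"].mean() == pytest.approx(0.92, abs=0.06)


class TestFitIndices:
    def test_saturated_comparison_yields_perfect_fit(self):
        """Refitting the saturated moments as a 'model' gives chi-square 0,
        CFI 1 and RMSEA 0 by construction."""
        rng = np.random.default_rng(1)
        y = rng.standard_normal((150, 3)) @ np.diag([1.0, 1.5, 0.7])
        y[:40, 2] = np.nan
        from cogslope.sem.model import ModelBuilder

        b = ModelBuilder()
        for j in range(3):
            b.add_variable(f"y{j}")
            b.free_mean(f"y{j}", f"m{j}")
            b.free_var(f"y{j}", f"v{j}")
        for j in range(3):
            for i in range(j):
                b.free_cov(f"y{i}", f"y{j}", f"c{i}{j}")
        model = b.build()
        fit = fit_sem(model, y, n_starts=1, compute_se=False)
        ind = fit_indices(fit)
        assert ind.chisq == pytest.approx(0.0, abs=1e-4)
        assert ind.cfi == pytest.approx(1.0, abs=1e-6)
        assert ind.rmsea == pytest.approx(0.0, abs=1e-6)
        assert ind.df == 0

    def test_independence_model_has_cfi_zero(self):
        rng = np.random.default_rng(2)
        f = rng.standard_normal((200, 1))
        y = f @ np.ones((1, 3)) + rng.standard_normal((200, 3))
        from cogslope.sem.model import ModelBuilder

        b = ModelBuilder()
        for j in range(3):
            b.add_variable(f"y{j}")
            b.free_mean(f"y{j}", f"m{j}")
            b.free_var(f"y{j}", f"v{j}")
        model = b.build()
        fit = fit_sem(model, y, n_starts=1, compute_se=False)
        ind = fit_indices(fit)
        assert ind.cfi == pytest.approx(0.0, abs=1e-6)

    def test_rmsea_zero_when_chisq_at_most_df(self):
        # formula boundary: chi-square exactly equal to df
        assert np.sqrt(max(100.0 - 100, 0) / (100 * 500)) == 0.0


class TestVarianceDecomposition:
    def test_shares_sum_to_one(self, fitted_small):
        *_, fitted = fitted_small
        dec = variance_decomposition(fitted)
        totals = dec[["general_share", "domain_share", "unique_share"]].sum(axis=1)
        assert np.allclose(totals, 1.0, atol=1e-6)

    def test_hand_computed_product_rule(self):
        # standardized test loading 0.8, domain loading 0.5
        assert (0.8 * 0.5) ** 2 == pytest.approx(0.16)
        # domain-on-general loading 0 kills the general share
        assert (0.8 * 0.0) ** 2 == 0.0
        # perfect hierarchy: both loadings 1 -> share 1
        assert (1.0 * 1.0) ** 2 == 1.0

    def test_refuses_nonconverged_fit(self, fitted_small):
        *_, fitted = fitted_small
        import dataclasses

        broken_fit = dataclasses.replace(fitted.fit, converged=False)
        broken = dataclasses.replace(fitted, fit=broken_fit)
        with pytest.raises(ConvergenceError):
            variance_decomposition(broken)


class TestFactorScores:
    def test_complete_data_matches_closed_form_oracle(self, fitted_small):
        spec, frame, fspec, fitted = fitted_small
        scores = factor_scores(fitted, frame)
        imp = fitted.model.implied(fitted.fit.theta, full=True)
        lat = [fitted.model.var_names.index("gL"), fitted.model.var_names.index("gS")]
        obs_v = fitted.model.obs
        K = imp.sigma_v[np.ix_(lat, obs_v)] @ np.linalg.inv(imp.sigma_y)
        y, _, _, rows = prepare_matrices(frame, fspec)
        complete = ~np.isnan(y).any(axis=1)
        expected = (y[complete] - imp.mu_y) @ K.T
        got = scores.loc[rows[complete], ["g_level_score", "g_slope_score"]].to_numpy()
        assert np.allclose(got, expected, atol=1e-8)

    def test_linearity_in_observed_deviations(self, fitted_small):
        spec, frame, fspec, fitted = fitted_small
        cols = fspec.observed_columns
        scores1 = factor_scores(fitted, frame)
        doubled = frame.copy()
        y, _, scale, _ = prepare_matrices(frame, fspec)
        mu_scaled = fitted.model.implied(fitted.fit.theta).mu_y
        for j, c in enumerate(cols):
            t = c.rsplit("_w", 1)[0]
            mu_raw = mu_scaled[j] * scale[t]
            doubled[c] = mu_raw + 2 * (frame[c] - mu_raw)
        scores2 = factor_scores(fitted, doubled)
        d1 = scores1["g_level_score"] - scores1["g_level_score"].mean()
        d2 = scores2["g_level_score"] - scores2["g_level_score"].mean()
        ok = d1.notna()
        assert np.allclose(d2[ok], 2 * d1[ok], atol=1e-6)

    def test_scores_beat_any_single_indicator(self, fitted_small):
        spec, frame, fspec, fitted = fitted_small
        scores = factor_scores(fitted, frame)
        truth = frame["true_g_level"]
        ok = scores["g_level_score"].notna()
        r_score = np.corrcoef(scores.loc[ok, "g_level_score"], truth[ok])[0, 1]
        for t in spec.tests:
            r_test = np.corrcoef(frame.loc[ok, f"{t}_w1"], truth[ok])[0, 1]
            assert r_score > abs(r_test)

    def test_all_missing_person_gets_missing_score(self, fitted_small):
        spec, frame, fspec, fitted = fitted_small
        broken = frame.copy()
        cols = fspec.observed_columns
        broken.loc[broken.index[0], cols] = np.nan
        scores = factor_scores(fitted, broken)
        assert scores.iloc[0].isna().all()


class TestUnivariateLgc:
    TB = (0.0, 3.0, 6.0, 9.0)

    def test_exact_on_noiseless_linear_trajectories(self):
        rng = np.random.default_rng(3)
        n = 200
        icept = rng.normal(10, 2, n)
        slope = np.full(n, -0.1)
        y = icept[:, None] + np.outer(slope, self.TB) + rng.standard_normal((n, 4)) * 1e-4
        g = fit_univariate_lgc(y, self.TB, compute_se=False)
        assert g.mean_slope == pytest.approx(-0.1, abs=1e-3)

    def test_flat_trajectories_give_zero_slope(self):
        rng = np.random.default_rng(4)
        y = np.tile(rng.normal(5, 1, 100)[:, None], (1, 4)) + rng.standard_normal((100, 4)) * 1e-4
        g = fit_univariate_lgc(y, self.TB, compute_se=False)
        assert g.mean_slope == pytest.approx(0.0, abs=1e-3)

    def test_recovers_default_block_design_slope(self):
        """The generator's Block-Design-like default (-0.423/year) is
        recovered from a complete synthetic cohort within Monte-Carlo error."""
        from cogslope.simulate import GenerativeSpec

        spec = GenerativeSpec(n_individuals=2000, retention_targets=(2000,) * 4, seed=17)
        frame = analysis_scale(simulate_cohort(spec), spec.test_battery)
        y = frame[[f"block_design_w{w}" for w in (1, 2, 3, 4)]].to_numpy()
        g = fit_univariate_lgc(y, spec.time_basis)
        assert g.mean_slope == pytest.approx(-0.423, abs=3 * g.slope_se)

    def test_too_few_waves_rejected(self):
        with pytest.raises(IdentificationError):
            fit_univariate_lgc(np.zeros((10, 2)), (0.0, 1.0))
        y = np.full((10, 4), np.nan)
        y[:, :2] = 1.0
        with pytest.raises(IdentificationError):
            fit_univariate_lgc(y, self.TB)
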