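"""Association, mediation, FDR and dependent-correlation comparisons."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from cogslope.association import (
    _factor_score_results,
    apoe_adjusted_association,
    fdr_adjust,
    lifetime_change_association,
    mediation_from_moments,
    simultaneous_association,
    single_predictor_association,
    williams_test,
)
from cogslope.battery import PredictorEffect
from cogslope.errors import ParameterError
from cogslope.sem.foc import FoCModelSpec, fit_foc, residualize_scores
from cogslope.simulate import simulate_cohort

from conftest import small_spec


def prepared(spec):
    coh = simulate_cohort(spec)
    resid = residualize_scores(coh, spec.test_battery)
    return pd.concat([resid, coh.drop(columns=resid.columns)], axis=1)


@pytest.fixture(scope="module")
def assoc_setup():
    spec = small_spec(n=600, seed=41)
    frame = prepared(spec)
    fspec = FoCModelSpec.from_generative(spec)
    baseline = fit_foc(frame, fspec, n_starts=2, seed=0)
    return spec, frame, fspec, baseline


class TestSinglePredictor:
    def test_rescaling_leaves_standardized_beta_unchanged(self, assoc_setup):
        spec, frame, fspec, baseline = assoc_setup
        r1 = single_predictor_association(frame, fspec, "pgs_education", baseline=baseline)
        rescaled = frame.assign(pgs_education=frame["pgs_education"] * 10)
        r2 = single_predictor_association(rescaled, fspec, "pgs_education", baseline=baseline)
        for a, b in zip(r1, r2):
            assert a.beta == pytest.approx(b.beta, abs=1e-6)
            assert a.se == pytest.approx(b.se, rel=1e-4)

    def test_level_effect_recovered(self, assoc_setup):
        spec, frame, fspec, baseline = assoc_setup
        res = single_predictor_association(frame, fspec, "pgs_education", baseline=baseline)
        level = next(r for r in res if r.outcome == "level")
        assert level.beta == pytest.approx(0.30, abs=3 * level.se)
        assert level.method == "sem"

    def test_null_predictor_small_effect(self, assoc_setup):
        spec, frame, fspec, baseline = assoc_setup
        res = single_predictor_association(frame, fspec, "pgs_noise", baseline=baseline)
        for r in res:
            assert abs(r.beta) < 3 * r.se

    def test_constant_predictor_refused(self, assoc_setup):
        spec, frame, fspec, baseline = assoc_setup
        bad = frame.assign(pgs_noise=1.0)
        with pytest.raises(ParameterError):
            single_predictor_association(bad, fspec, "pgs_noise", baseline=baseline)

    def test_sem_and_factor_score_paths_agree(self, assoc_setup):
        spec, frame, fspec, baseline = assoc_setup
        sem_res = single_predictor_association(frame, fspec, "pgs_education", baseline=baseline)
        fs_res = _factor_score_results(
            baseline, frame.assign(
                pgs_education=(frame.pgs_education - frame.pgs_education.mean())
                / frame.pgs_education.std()
            ),
            ["pgs_education"], ("mds1", "mds2", "mds3", "mds4"),
        )
        for s, f in zip(sem_res, fs_res):
            assert s.beta == pytest.approx(f.beta, abs=2 * max(s.se, f.se))
            assert f.method == "factor_score_regression"


class TestApoeAdjusted:
    def test_orthogonal_apoe_leaves_beta_similar(self, assoc_setup):
        spec, frame, fspec, baseline = assoc_setup
        solo = single_predictor_association(frame, fspec, "pgs_education", baseline=baseline)
        adj = apoe_adjusted_association(frame, fspec, "pgs_education", baseline=baseline)
        solo_level = next(r for r in solo if r.outcome == "level")
        adj_level = next(
            r for r in adj if r.outcome == "level" and r.predictor == "pgs_education"
        )
        assert adj_level.beta == pytest.approx(solo_level.beta, abs=2 * solo_level.se)

    def test_apoe_coefficient_matches_own_model_when_other_is_noise(self, assoc_setup):
        spec, frame, fspec, baseline = assoc_setup
        solo = single_predictor_association(frame, fspec, "apoe_e4", baseline=baseline)
        adj = apoe_adjusted_association(frame, fspec, "pgs_noise", baseline=baseline)
        for outcome in ("level", "slope"):
            b_solo = next(r for r in solo if r.outcome == outcome)
            b_adj = next(
                r for r in adj if r.outcome == outcome and r.predictor == "apoe_e4"
            )
            assert b_adj.beta == pytest.approx(b_solo.beta, abs=1.0 * b_solo.se)

    def test_confounded_predictor_attenuates(self):
        """A predictor correlated (r=0.5) with the causal one, itself null,
        shows a marginal effect that the joint model pushes back toward 0 —
        matching the closed-form two-variable OLS attenuation oracle."""
        spec = small_spec(
            n=2500,
            seed=43,
            retention_targets=(2500, 2000, 1700, 1400),
            predictor_effects={
                "pgs_causal": PredictorEffect(0.3, 0.0, 0.0),
                "pgs_proxy": PredictorEffect(0.0, 0.0, 0.0),
                "apoe_e4": PredictorEffect(0.0, 0.0, 0.0, binary=True),
            },
            mediation=None,
        )
        rng = np.random.default_rng(44)
        x1 = rng.standard_normal(2500)
        x2 = 0.5 * x1 + np.sqrt(0.75) * rng.standard_normal(2500)
        coh = simulate_cohort(spec, pgs_truth={"pgs_causal": x1, "pgs_proxy": x2})
        resid = residualize_scores(coh, spec.test_battery)
        frame = pd.concat([resid, coh.drop(columns=resid.columns)], axis=1)
        fspec = FoCModelSpec.from_generative(spec)
        baseline = fit_foc(frame, fspec, n_starts=2, seed=0)
        solo = single_predictor_association(frame, fspec, "pgs_proxy", baseline=baseline)
        marg = next(r for r in solo if r.outcome == "level")
        joint = simultaneous_association(
            frame, fspec, ["pgs_causal", "pgs_proxy"], baseline=baseline
        )
        cond = next(
            r for r in joint if r.predictor == "pgs_proxy" and r.outcome == "level"
        )
        # population oracle: marginal 0.15, conditional exactly 0
        oracle = np.linalg.solve(np.array([[1, 0.5], [0.5, 1]]), np.array([0.3, 0.15]))
        assert marg.beta == pytest.approx(0.15, abs=3 * marg.se)
        assert cond.beta == pytest.approx(oracle[1], abs=3 * cond.se)
        assert abs(cond.beta) < abs(marg.beta)


class TestSimultaneous:
    def test_duplicated_predictor_is_collinearity_error(self, assoc_setup):
        spec, frame, fspec, baseline = assoc_setup
        dup = frame.assign(pgs_dup=frame["pgs_education"])
        with pytest.raises(ParameterError, match="collinear"):
            simultaneous_association(dup, fspec, ["pgs_education", "pgs_dup"], baseline=baseline)

    def test_needs_two_predictors(self, assoc_setup):
        spec, frame, fspec, baseline = assoc_setup
        with pytest.raises(ParameterError):
            simultaneous_association(frame, fspec, ["pgs_education"], baseline=baseline)

    def test_orthogonal_predictors_match_single_models(self, assoc_setup):
        spec, frame, fspec, baseline = assoc_setup
        joint = simultaneous_association(
            frame, fspec, ["pgs_education", "pgs_noise"], baseline=baseline
        )
        solo = single_predictor_association(frame, fspec, "pgs_education", baseline=baseline)
        j = next(r for r in joint if r.predictor == "pgs_education" and r.outcome == "level")
        s = next(r for r in solo if r.outcome == "level")
        assert j.beta == pytest.approx(s.beta, abs=1.5 * s.se)


class TestLifetimeChange:
    def test_independent_predictor_null_everywhere(self, assoc_setup):
        spec, frame, fspec, baseline = assoc_setup
        res = lifetime_change_association(frame, fspec, "pgs_noise", baseline=baseline)
        for r in res:
            assert abs(r.beta) < 3 * r.se

    def test_injection_into_post_age11_residual_recovered(self):
        """A predictor with a pure level effect and no age-11 path keeps its
        full conditional effect and shows no age-11 association."""
        spec = small_spec(
            n=2000,
            seed=47,
            retention_targets=(2000, 1600, 1300, 1000),
            predictor_effects={
                "pgs_late": PredictorEffect(0.25, 0.0, 0.0),
                "apoe_e4": PredictorEffect(0.0, 0.0, 0.0, binary=True),
            },
            mediation=None,
        )
        frame = prepared(spec)
        fspec = FoCModelSpec.from_generative(spec)
        baseline = fit_foc(frame, fspec, n_starts=2, seed=0)
        res = lifetime_change_association(frame, fspec, "pgs_late", baseline=baseline)
        cond = next(r for r in res if r.outcome == "lifetime_change")
        marg11 = next(r for r in res if r.outcome == "age11")
        assert cond.beta == pytest.approx(0.25, abs=3 * cond.se)
        assert abs(marg11.beta) < 3 * marg11.se

    def test_age11_generating_link_recovered(self, assoc_setup):
        spec, frame, fspec, baseline = assoc_setup
        # the generating standardized age-11 -> level regression (0.814) is
        # recovered by the in-SEM conditional coefficient of age11
        from cogslope.association import _prepare_predictors, _fit_predictor_model, _sem_results

        prepped = _prepare_predictors(frame, ["age11"])
        fitted = _fit_predictor_model(
            prepped, fspec, ["age11"], (), level_only=True, seed=0, warm_start=baseline
        )
        res = _sem_results(fitted, prepped, ["age11"], (), outcomes=(("gL", "level"),))
        assert res[0].beta == pytest.approx(0.814, abs=3 * res[0].se)


class TestMediationMoments:
    def test_population_closure_exact(self):
        a, b, c = 0.3, 0.2, 0.14
        cov = np.array(
            [
                [1.0, a, a * b + c],
                [a, 1.0, b + a * c],
                [a * b + c, b + a * c, 1.0],
            ]
        )
        m = mediation_from_moments(cov, 0, 1, 2)
        assert m.a == pytest.approx(a, abs=1e-12)
        assert m.b == pytest.approx(b, abs=1e-12)
        assert m.c_prime == pytest.approx(c, abs=1e-12)
        assert m.proportion_mediated == pytest.approx(a * b / (a * b + c), abs=1e-12)
        assert m.proportion_mediated == pytest.approx(0.06 / 0.20, abs=1e-12)

    def test_full_mediation_proportion_one(self):
        a, b = 0.5, 0.4
        cov = np.array([[1, a, a * b], [a, 1, b], [a * b, b, 1]])
        m = mediation_from_moments(cov, 0, 1, 2)
        assert m.c_prime == pytest.approx(0.0, abs=1e-12)
        assert m.proportion_mediated == pytest.approx(1.0, abs=1e-9)

    def test_no_first_path_gives_zero_proportion(self):
        b, c = 0.4, 0.3
        cov = np.array([[1, 0, c], [0, 1, b], [c, b, 1]])
        m = mediation_from_moments(cov, 0, 1, 2)
        assert m.a == pytest.approx(0.0, abs=1e-12)
        assert m.indirect == pytest.approx(0.0, abs=1e-12)
        assert m.proportion_mediated == pytest.approx(0.0, abs=1e-12)


class TestFdrAdjust:
    def test_single_p_unchanged(self):
        assert fdr_adjust([0.031])[0] == pytest.approx(0.031)

    def test_hand_computed_step_up(self):
        q = fdr_adjust([0.01, 0.02, 0.03, 0.04, 0.05])
        assert np.allclose(q, 0.05)

    @staticmethod
    def direct_step_up(p):
        """Exhaustive evaluation: q_(i) = min over j >= i of p_(j) * m / j."""
        p = np.asarray(p, dtype=float)
        m = len(p)
        order = np.argsort(p, kind="mergesort")
        q = np.empty(m)
        for rank_i, i in enumerate(order, start=1):
            q[i] = min(
                min(p[j] * m / (rank_j) for rank_j, j in enumerate(order, start=1) if rank_j >= rank_i),
                1.0,
            )
        return q

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_matches_direct_definition_on_random_inputs(self, seed):
        p = np.random.default_rng(seed).uniform(size=17)
        assert np.allclose(fdr_adjust(p), self.direct_step_up(p), atol=1e-12)

    def test_properties_q_ge_p_and_monotone(self):
        p = np.random.default_rng(1).uniform(size=40)
        q = fdr_adjust(p)
        assert np.all(q >= p - 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_agrees_with_statsmodels_cross_check(self):
        from statsmodels.stats.multitest import multipletests

        p = np.random.default_rng(5).uniform(size=25)
        assert np.allclose(fdr_adjust(p), multipletests(p, method="fdr_bh")[1], atol=1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ParameterError):
            fdr_adjust([0.5, 1.2])
        with pytest.raises(ParameterError):
            fdr_adjust([-0.1])


class TestWilliams:
    def test_equal_correlations_give_t_zero(self):
        t, df, p = williams_test(0.4, 0.4, 0.3, 50)
        assert t == 0.0
        assert p == pytest.approx(1.0)
        assert df == 47

    def test_formula_oracle(self):
        """Independently coded statement of the published formula."""

        def oracle(r12, r13, r23, n):
            detR = 1 - r12**2 - r13**2 - r23**2 + 2 * r12 * r13 * r23
            rbar = (r12 + r13) / 2
            t = (r12 - r13) * np.sqrt(
                ((n - 1) * (1 + r23))
                / (2 * detR * (n - 1) / (n - 3) + rbar**2 * (1 - r23) ** 3)
            )
            return t, 2 * stats.t.sf(abs(t), n - 3)

        for args in [(0.5, 0.3, 0.2, 100), (-0.2, 0.4, 0.1, 60), (0.8, 0.75, 0.6, 500)]:
            t, df, p = williams_test(*args)
            t0, p0 = oracle(*args)
            assert t == pytest.approx(t0, abs=1e-12)
            assert p == pytest.approx(p0, abs=1e-12)

    def test_impossible_triple_rejected(self):
        with pytest.raises(ParameterError):
            williams_test(0.99, 0.99, -0.99, 100)

    def test_domain_checks(self):
        with pytest.raises(ParameterError):
            williams_test(1.0, 0.5, 0.2, 100)
        with pytest.raises(ParameterError):
            williams_test(0.5, 0.4, 0.2, 3)
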