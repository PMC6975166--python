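"""Tests of the censored Cox actTime model and its survival integral."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from acttime.survival import (
    CoxActTimeModel,
    CoxActTimeResults,
    CoxDesign,
    CoxFitError,
    EmptyDesignError,
    act_time_bias,
    build_cox_design,
    deterministic_act_time,
    deterministic_table,
    fit_sessions,
    schemper_v,
    survival_curve,
)
from acttime.task import N_BACK, default_agent, generate_cohort


def _toy_design(x, duration, event):
    X = pd.DataFrame({"x": np.asarray(x, float)})
    return CoxDesign(
        X=X,
        duration=np.asarray(duration, float),
        event=np.asarray(event, bool),
        center=X.mean() * 0,
        scale=X.std(ddof=0) * 0 + 1,
        trial_index=np.arange(len(X)),
        max_dots=25,
    )


def _efron_loglik(beta, x, duration, event):
    """Hand-written Efron partial likelihood for one covariate."""
    eta = beta * np.asarray(x, float)
    ll = 0.0
    for t in np.unique(duration[event]):
        D = np.nonzero((duration == t) & event)[0]
        R = np.nonzero(duration >= t)[0]
        d = len(D)
        s_r = np.exp(eta[R]).sum()
        s_d = np.exp(eta[D]).sum()
        ll += eta[D].sum()
        for l in range(d):
            ll -= np.log(s_r - (l / d) * s_d)
    return ll


class TestDesign:
    def test_history_trimming_and_column_count(self, one_session):
        d = build_cox_design(one_session, n_back=10)
        assert len(d.X) == len(one_session) - 10
        assert len(d.columns) == 23

    @pytest.mark.parametrize("variant, ncol", [("present", 3), ("past", 20)])
    def test_variant_columns(self, one_session, variant, ncol):
        d = build_cox_design(one_session, variant=variant)
        assert len(d.columns) == ncol

    def test_short_session_raises(self, one_session):
        with pytest.raises(EmptyDesignError):
            build_cox_design(one_session.head(8))

    def test_all_censored_refused(self, one_session):
        sess = one_session.copy()
        sess["responded"] = False
        with pytest.raises(CoxFitError, match="censored"):
            CoxActTimeModel(sess).fit()

    def test_standardized_columns(self, one_session):
        d = build_cox_design(one_session)
        np.testing.assert_allclose(d.X.mean(), 0.0, atol=1e-12)
        np.testing.assert_allclose(d.X.std(ddof=0), 1.0, atol=1e-12)


class TestFitCox:
    def test_null_covariate_estimates_near_zero(self):
        rng = np.random.default_rng(0)
        n = 2000
        h = 0.2
        T = np.minimum(rng.geometric(h, size=n), 25)
        event = T < 25
        d = _toy_design(rng.standard_normal(n), T, event)
        res = CoxActTimeModel.from_design(d).fit()
        assert abs(res.beta.iloc[0]) < 0.1

    @pytest.mark.parametrize(
        "x, duration, event",
        [
            ([1.0, 0.0], [1, 1], [True, True]),
            ([1, 0, 1, 1, 0], [1, 1, 2, 2, 3], [True, True, True, False, True]),
        ],
    )
    def test_matches_grid_search_of_partial_likelihood(self, x, duration, event):
        """The fitted coefficient maximizes the hand-written Efron
        partial likelihood (1-D grid search oracle, <=5 trials)."""
        duration = np.asarray(duration, float)
        event = np.asarray(event, bool)
        grid = np.arange(-4.0, 4.0, 1e-3)
        ll = [_efron_loglik(b, np.asarray(x, float), duration, event) for b in grid]
        beta_oracle = grid[int(np.argmax(ll))]
        res = CoxActTimeModel.from_design(_toy_design(x, duration, event)).fit()
        assert res.beta.iloc[0] == pytest.approx(beta_oracle, abs=1e-3)

    def test_baseline_hazard_is_breslow_at_zero_covariates(self):
        """Check lifelines' baseline against a hand Breslow estimator
        (z-scored design => baseline at x=0)."""
        rng = np.random.default_rng(3)
        n = 400
        x = rng.standard_normal(n)
        x = (x - x.mean()) / x.std()
        h = 0.15 * np.exp(0.5 * x)
        T = np.array([min(np.argmax(rng.random(25) < hi) + 1 if (rng.random(25) < hi).any() else 25, 25) for hi in h])
        event = T < 25
        res = CoxActTimeModel.from_design(_toy_design(x, T, event)).fit()
        beta = res.beta.iloc[0]
        # hand Breslow cumulative hazard at x=0
        cum = 0.0
        for t in np.unique(T[event]):
            d = int(((T == t) & event).sum())
            denom = np.exp(beta * x[T >= t]).sum()
            cum += d / denom
            assert res.baseline_cum_hazard[int(t)] == pytest.approx(cum, rel=5e-2)

    def test_parameter_recovery_signs(self, cfg=None):
        """A small cohort from the default world reproduces the sign
        pattern: reward +, dot period -, ITI -, past reward +, past
        actTime -."""
        trials = generate_cohort(2, 5, rng=17, n_trials=250)
        fits = fit_sessions(trials)
        mean = pd.DataFrame({k: r.beta for k, r in fits.items()}).mean(axis=1)
        assert mean["reward"] > 0
        assert mean["dot_period"] < 0
        assert mean["iti"] < 0
        assert mean["past_rew1"] > 0
        assert mean["past_act1"] < 0


class TestSurvivalCurve:
    def test_baseline_identity(self, one_session):
        res = CoxActTimeModel(one_session).fit()
        S = res.survival_curve(np.zeros(23))
        np.testing.assert_allclose(S, np.exp(-res.baseline_cum_hazard))

    def test_extreme_risk_limit(self, one_session):
        res = CoxActTimeModel(one_session).fit()
        x = np.zeros(23)
        x[0] = 40.0 / max(res.beta.iloc[0], 1e-6)
        S = res.survival_curve(x)
        first_event = np.nonzero(res.baseline_cum_hazard > 0)[0][0]
        assert np.all(S[first_event:] < 1e-6)

    def test_hand_built_cumulative_hazard(self):
        """Lambda0 steps of 0.1 at t=5 and +0.2 at t=10 with beta.x=ln 2
        give S(10) = exp(-0.6)."""
        cum = np.zeros(26)
        cum[5:] = 0.1
        cum[10:] += 0.2
        S = survival_curve(cum, np.log(2.0))
        assert S[10] == pytest.approx(np.exp(-0.6), abs=1e-12)
        assert S[0] == 1.0

    def test_monotonicity_properties(self, one_session):
        res = CoxActTimeModel(one_session).fit()
        assert np.all(np.diff(res.baseline_cum_hazard) >= 0)
        S = res.survival_curve(res.design.X.to_numpy())
        assert np.all(np.diff(S, axis=1) <= 1e-12)
        assert np.all((S >= 0) & (S <= 1))


class TestDeterministicActTime:
    def test_maximal_wait(self):
        assert deterministic_act_time(np.ones(26)) == pytest.approx(25.0)

    def test_immediate_action(self):
        S = np.zeros(26)
        S[0] = 1.0
        assert deterministic_act_time(S) == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration(self):
        """Sum-of-survival expectation equals brute-force E[min(T,25)]
        enumerated over all 26 outcomes for a constant hazard."""
        h = 0.2
        S = (1 - h) ** np.arange(26)
        # enumeration: P(T=t) = (1-h)^(t-1) h for t=1..25, censored mass at 25
        probs = np.array([(1 - h) ** (t - 1) * h for t in range(1, 26)])
        e_brute = float(np.sum(probs * np.arange(1, 26)) + (1 - probs.sum()) * 25)
        assert deterministic_act_time(S) == pytest.approx(e_brute, abs=1e-9)

    @given(st.lists(st.floats(0.01, 0.9), min_size=25, max_size=25))
    @settings(max_examples=30, deadline=None)
    def test_enumeration_for_arbitrary_hazard(self, hazards):
        h = np.asarray(hazards)
        S = np.concatenate([[1.0], np.cumprod(1 - h)])
        probs = S[:-1] * h
        e_brute = float(np.sum(probs * np.arange(1, 26)) + S[-1] * 25)
        assert deterministic_act_time(S) == pytest.approx(e_brute, abs=1e-9)

    def test_range_invariant(self, small_cohort):
        det = deterministic_table(small_cohort[small_cohort.session_id.isin(
            ["A1-S1", "A2-S1"])])
        for col in ("det_full", "det_present", "det_past"):
            assert det[col].between(0, 25).all()


class TestSchemperV:
    def test_null_covariates_give_zero(self):
        rng = np.random.default_rng(2)
        n = 2000
        T = np.minimum(rng.geometric(0.18, size=n), 25)
        event = T < 25
        d = _toy_design(rng.standard_normal(n), T, event)
        res = CoxActTimeModel.from_design(d).fit()
        assert abs(res.schemper_v().V) < 0.02

    def test_six_trial_hand_computed_oracle(self):
        """V on a 6-trial dataset matches an explicit hand calculation
        of KM curve and survival-process distances."""
        duration = np.array([2.0, 3.0, 3.0, 5.0, 6.0, 6.0])
        event = np.array([True, True, False, True, True, False])
        d = _toy_design([0.0] * 6, duration, event)
        # hand KM: events at t=2 (1/6), t=3 (1/5), t=5 (1/3), t=6 (1/2)
        km = {2: 5 / 6, 3: 5 / 6 * 4 / 5, 5: 5 / 6 * 4 / 5 * 2 / 3,
              6: 5 / 6 * 4 / 5 * 2 / 3 * 1 / 2}
        # predicted curves: use the KM curve itself for every trial =>
        # Dx must equal D and V must be exactly 0
        times = np.array([2, 3, 5, 6])
        S_pred = np.tile([1.0] * 26, (6, 1))
        for t, v in km.items():
            S_pred[:, t:] = np.minimum(S_pred[:, t:], v)
        res = schemper_v(d, S_pred)
        # hand D: per event time, mean |1{t<Ti} - KM(t)| over defined trials
        total, count = 0.0, 0
        for t in times:
            for i in range(6):
                if event[i] or t <= duration[i]:
                    si = 1.0 if t < duration[i] else 0.0
                    total += abs(si - km[t])
                    count += 1
        d_hand = total / count
        assert res.D == pytest.approx(d_hand, abs=1e-6)
        assert res.Dx == pytest.approx(d_hand, abs=1e-6)
        assert res.V == pytest.approx(0.0, abs=1e-6)

    def test_monotone_in_effect_size(self):
        """V increases with the planted covariate effect."""
        rng = np.random.default_rng(8)
        n = 1500
        vs = []
        for beta in (0.0, 0.5, 1.0, 2.0):
            x = rng.choice([-1.0, 1.0], size=n)
            h = np.minimum(0.12 * np.exp(beta * x), 1.0)
            u = rng.random((n, 25))
            hit = u < h[:, None]
            T = np.where(hit.any(1), hit.argmax(1) + 1, 25)
            event = hit.any(1)
            d = _toy_design(x, T.astype(float), event)
            res = CoxActTimeModel.from_design(d).fit()
            vs.append(res.schemper_v().V)
        assert vs == sorted(vs)

    def test_affine_invariance(self):
        """V is unchanged by affine rescaling of covariates (refit included)."""
        rng = np.random.default_rng(4)
        n = 600
        x = rng.standard_normal(n)
        h = np.minimum(0.15 * np.exp(0.6 * x), 1.0)
        u = rng.random((n, 25))
        hit = u < h[:, None]
        T = np.where(hit.any(1), hit.argmax(1) + 1, 25).astype(float)
        event = hit.any(1)
        v1 = CoxActTimeModel.from_design(_toy_design(x, T, event)).fit().schemper_v().V
        v2 = CoxActTimeModel.from_design(_toy_design(2.0 * x + 3.0, T, event)).fit().schemper_v().V
        assert v1 == pytest.approx(v2, abs=1e-4)

    def test_pooled_ordering_full_vs_components(self, small_cohort):
        """With both present and past effects in the generator, the full
        model explains at least as much as either component."""
        sub = small_cohort[small_cohort.session_id.isin(["A1-S1", "A1-S2", "A2-S1"])]
        means = {}
        for variant in ("full", "present", "past"):
            fits = fit_sessions(sub, variant=variant)
            means[variant] = np.mean([r.schemper_v().V for r in fits.values()])
        assert means["full"] >= means["present"] - 0.02
        assert means["full"] >= means["past"] - 0.02


class TestDecomposition:
    def test_present_only_generator(self):
        """Past-context V vanishes and present V tracks the full V when
        the generator has no past effects."""
        beta = np.zeros(23)
        beta[:3] = (0.6, -1.0, -0.4)
        ag = default_agent(beta_truth=beta, noise_sd=0.0)
        trials = generate_cohort(2, 2, agent=ag, rng=31, n_trials=700)
        v_full, v_pres, v_past = [], [], []
        for variant, acc in (("full", v_full), ("present", v_pres), ("past", v_past)):
            for r in fit_sessions(trials, variant=variant).values():
                acc.append(r.schemper_v().V)
        # past V reflects only in-sample overfit of the 20 junk covariates
        assert np.mean(v_past) < 0.05
        assert abs(np.mean(v_pres) - np.mean(v_full)) < 0.06

    def test_past_only_generator(self):
        """With only past effects, the past decomposition correlates
        better with the full deterministic actTime than the present one."""
        beta = np.zeros(23)
        beta[3] = 0.8
        beta[3 + N_BACK] = -0.8
        ag = default_agent(beta_truth=beta, noise_sd=0.0)
        trials = generate_cohort(1, 3, agent=ag, rng=37, n_trials=300)
        det = deterministic_table(trials)
        r_past = np.corrcoef(det.det_past, det.det_full)[0, 1]
        r_pres = np.corrcoef(det.det_present, det.det_full)[0, 1]
        assert r_past > r_pres

    def test_null_generator_constant_series(self):
        """With beta_truth = 0 all deterministic series are ~constant."""
        ag = default_agent(beta_truth=np.zeros(23), noise_sd=0.0)
        trials = generate_cohort(1, 2, agent=ag, rng=41, n_trials=300)
        det = deterministic_table(trials)
        for col in ("det_full", "det_present", "det_past"):
            assert det[col].std() < 1.0


class TestActTimeBias:
    def test_arithmetic(self):
        np.testing.assert_allclose(act_time_bias([14, 10], [14, 13.5]), [0.0, 3.5])

    def test_censored_excluded(self):
        out = act_time_bias([10, 25, 12], [11, 20, 12], responded=[True, False, True])
        np.testing.assert_allclose(out, [1.0, 0.0])

    def test_bias_shrinks_with_agent_noise(self):
        """Mean |observed - deterministic| decreases as the agent's
        unexplained log-hazard jitter shrinks."""
        means = []
        for noise in (1.0, 0.0):
            ag = default_agent(noise_sd=noise)
            trials = generate_cohort(1, 4, agent=ag, rng=53, n_trials=250)
            det = deterministic_table(trials, which_past="all")
            resp = det[det.responded]
            means.append(np.mean(np.abs(resp.act_time_dots - resp.det_full)))
        assert means[1] < means[0]
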