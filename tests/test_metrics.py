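import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from lifelines import KaplanMeierFitter

from bootimpute import (
    Cohort,
    CoxFitError,
    GenerationConfig,
    UndefinedMetricError,
    censoring_weights,
    fit_cox,
    generate_cohort,
    predict_risk,
    td_auc,
    td_brier,
)

TAU = 5.0


def _uncensored(case_risks, control_risks):
    """Cases die before TAU, controls are followed well past it."""
    risks = np.concatenate([case_risks, control_risks])
    time = np.concatenate([
        np.linspace(1, 2, len(case_risks)),
        np.linspace(10, 11, len(control_risks)),
    ])
    event = np.concatenate([
        np.ones(len(case_risks)), np.zeros(len(control_risks))])
    return risks, time, event


class TestTdAuc:
    def test_brute_force_four_pairs(self):
        risks, time, event = _uncensored([0.9, 0.4], [0.5, 0.1])
        assert td_auc(risks, time, event, TAU) == pytest.approx(3 / 4)

    def test_constant_risk_is_half(self):
        risks, time, event = _uncensored([0.3] * 4, [0.3] * 5)
        assert td_auc(risks, time, event, TAU) == pytest.approx(0.5)

    def test_perfect_separation_is_one(self):
        risks, time, event = _uncensored([0.8, 0.9], [0.1, 0.2, 0.3])
        assert td_auc(risks, time, event, TAU) == pytest.approx(1.0)

    def test_no_cases_raises(self):
        with pytest.raises(UndefinedMetricError):
            td_auc([0.1, 0.2], [10.0, 11.0], [0, 0], TAU)

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(0, 2**31 - 1))
    def test_invariant_to_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        n = 60
        risks = rng.uniform(size=n)
        time = rng.uniform(0.5, 12.0, size=n)
        event = rng.integers(0, 2, size=n)
        if not ((time <= TAU) & (event == 1)).any() or not (time > TAU).any():
            return
        base = td_auc(risks, time, event, TAU)
        assert td_auc(np.exp(3 * risks), time, event, TAU) == pytest.approx(
            base, rel=1e-12)

    def test_uncensored_reduces_to_binary_auc_oracle(self, rng):
        n = 200
        risks = rng.uniform(size=n)
        time = np.where(rng.uniform(size=n) < 0.4, 2.0, 9.0)
        event = np.ones(n, dtype=int)
        y = time <= TAU
        # brute-force binary AUC over all pairs
        pos, neg = risks[y], risks[~y]
        diff = pos[:, None] - neg[None, :]
        oracle = (np.sum(diff > 0) + 0.5 * np.sum(diff == 0)) / diff.size
        assert td_auc(risks, time, event, TAU) == pytest.approx(oracle,
                                                                rel=1e-12)


class TestCensoringWeights:
    def test_no_censoring_gives_unit_weights(self):
        time = np.array([1.0, 2.0, 8.0, 9.0])
        event = np.array([1, 1, 1, 0])  # censoring only after tau
        w = censoring_weights(time, event, TAU)
        assert np.allclose(w, 1.0)

    def test_hand_computed_reverse_km(self):
        # one censoring at t=2 (risk set 4): G = 3/4 on [2, 6)
        time = np.array([1.0, 2.0, 3.0, 4.0, 6.0])
        event = np.array([1, 0, 1, 1, 0])
        w = censoring_weights(time, event, TAU)
        assert w == pytest.approx([1.0, 0.0, 4 / 3, 4 / 3, 4 / 3])

    def test_censored_before_tau_weight_zero(self):
        time = np.array([1.0, 3.0, 9.0])
        event = np.array([1, 0, 0])
        assert censoring_weights(time, event, TAU)[1] == 0.0


class TestTdBrier:
    def test_constant_half_prediction_is_quarter(self):
        time = np.array([1.0, 2.0, 8.0, 9.0, 10.0])
        event = np.ones(5, dtype=int)
        assert td_brier(np.full(5, 0.5), time, event, TAU) == 0.25

    def test_perfect_predictions_zero(self):
        time = np.array([1.0, 9.0])
        event = np.array([1, 1])
        assert td_brier(np.array([0.0, 1.0]), time, event, TAU) == 0.0

    @pytest.mark.parametrize("p", [0.1, 0.35, 0.8])
    def test_constant_prediction_formula_uncensored(self, p, rng):
        n = 100
        time = np.where(rng.uniform(size=n) < 0.3, 2.0, 9.0)
        event = np.ones(n, dtype=int)
        alive = (time > TAU).astype(float)
        expected = np.mean((alive - (1 - p)) ** 2)
        got = td_brier(np.full(n, 1 - p), time, event, TAU)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_hand_computed_weighted_sum(self):
        time = np.array([1.0, 2.0, 3.0, 4.0, 6.0])
        event = np.array([1, 0, 1, 1, 0])
        sp = np.array([0.2, 0.5, 0.4, 0.3, 0.9])
        # weights (1, 0, 4/3, 4/3, 4/3); mean of w * (alive - sp)^2
        expected = (1 * 0.04 + 0 + 4 / 3 * 0.16 + 4 / 3 * 0.09
                    + 4 / 3 * 0.01) / 5
        assert td_brier(sp, time, event, TAU) == pytest.approx(expected,
                                                               rel=1e-12)


class TestAgainstScikitSurvival:
    """Independent oracle: scikit-survival's IPCW estimators on censored
    simulated data."""

    @pytest.fixture(scope="class")
    def scored_cohort(self):
        rng = np.random.default_rng(17)
        cohort = generate_cohort(GenerationConfig.default(2000), rng)
        fit = fit_cox(cohort)
        risk = predict_risk(fit, cohort.X, TAU)
        return cohort, risk

    def test_td_auc_matches_cumulative_dynamic_auc(self, scored_cohort):
        from sksurv.metrics import cumulative_dynamic_auc
        from sksurv.util import Surv

        cohort, risk = scored_cohort
        y = Surv.from_arrays(event=cohort.event.astype(bool),
                             time=cohort.time)
        ref, _ = cumulative_dynamic_auc(y, y, risk, times=[TAU])
        ours = td_auc(risk, cohort.time, cohort.event, TAU)
        assert ours == pytest.approx(ref[0], abs=0.005)

    def test_td_brier_matches_brier_score(self, scored_cohort):
        from sksurv.metrics import brier_score
        from sksurv.util import Surv

        cohort, risk = scored_cohort
        y = Surv.from_arrays(event=cohort.event.astype(bool),
                             time=cohort.time)
        _, ref = brier_score(y, y, (1 - risk).reshape(-1, 1), times=[TAU])
        ours = td_brier(1 - risk, cohort.time, cohort.event, TAU)
        assert ours == pytest.approx(ref[0], abs=0.005)


class TestFitCox:
    def test_two_group_exponential_rate_ratio(self, rng):
        n = 4000
        x = rng.integers(0, 2, size=n).astype(float)
        time = rng.exponential(1.0 / np.exp(np.log(2.0) * x))
        cohort = Cohort(X=x.reshape(-1, 1), time=time,
                        event=np.ones(n, dtype=int))
        fit = fit_cox(cohort)
        assert np.exp(fit.coefficients.iloc[0]) == pytest.approx(2.0,
                                                                 rel=0.1)

    def test_under_determined_fit_signals_failure(self, rng):
        cohort = Cohort(
            X=rng.normal(size=(12, 11)),
            time=rng.uniform(1, 10, 12),
            event=np.array([1, 1, 1] + [0] * 9),
        )
        with pytest.raises(CoxFitError):
            fit_cox(cohort)

    def test_no_events_signals_failure(self, rng):
        cohort = Cohort(X=rng.normal(size=(50, 2)),
                        time=rng.uniform(1, 10, 50),
                        event=np.zeros(50, dtype=int))
        with pytest.raises(CoxFitError):
            fit_cox(cohort)


class TestPredictRisk:
    @pytest.fixture(scope="class")
    def fitted(self):
        rng = np.random.default_rng(19)
        cohort = generate_cohort(GenerationConfig.default(2000), rng)
        return cohort, fit_cox(cohort)

    def test_baseline_risk_at_mean_covariates(self, fitted):
        cohort, fit = fitted
        mean_row = cohort.X.mean(axis=0, keepdims=True)
        s0 = fit.model.baseline_survival_
        idx = s0.index.to_numpy() <= TAU
        expected = 1.0 - s0.iloc[:, 0].to_numpy()[idx][-1]
        assert predict_risk(fit, mean_row, TAU)[0] == pytest.approx(
            expected, abs=1e-6)

    def test_risk_ordering_matches_linear_predictor(self, fitted):
        cohort, fit = fitted
        risk = predict_risk(fit, cohort.X, TAU)
        lp = cohort.X @ fit.coefficients.to_numpy()
        assert np.array_equal(np.argsort(risk), np.argsort(lp))

    def test_extreme_linear_predictor_saturates(self, fitted):
        cohort, fit = fitted
        beta = fit.coefficients.to_numpy()
        X_hi = cohort.X.mean(axis=0) + 50 * np.sign(beta)
        assert predict_risk(fit, X_hi.reshape(1, -1), TAU)[0] > 0.999

    def test_null_model_matches_product_limit_oracle(self):
        # a pure-noise covariate: predicted survival at the mean must agree
        # with the Kaplan-Meier estimate of the pooled sample
        rng = np.random.default_rng(23)
        n = 3000
        cfg = GenerationConfig.default(n)
        cohort = generate_cohort(cfg, rng)
        noise = Cohort(X=rng.normal(size=(n, 1)), time=cohort.time,
                       event=cohort.event)
        fit = fit_cox(noise)
        risk = predict_risk(fit, np.zeros((1, 1)), TAU)[0]
        km = KaplanMeierFitter().fit(noise.time, noise.event)
        km_risk = 1.0 - float(
            km.survival_function_at_times(TAU).iloc[0])
        assert risk == pytest.approx(km_risk, abs=0.01)

    def test_horizon_beyond_followup_warns(self, fitted):
        cohort, fit = fitted
        with pytest.warns(RuntimeWarning):
            predict_risk(fit, cohort.X[:3], 1e6)
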