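import numpy as np
import pytest

from bootimpute import (
    ImputationError,
    MaskedCohort,
    Strategy,
    apply_imputation,
    apply_strategy,
    complete_cases,
    fit_imputation_models,
)
from bootimpute.imputation import ImputationModel


def _masked(X, mask, time=None, event=None):
    X = np.asarray(X, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    Xm = X.copy()
    Xm[mask] = np.nan
    n = X.shape[0]
    return MaskedCohort(
        X=Xm, mask=mask,
        time=np.arange(1, n + 1, dtype=float) if time is None else time,
        event=np.ones(n, dtype=int) if event is None else event,
    )


@pytest.fixture()
def linear_masked(rng):
    """x2 = 1 + 2 x1 + noise, with x2 masked MCAR on 30% of rows."""
    n = 400
    x1 = rng.normal(size=n)
    x2 = 1.0 + 2.0 * x1 + rng.normal(scale=0.3, size=n)
    mask = np.zeros((n, 2), dtype=bool)
    mask[:, 1] = rng.uniform(size=n) < 0.3
    return _masked(np.column_stack([x1, x2]), mask)


class TestFitModels:
    def test_no_missing_gives_empty_set(self, rng):
        m = _masked(rng.normal(size=(20, 3)), np.zeros((20, 3), dtype=bool))
        assert len(fit_imputation_models(m)) == 0

    def test_identity_link_matches_least_squares_oracle(self, linear_masked):
        models = fit_imputation_models(linear_masked)
        model = models["x2"]
        assert model.link == "identity"
        obs = ~linear_masked.mask[:, 1]
        design = np.column_stack(
            [np.ones(obs.sum()), linear_masked.X[obs, 0]])
        oracle, *_ = np.linalg.lstsq(design, linear_masked.X[obs, 1],
                                     rcond=None)
        assert model.intercept == pytest.approx(oracle[0], rel=1e-8)
        assert model.coefficients[0] == pytest.approx(oracle[1], rel=1e-8)
        assert model.n_fit == int(obs.sum())

    def test_binary_target_uses_logit_and_predicts_probabilities(self, rng):
        n = 300
        x1 = rng.normal(size=n)
        y = (rng.uniform(size=n) < 1 / (1 + np.exp(-x1))).astype(float)
        mask = np.zeros((n, 2), dtype=bool)
        mask[:, 1] = rng.uniform(size=n) < 0.25
        m = _masked(np.column_stack([x1, y]), mask)
        model = fit_imputation_models(m)["x2"]
        assert model.link == "logit"
        preds = model.predict(rng.normal(size=(50, 1)))
        assert ((preds > 0) & (preds < 1)).all()

    def test_outcome_never_a_predictor(self, small_masked):
        models = fit_imputation_models(small_masked)
        for target, model in models.models.items():
            assert target not in model.predictors
            assert "time" not in model.predictors
            assert "event" not in model.predictors
            # predictors are exactly the fully observed covariates
            frac = small_masked.missing_fraction()
            assert all(frac[p] == 0 for p in model.predictors)

    def test_insufficient_observed_rows_signal(self):
        X = np.column_stack([np.arange(6.0), np.arange(6.0)])
        mask = np.zeros((6, 2), dtype=bool)
        mask[2:, 1] = True  # only 2 observed rows for x2
        with pytest.raises(ImputationError) as err:
            fit_imputation_models(_masked(X, mask))
        assert err.value.covariate == "x2"


class TestApplyImputation:
    def test_fully_observed_identity(self, rng):
        X = rng.normal(size=(15, 3))
        m = _masked(X, np.zeros((15, 3), dtype=bool))
        out = apply_imputation(m, fit_imputation_models(m))
        assert np.array_equal(out.X, X)

    def test_hand_computed_linear_prediction(self):
        model = ImputationModel(
            target="x2", link="identity", intercept=1.0,
            coefficients=np.array([2.0]), predictors=("x1",), n_fit=10)
        assert model.predict(np.array([[3.0]]))[0] == pytest.approx(7.0)

    def test_observed_entries_bit_exact_and_no_nan_left(self, small_masked):
        models = fit_imputation_models(small_masked)
        out = apply_imputation(small_masked, models)
        obs = ~small_masked.mask
        assert np.array_equal(out.X[obs], small_masked.X[obs])
        assert not np.isnan(out.X).any()
        assert np.array_equal(out.time, small_masked.time)
        assert np.array_equal(out.event, small_masked.event)

    def test_binary_imputations_are_unthresholded_probabilities(
            self, small_masked):
        # x1 and x4 are binary in the default generator
        models = fit_imputation_models(small_masked)
        out = apply_imputation(small_masked, models)
        j = small_masked.columns.index("x4")
        filled = out.X[small_masked.mask[:, j], j]
        assert ((filled > 0) & (filled < 1)).all()
        assert not np.isin(filled, (0.0, 1.0)).any()

    def test_threshold_binary_rounds_to_classes(self, small_masked):
        models = fit_imputation_models(small_masked)
        out = apply_imputation(small_masked, models, threshold_binary=True)
        j = small_masked.columns.index("x4")
        filled = out.X[small_masked.mask[:, j], j]
        assert np.isin(filled, (0.0, 1.0)).all()
        # continuous targets are unaffected by the switch
        j3 = small_masked.columns.index("x3")
        base = apply_imputation(small_masked, models)
        assert np.array_equal(out.X[:, j3], base.X[:, j3])

    def test_uncovered_covariate_rejected(self, small_masked):
        models = fit_imputation_models(small_masked, targets=["x3"])
        with pytest.raises(ImputationError):
            apply_imputation(small_masked, models)


class TestStrategies:
    def test_impute_all_drops_nothing(self, small_masked):
        cohort, dropped = apply_strategy(small_masked, Strategy.IMPUTE_ALL)
        assert dropped == 0
        assert cohort.n == small_masked.n
        assert not np.isnan(cohort.X).any()

    def test_gt10_imputes_only_frequent_and_drops_rest(self, small_masked):
        # pattern E marginals ~5/15/30%: x1 below the 10% rule, x3/x4 above
        frac = small_masked.missing_fraction()
        assert frac["x1"] < 0.10 < frac["x3"]
        cohort, dropped = apply_strategy(small_masked, Strategy.IMPUTE_GT10)
        n_x1_missing = int(small_masked.mask[
            :, small_masked.columns.index("x1")].sum())
        assert dropped == n_x1_missing
        assert cohort.n == small_masked.n - n_x1_missing
        # retained rows' x1 values are original (never imputed)
        j = small_masked.columns.index("x1")
        kept = np.isin(small_masked.index, cohort.index)
        assert np.array_equal(cohort.X[:, j], small_masked.X[kept, j])

    def test_le2_equals_impute_all_when_no_row_misses_three(self,
                                                            small_masked):
        per_row = small_masked.mask.sum(axis=1)
        keep = per_row <= 2
        sub = small_masked.take(np.flatnonzero(keep))
        a, da = apply_strategy(sub, Strategy.IMPUTE_LE2)
        b, db = apply_strategy(sub, Strategy.IMPUTE_ALL)
        assert da == db == 0
        assert np.allclose(a.X, b.X)

    def test_le2_drops_rows_missing_three_or_more(self, small_masked):
        cohort, dropped = apply_strategy(small_masked, Strategy.IMPUTE_LE2)
        n_heavy = int((small_masked.mask.sum(axis=1) >= 3).sum())
        assert dropped == n_heavy

    def test_complete_case_matches_row_scan_oracle(self, small_masked):
        cohort = complete_cases(small_masked)
        oracle = ~np.isnan(small_masked.X).any(axis=1)
        assert cohort.n == int(oracle.sum())
        assert np.array_equal(cohort.X, small_masked.X[oracle])

    def test_complete_case_identity_on_full_data(self, rng):
        X = rng.normal(size=(30, 2))
        m = _masked(X, np.zeros((30, 2), dtype=bool))
        assert complete_cases(m).n == 30

    def test_refit_differs_across_resamples(self, small_masked, rng):
        """Imputation models are refit from each resample's own rows."""
        idx1 = rng.integers(0, small_masked.n, small_masked.n)
        idx2 = rng.integers(0, small_masked.n, small_masked.n)
        m1 = fit_imputation_models(small_masked.take(idx1))["x3"]
        m2 = fit_imputation_models(small_masked.take(idx2))["x3"]
        assert not np.allclose(m1.coefficients, m2.coefficients)
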