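"""Metrics, RI arithmetic, individual/stacked/average models, splits."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sklearn.tree import DecisionTreeRegressor
from sklearn.model_selection import KFold

from plantargait import (
    ConfigurationError,
    ModelMetrics,
    ValidationError,
    baseline_predict,
    compute_ri,
    evaluate,
    fit_average_ensemble,
    fit_individual,
    fit_stacked,
    holdout_split,
)
from plantargait.models import _oof_predictions
from plantargait.reference import BENCHMARK_CV_METRICS, BENCHMARK_RI


class TestEvaluate:
    def test_perfect_predictions(self):
        m = evaluate([10.0, 20.0], [10.0, 20.0])
        assert m.as_tuple() == (0.0, 0.0, 0.0)

    def test_arithmetic_example(self):
        m = evaluate([10.0, 20.0], [9.0, 22.0])
        assert m.mae == pytest.approx(1.5)
        assert m.mape == pytest.approx(10.0)
        assert m.rmse == pytest.approx(np.sqrt(2.5))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(1, 30)
        y = rng.uniform(1, 50, n)
        p = rng.uniform(0, 50, n)
        m = evaluate(y, p)
        assert m.mae == pytest.approx(sum(abs(a - b) for a, b in zip(p, y)) / n)
        assert m.mape == pytest.approx(
            100 * sum(abs(a - b) / b for a, b in zip(p, y)) / n)
        assert m.rmse == pytest.approx(
            (sum((a - b) ** 2 for a, b in zip(p, y)) / n) ** 0.5)
        assert m.rmse >= m.mae - 1e-12  # Jensen

    def test_zero_label_rejected(self):
        with pytest.raises(ValidationError):
            evaluate([0.0, 1.0], [1.0, 1.0])


class TestBaselineAndRI:
    def test_baseline_is_training_mean(self):
        np.testing.assert_allclose(baseline_predict([10.0, 20.0], 3), 15.0)

    def test_baseline_ri_is_zero(self):
        b = ModelMetrics(2.0, 10.0, 3.0)
        assert compute_ri(b, b).ri == 0.0

    def test_reproduces_printed_benchmark_ri(self):
        """RI arithmetic reproduces every printed benchmark RI to 3 dp."""
        for task, table in BENCHMARK_CV_METRICS.items():
            base = ModelMetrics(*table["Baseline"])
            for model, printed in BENCHMARK_RI[task].items():
                got = compute_ri(base, ModelMetrics(*table[model])).ri
                assert round(got, 3) == pytest.approx(printed, abs=5e-4), \
                    (task, model)

    def test_zero_baseline_metric_rejected(self):
        with pytest.raises(ValidationError):
            compute_ri(ModelMetrics(0.0, 1.0, 1.0), ModelMetrics(1.0, 1.0, 1.0))


class TestHoldoutSplit:
    def test_92_participants_give_61_31(self):
        train, test = holdout_split(92, test_fraction=0.33, seed=0)
        assert len(train) == 61 and len(test) == 31
        assert not set(train) & set(test)
        assert sorted(np.r_[train, test].tolist()) == list(range(92))

    def test_minimal_split(self):
        train, test = holdout_split(3, test_fraction=0.33, seed=1)
        assert len(train) == 2 and len(test) == 1

    def test_determinism_and_seed_sensitivity(self):
        a = holdout_split(50, seed=5)
        b = holdout_split(50, seed=5)
        c = holdout_split(50, seed=6)
        np.testing.assert_array_equal(a[0], b[0])
        assert not np.array_equal(a[1], c[1])

    def test_too_small(self):
        with pytest.raises(ValidationError):
            holdout_split(2)


def _linear_data(n=40, p=3, seed=0, noise=0.0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    y = 20.0 + X @ np.array([2.0, -1.0, 0.5][:p]) + noise * rng.normal(size=n)
    return X, y


class TestFitIndividual:
    def test_lr_on_linear_data_near_zero_mae(self):
        X, y = _linear_data()
        _, metrics = fit_individual("LR", X, y, tuning_budget=0, seed=0)
        assert metrics.mae < 1e-8

    def test_same_seed_identical_metrics(self):
        X, y = _linear_data(noise=1.0, seed=1)
        _, m1 = fit_individual("RF", X, y, tuning_budget=3, seed=7)
        _, m2 = fit_individual("RF", X, y, tuning_budget=3, seed=7)
        assert m1 == m2

    def test_unknown_model_rejected(self):
        X, y = _linear_data()
        with pytest.raises(ConfigurationError):
            fit_individual("MLP", X, y)

    @pytest.mark.parametrize("name", ["SVM", "XGBoost", "LGBM", "AdaBoost"])
    def test_all_model_families_fit(self, name):
        X, y = _linear_data(n=30, noise=0.5, seed=2)
        model, metrics = fit_individual(name, X, y, tuning_budget=2, seed=0)
        assert np.isfinite(metrics.as_tuple()).all()
        assert model.predict(X[:3]).shape == (3,)


class TestFitStacked:
    def test_second_level_input_dimension_is_four(self):
        X, y = _linear_data(n=40, noise=0.5, seed=3)
        model, metrics = fit_stacked(X, y, second_level="linear", seed=0)
        P = model.member_matrix(X[:5])
        assert P.shape == (5, 4)
        assert np.isfinite(metrics.as_tuple()).all()
        assert model.predict(X[:5]).shape == (5,)

    def test_oof_predictions_are_out_of_fold(self):
        # a fully-grown tree memorizes its training rows: if fold handling
        # leaked, OOF predictions would equal y exactly
        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 3))
        y = rng.uniform(10, 30, size=30)
        members = {"tree": DecisionTreeRegressor(random_state=0)}
        cv = KFold(n_splits=5, shuffle=True, random_state=0)
        P, assign = _oof_predictions(members, X, y, cv)
        assert np.mean(np.abs(P[:, 0] - y)) > 0.5
        assert set(assign) == set(range(5))
        # and the memorizing tree does predict training rows exactly
        tree = DecisionTreeRegressor(random_state=0).fit(X, y)
        np.testing.assert_allclose(tree.predict(X), y)

    def test_oof_matrix_independent_of_heldout_data(self):
        X, y = _linear_data(n=30, noise=0.3, seed=5)
        members = {"tree": DecisionTreeRegressor(random_state=0)}
        cv = KFold(n_splits=5, shuffle=True, random_state=0)
        P1, _ = _oof_predictions(members, X, y, cv)
        P2, _ = _oof_predictions(members, X.copy(), y.copy(), cv)
        np.testing.assert_array_equal(P1, P2)


class _Const:
    def __init__(self, v):
        self.v = v

    def predict(self, X):
        return np.full(len(X), self.v)


class TestAverageEnsembles:
    def test_wae_equals_sae_under_equal_ris(self):
        members = {"a": _Const(1.0), "b": _Const(3.0)}
        X = np.zeros((4, 2))
        sae = fit_average_ensemble(members, mode="SAE")
        wae = fit_average_ensemble(members, mode="WAE",
                                   member_ris={"a": 0.7, "b": 0.7})
        np.testing.assert_allclose(sae.predict(X), wae.predict(X))

    def test_weighted_example(self):
        members = {"a": _Const(0.0), "b": _Const(4.0)}
        wae = fit_average_ensemble(members, mode="WAE",
                                   member_ris={"a": 1.0, "b": 3.0})
        np.testing.assert_allclose(wae.predict(np.zeros((2, 1))), 3.0)

    def test_weights_nonnegative_and_sum_to_one(self):
        members = {k: _Const(i) for i, k in enumerate("abcd")}
        ris = {"a": 0.5, "b": 1.5, "c": 0.1, "d": 2.0}
        wae = fit_average_ensemble(members, mode="WAE", member_ris=ris)
        w = np.array(list(wae.weights.values()))
        assert np.all(w >= 0) and w.sum() == pytest.approx(1.0)

    def test_nonpositive_ri_member_excluded(self):
        members = {"a": _Const(0.0), "b": _Const(4.0)}
        wae = fit_average_ensemble(members, mode="WAE",
                                   member_ris={"a": -0.5, "b": 1.0})
        assert list(wae.members) == ["b"]
        np.testing.assert_allclose(wae.predict(np.zeros((2, 1))), 4.0)

    def test_all_nonpositive_ris_rejected(self):
        members = {"a": _Const(0.0)}
        with pytest.raises(ConfigurationError):
            fit_average_ensemble(members, mode="WAE", member_ris={"a": -1.0})
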