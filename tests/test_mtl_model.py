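"""Sparse multi-task logistic model: loss, solver, selection, thresholds."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import minimize

from driverank.io_formats import ContractError
from driverank.mtl_model import (
    MTLConfig,
    TaskDataset,
    classify_drivers,
    cv_select_lambda1,
    fit_mtl,
    lambda1_max,
    load_mtl_model,
    logistic_loss,
    mtl_objective,
    predict_probability,
    save_mtl_model,
    select_lambda2_on_validation,
    select_task_thresholds,
    sigmoid,
    soft_threshold,
)
from driverank.synthetic_fixtures import SimulationConfig, simulate_mtl_tasks

NO_BIAS = MTLConfig(add_bias=False)


def toy_task(n=200, p=26, seed=0, name="t"):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    w = np.zeros(p)
    w[:5] = [1.5, -1.0, 2.0, 0.5, -2.0]
    Y = np.where(rng.random(n) < sigmoid(X @ w), 1.0, -1.0)
    return TaskDataset(name, X, Y)


class TestLogisticLoss:
    def test_zero_weights_give_log_two(self):
        t = toy_task()
        assert logistic_loss(np.zeros(26), t.X, t.Y) == pytest.approx(math.log(2))

    def test_hand_computed_single_sample(self):
        # one sample with margin X w = 1 and label +1
        X = np.array([[1.0]])
        assert logistic_loss(np.array([1.0]), X, np.array([1.0])) == pytest.approx(
            math.log(1 + math.exp(-1)), abs=1e-12
        )

    def test_large_correct_margin_vanishes_without_overflow(self):
        X = np.array([[1000.0]])
        assert logistic_loss(np.array([1.0]), X, np.array([1.0])) == 0.0
        # large wrong-side margin is finite and ~linear, not inf
        wrong = logistic_loss(np.array([1.0]), X, np.array([-1.0]))
        assert wrong == pytest.approx(1000.0, rel=1e-6)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ContractError):
            logistic_loss(np.zeros(3), np.zeros((5, 4)), np.ones(5))


class TestObjective:
    def test_zero_matrix_gives_t_log_two(self):
        tasks = [toy_task(seed=i, name=f"t{i}") for i in range(3)]
        W = np.zeros((26, 3))
        assert mtl_objective(W, tasks, 1.0, 1.0, NO_BIAS) == pytest.approx(
            3 * math.log(2)
        )

    def test_no_penalty_reduces_to_sum_of_losses(self):
        tasks = [toy_task(seed=i, name=f"t{i}") for i in range(2)]
        rng = np.random.default_rng(1)
        W = rng.normal(scale=0.1, size=(26, 2))
        expected = sum(
            logistic_loss(W[:, i], t.X, t.Y) for i, t in enumerate(tasks)
        )
        assert mtl_objective(W, tasks, 0.0, 0.0, NO_BIAS) == pytest.approx(expected)

    def test_matches_independent_term_by_term_summation(self):
        tasks = [toy_task(seed=i, name=f"t{i}") for i in range(2)]
        rng = np.random.default_rng(2)
        W = rng.normal(scale=0.3, size=(26, 2))
        lam1, lam2 = 0.37, 0.11
        # independent summation: per-sample loop, element-wise penalties
        total = 0.0
        for i, t in enumerate(tasks):
            for x, y in zip(t.X, t.Y):
                total += math.log1p(math.exp(-y * float(x @ W[:, i]))) / t.n
        total += lam1 * sum(abs(v) for v in W.ravel())
        total += lam2 * sum(v * v for v in W.ravel())
        assert mtl_objective(W, tasks, lam1, lam2, NO_BIAS) == pytest.approx(
            total, abs=1e-10
        )

    def test_negative_penalty_rejected(self):
        with pytest.raises(ContractError):
            mtl_objective(np.zeros((26, 1)), [toy_task()], -0.1, 0.0)


class TestSoftThreshold:
    @given(
        st.lists(st.floats(-10, 10), min_size=1, max_size=20),
        st.floats(0, 5),
    )
    def test_matches_closed_form_elementwise(self, values, tau):
        x = np.array(values)
        expected = np.array(
            [math.copysign(max(abs(v) - tau, 0.0), v) for v in values]
        )
        np.testing.assert_allclose(soft_threshold(x, tau), expected, atol=1e-15)

    def test_shrinks_toward_zero_and_preserves_sign(self):
        x = np.array([-3.0, -0.5, 0.0, 0.5, 3.0])
        out = soft_threshold(x, 1.0)
        np.testing.assert_allclose(out, [-2.0, 0.0, 0.0, 0.0, 2.0])


class TestSolver:
    def test_unregularized_single_task_matches_convex_oracle(self):
        task = toy_task(n=200, p=26, seed=0)
        model = fit_mtl([task], 0.0, 0.0, config=NO_BIAS)
        oracle = minimize(
            lambda w: logistic_loss(w, task.X, task.Y),
            np.zeros(26),
            method="L-BFGS-B",
            options={"ftol": 1e-15, "gtol": 1e-10},
        )
        assert np.abs(model.W[:, 0] - oracle.x).max() <= 1e-3

    def test_objective_never_increases_across_iterates(self):
        tasks, _ = simulate_mtl_tasks(SimulationConfig(seed=3), n_per_task=150)
        model = fit_mtl(tasks, 1e-2, 1e-3, config=NO_BIAS)
        history = np.array(model.objective_history)
        assert np.all(np.diff(history) <= 1e-12)

    def test_full_shrinkage_at_lambda1_max(self):
        tasks, _ = simulate_mtl_tasks(SimulationConfig(seed=4), n_per_task=150)
        lmax = lambda1_max(tasks, 1e-4, NO_BIAS)
        model = fit_mtl(tasks, lmax * 1.001, 1e-4, config=NO_BIAS)
        assert np.all(model.W == 0.0)
        probs = predict_probability(model, tasks[0].X, tasks[0].task_name)
        np.testing.assert_allclose(probs, 0.5)

    def test_just_below_lambda1_max_some_weight_survives(self):
        tasks, _ = simulate_mtl_tasks(SimulationConfig(seed=4), n_per_task=150)
        lmax = lambda1_max(tasks, 1e-4, NO_BIAS)
        model = fit_mtl(tasks, lmax * 0.9, 1e-4, config=NO_BIAS)
        assert np.abs(model.W).max() > 0.0

    def test_l1_produces_exact_zeros_on_noise_features(self):
        tasks, W_true = simulate_mtl_tasks(SimulationConfig(seed=5), n_per_task=300)
        model = fit_mtl(tasks, 5e-2, 1e-4, config=NO_BIAS)
        noise_rows = np.flatnonzero(np.abs(W_true).sum(axis=1) == 0)
        zero_fraction = np.mean(model.W[noise_rows] == 0.0)
        assert zero_fraction > 0.5

    def test_task_order_permutation_permutes_columns(self):
        tasks, _ = simulate_mtl_tasks(
            SimulationConfig(seed=6, n_tasks=3), n_per_task=100
        )
        model = fit_mtl(tasks, 1e-3, 1e-4, config=NO_BIAS)
        perm = [2, 0, 1]
        permuted = fit_mtl([tasks[i] for i in perm], 1e-3, 1e-4, config=NO_BIAS)
        np.testing.assert_allclose(permuted.W, model.W[:, perm], atol=1e-6)
        assert permuted.task_names == tuple(tasks[i].task_name for i in perm)

    def test_intercept_exempt_from_l1_but_fitted(self):
        # imbalanced labels, no informative features: only the intercept moves
        rng = np.random.default_rng(7)
        X = rng.standard_normal((400, 4))
        Y = np.where(rng.random(400) < 0.9, 1.0, -1.0)
        task = TaskDataset("t", X, Y)
        lmax = lambda1_max([task], 1e-4, MTLConfig(add_bias=True))
        model = fit_mtl([task], lmax * 1.01, 1e-4, config=MTLConfig(add_bias=True))
        assert np.all(model.W[:-1] == 0.0)
        assert model.W[-1, 0] > 0.5  # log-odds of the majority class

    def test_empty_task_list_rejected(self):
        with pytest.raises(ContractError):
            fit_mtl([], 0.1, 0.1)


class TestLambdaSelection:
    def test_single_value_grid_returned(self):
        tasks, _ = simulate_mtl_tasks(SimulationConfig(seed=8), n_per_task=100)
        assert cv_select_lambda1(tasks, 1e-4, grid=[0.123], folds=3) == 0.123

    def test_informative_simulation_prefers_small_lambda1(self):
        tasks, _ = simulate_mtl_tasks(SimulationConfig(seed=9), n_per_task=200)
        lam = cv_select_lambda1(
            tasks, 1e-4, grid=[1e-5, 1e3], folds=5, seed=0, config=NO_BIAS
        )
        assert lam == 1e-5

    def test_selection_is_deterministic(self):
        tasks, _ = simulate_mtl_tasks(SimulationConfig(seed=10), n_per_task=150)
        grid = [1e-4, 1e-2, 1.0]
        a = cv_select_lambda1(tasks, 1e-4, grid=grid, folds=5, seed=3)
        b = cv_select_lambda1(tasks, 1e-4, grid=grid, folds=5, seed=3)
        assert a == b

    def test_lambda2_single_value_grid(self):
        tasks, _ = simulate_mtl_tasks(SimulationConfig(seed=11), n_per_task=100)
        assert select_lambda2_on_validation(tasks, tasks, grid=[0.5]) == 0.5

    def test_lambda2_avoids_degenerate_fit(self):
        tasks, _ = simulate_mtl_tasks(SimulationConfig(seed=12), n_per_task=200)
        # an absurd lambda2 crushes all coefficients -> constant predictions
        lam = select_lambda2_on_validation(
            tasks, tasks, grid=[1e-4, 1e6], lambda1=1e-5, config=NO_BIAS
        )
        assert lam == 1e-4

    def test_lambda2_tie_goes_to_smaller(self):
        tasks, _ = simulate_mtl_tasks(SimulationConfig(seed=13), n_per_task=100)
        # two tiny values that give identical predictions -> tie -> smaller
        lam = select_lambda2_on_validation(
            tasks, tasks, grid=[1e-12, 1e-11], lambda1=1e-5
        )
        assert lam == 1e-12

    def test_empty_validation_rejected(self):
        tasks, _ = simulate_mtl_tasks(SimulationConfig(seed=14), n_per_task=50)
        with pytest.raises(ContractError):
            select_lambda2_on_validation(tasks, [], grid=[1e-4, 1e-3])


class TestPredictAndThresholds:
    def test_zero_features_zero_bias_give_half(self):
        model = fit_mtl([toy_task(n=50)], 1e3, 0.0, config=NO_BIAS)
        prob = predict_probability(model, np.zeros((1, 26)), "t")
        assert prob[0] == pytest.approx(0.5)

    def test_probabilities_strictly_inside_unit_interval(self):
        task = toy_task(n=100, seed=2)
        model = fit_mtl([task], 1e-3, 1e-4)
        probs = predict_probability(model, task.X, "t")
        assert np.all((probs > 0) & (probs < 1))

    def test_hand_computed_sigmoid_single_gene(self):
        model = fit_mtl([toy_task(n=80, seed=3)], 1e-3, 1e-4, config=NO_BIAS)
        x = np.arange(26, dtype=float) / 26
        expected = 1.0 / (1.0 + math.exp(-float(x @ model.W[:, 0])))
        assert predict_probability(model, x, "t")[0] == pytest.approx(expected)

    def test_unknown_task_lists_available(self):
        model = fit_mtl([toy_task()], 1e-3, 1e-4)
        with pytest.raises(ContractError, match="'t'"):
            predict_probability(model, np.zeros((1, 26)), "nope")

    def _model_with_probs(self, probs):
        """A 1-feature no-bias model whose predictions on logit(p) are p."""
        task = TaskDataset(
            "t", np.array([[1.0], [-1.0]]), np.array([1.0, -1.0])
        )
        model = fit_mtl([task], 0.0, 0.0, config=NO_BIAS)
        model.W[:, 0] = [1.0]
        X = np.log(np.array(probs) / (1 - np.array(probs)))[:, None]
        return model, X

    def test_threshold_brute_force_oracle_agreement(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            probs = rng.uniform(0.05, 0.95, size=10).round(2)
            labels = np.where(rng.random(10) < 0.5, 1.0, -1.0)
            if len(set(labels)) < 2:
                continue
            model, X = self._model_with_probs(probs)
            # evaluate on the model's own (float-rounded) probabilities
            probs = predict_probability(model, X, "t")
            thr = select_task_thresholds(
                model, [TaskDataset("t", X, labels)]
            )["t"]
            # oracle: exhaustive scan over the same candidate set
            uniq = np.unique(probs)
            candidates = np.unique(
                np.concatenate([[0.0, 1.0], uniq, (uniq[:-1] + uniq[1:]) / 2])
            )
            best_acc, best_thr = -1.0, None
            for c in candidates:
                acc = np.mean((probs >= c) == (labels > 0))
                if acc > best_acc or (acc == best_acc and c > best_thr):
                    best_acc, best_thr = acc, c
            got = np.mean((probs >= thr) == (labels > 0))
            assert got == pytest.approx(best_acc)
            assert thr == pytest.approx(best_thr)

    def test_separated_probabilities_pick_largest_candidate_in_gap(self):
        probs = np.array([0.1, 0.2, 0.8, 0.9])
        labels = np.array([-1.0, -1.0, 1.0, 1.0])
        model, X = self._model_with_probs(probs)
        thr = select_task_thresholds(model, [TaskDataset("t", X, labels)])["t"]
        assert thr == pytest.approx(0.8)  # largest candidate with accuracy 1

    def test_single_class_validation_gets_extreme_threshold(self):
        probs = np.array([0.2, 0.4, 0.6])
        labels = np.array([-1.0, -1.0, -1.0])
        model, X = self._model_with_probs(probs)
        thr = select_task_thresholds(model, [TaskDataset("t", X, labels)])["t"]
        acc = np.mean((probs >= thr) == (labels > 0))
        assert acc == 1.0
        assert thr == 1.0

    def test_missing_validation_task_defaults_to_half_with_warning(self):
        model = fit_mtl([toy_task()], 1e-3, 1e-4)
        with pytest.warns(RuntimeWarning, match="0.5"):
            thr = select_task_thresholds(model, [])
        assert thr == {"t": 0.5}


class TestClassification:
    def test_probability_equal_to_threshold_is_driver(self):
        assert classify_drivers(np.array([0.7]), 0.7).tolist() == ["driver"]

    def test_zero_threshold_calls_everything(self):
        labels = classify_drivers(np.array([0.0, 0.5, 1.0]), 0.0)
        assert (labels == "driver").all()

    def test_driver_count_non_increasing_in_threshold(self):
        rng = np.random.default_rng(19)
        probs = rng.random(100)
        counts = [
            (classify_drivers(probs, thr) == "driver").sum()
            for thr in np.linspace(0, 1, 21)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestSerialization:
    def test_round_trip_preserves_predictions(self, tmp_path):
        tasks, _ = simulate_mtl_tasks(SimulationConfig(seed=20), n_per_task=80)
        model = fit_mtl(tasks, 1e-3, 1e-4)
        select_task_thresholds(model, tasks)
        path = tmp_path / "model.json"
        save_mtl_model(model, path)
        loaded = load_mtl_model(path)
        assert loaded.task_names == model.task_names
        assert loaded.thresholds == model.thresholds
        np.testing.assert_allclose(
            predict_probability(loaded, tasks[0].X, tasks[0].task_name),
            predict_probability(model, tasks[0].X, tasks[0].task_name),
        )
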