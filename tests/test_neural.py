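"""Tests for the feedforward engine: initialisation, forward arithmetic,
cost, backprop gradients, early stopping, warm starts, serialization."""

import numpy as np
import pytest

from conftest import labeled_table
from fjordsdm import neural
from fjordsdm.neural import (
    MLPModel,
    TrainConfig,
    bce_l1_cost,
    forward,
    init_mlp,
    load_mlp,
    save_mlp,
    train_mlp,
    update_monthly,
)


class TestInit:
    def test_same_seed_identical(self):
        a = init_mlp(7)
        b = init_mlp(7)
        assert all(np.array_equal(x, y) for x, y in zip(a.weights, b.weights))

    def test_different_seed_differs(self):
        a = init_mlp(7)
        b = init_mlp(8)
        assert any(not np.array_equal(x, y) for x, y in zip(a.weights, b.weights))

    def test_layer_shapes(self):
        m = init_mlp(0)
        shapes = [w.shape for w in m.weights]
        assert shapes == [(6, 16), (16, 32), (32, 64), (64, 1)]
        assert all(np.all(b == 0) for b in m.biases)

    def test_he_scale_per_layer(self):
        """Empirical weight sd matches sqrt(2 / fan_in) for each layer."""
        m = init_mlp(123, layer_sizes=(100, 200, 100, 1))
        for W in m.weights[:2]:  # large layers only, sd estimate is stable
            fan_in = W.shape[0]
            assert W.std() == pytest.approx(np.sqrt(2.0 / fan_in), rel=0.1)


class TestForward:
    def test_zero_network_outputs_half(self):
        m = init_mlp(0)
        for W in m.weights:
            W[:] = 0.0
        assert forward(m, np.zeros(6)) == pytest.approx(0.5)

    def test_relu_dead_zone_gives_sigmoid_of_output_bias(self):
        m = init_mlp(0)
        for W in m.weights:
            W[:] = 0.0
        for b in m.biases[:-1]:
            b[:] = -1.0  # hidden pre-activations negative -> ReLU outputs 0
        m.biases[-1][:] = 0.7
        expected = 1.0 / (1.0 + np.exp(-0.7))
        assert forward(m, np.ones(6)) == pytest.approx(expected, abs=1e-12)

    def test_hand_computed_2_2_1_network(self):
        m = init_mlp(0, layer_sizes=(2, 2, 1))
        m.weights[0] = np.array([[1.0, -2.0], [0.5, 1.0]])
        m.biases[0] = np.array([0.1, -0.2])
        m.weights[1] = np.array([[2.0], [-1.0]])
        m.biases[1] = np.array([0.3])
        x = np.array([1.0, 2.0])
        h = np.maximum(0.0, np.array([1.0 * 1 + 0.5 * 2 + 0.1, -2.0 * 1 + 1.0 * 2 - 0.2]))
        z = 2.0 * h[0] - 1.0 * h[1] + 0.3
        expected = 1.0 / (1.0 + np.exp(-z))
        assert forward(m, x) == pytest.approx(expected, abs=1e-12)

    def test_nonfinite_input_rejected(self):
        m = init_mlp(0)
        with pytest.raises(ValueError):
            forward(m, np.array([np.inf, 0, 0, 0, 0, 0]))


class TestCost:
    def test_perfect_prediction_zero_loss(self):
        m = init_mlp(0)
        for W in m.weights:
            W[:] = 0.0
        assert bce_l1_cost(np.array([1.0 - 1e-15]), np.array([1]), m, 0.0) == pytest.approx(0.0, abs=1e-9)

    def test_half_prediction_is_log_two(self):
        m = init_mlp(0)
        for W in m.weights:
            W[:] = 0.0
        assert bce_l1_cost(np.array([0.5]), np.array([0]), m, 0.0) == pytest.approx(np.log(2))

    def test_l1_term_linear(self):
        m = init_mlp(3)
        p = np.array([0.3, 0.6])
        y = np.array([0, 1])
        c0 = bce_l1_cost(p, y, m, 0.0)
        cs = bce_l1_cost(p, y, m, 0.01)
        assert cs - c0 == pytest.approx(0.01 * m.weight_l1(), rel=1e-10)

    def test_extreme_predictions_clipped_not_inf(self):
        m = init_mlp(0)
        c = bce_l1_cost(np.array([0.0, 1.0]), np.array([1, 0]), m, 0.0)
        assert np.isfinite(c)


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        """Analytic gradient vs central differences on a small harness."""
        rng = np.random.default_rng(11)
        m = init_mlp(5, layer_sizes=(2, 3, 2, 1))
        for b in m.biases:  # keep all pre-activations off the ReLU kink
            b[:] = rng.normal(0.3, 0.1, size=b.shape)
        X = rng.normal(size=(12, 2))
        y = rng.integers(0, 2, size=12).astype(float)
        l1 = 1e-3
        gW, gb = neural._gradients(m, X, y, l1)

        def cost():
            yhat = neural._forward_full(m, X)[-1].ravel()
            return bce_l1_cost(yhat, y, m, l1)

        eps = 1e-6
        for li in range(len(m.weights)):
            for idx in [(0, 0), (m.weights[li].shape[0] - 1, m.weights[li].shape[1] - 1)]:
                orig = m.weights[li][idx]
                m.weights[li][idx] = orig + eps
                cp = cost()
                m.weights[li][idx] = orig - eps
                cm = cost()
                m.weights[li][idx] = orig
                fd = (cp - cm) / (2 * eps)
                rel = abs(gW[li][idx] - fd) / max(abs(fd), 1e-8)
                assert rel < 1e-6, f"layer {li} weight {idx}"
            for bi in range(len(m.biases[li])):
                orig = m.biases[li][bi]
                m.biases[li][bi] = orig + eps
                cp = cost()
                m.biases[li][bi] = orig - eps
                cm = cost()
                m.biases[li][bi] = orig
                fd = (cp - cm) / (2 * eps)
                rel = abs(gb[li][bi] - fd) / max(abs(fd), 1e-8)
                assert rel < 1e-6, f"layer {li} bias {bi}"


def separable_table(n=20, seed=1):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 6))
    X[: n // 2, 0] += 6.0  # presences far away in the first covariate
    y = np.r_[np.ones(n // 2), np.zeros(n - n // 2)]
    return labeled_table(X, y)


class TestTraining:
    def test_separable_data_perfect_training_auc(self):
        from fjordsdm.evaluation import auc

        tab = separable_table()
        model = train_mlp(tab, TrainConfig(seed=2, learning_rate=0.3, l1_strength=0.0))
        scores = neural.predict_rows(model, tab.X)
        assert model.history[-1] < model.history[0]
        assert auc(scores[tab.y == 1], scores[tab.y == 0]) == 1.0

    def test_returned_cost_is_history_minimum(self, month_table):
        model = train_mlp(month_table, TrainConfig(seed=3, max_iterations=100))
        X = neural._standardize(month_table.X, model.standardization)
        yhat = neural._forward_full(model, X)[-1].ravel()
        final = bce_l1_cost(yhat, month_table.y.astype(float), model, 1e-4)
        assert final == pytest.approx(min(model.history), abs=1e-9)

    def test_l1_shrinks_weights(self):
        tab = separable_table(60, seed=4)
        free = train_mlp(tab, TrainConfig(seed=5, l1_strength=0.0))
        heavy = train_mlp(tab, TrainConfig(seed=5, l1_strength=10.0))
        assert heavy.weight_l1() < free.weight_l1()

    def test_zero_iterations_returns_warm_start_unchanged(self):
        tab = separable_table()
        base = train_mlp(tab, TrainConfig(seed=6, max_iterations=20))
        out = train_mlp(tab, TrainConfig(seed=7, max_iterations=0), warm_start=base)
        assert all(np.array_equal(a, b) for a, b in zip(out.weights, base.weights))
        assert all(np.array_equal(a, b) for a, b in zip(out.biases, base.biases))

    def test_early_stopping_before_max_iterations(self):
        tab = separable_table(40, seed=8)
        cfg = TrainConfig(seed=9, max_iterations=500, patience=5, learning_rate=0.5)
        model = train_mlp(tab, cfg)
        # history has initial cost + one entry per iteration actually run
        assert len(model.history) <= 501

    def test_exploding_cost_diagnosed(self):
        tab = separable_table(20, seed=10)
        with pytest.raises(FloatingPointError, match="learning_rate"):
            with np.errstate(over="ignore", invalid="ignore"):
                train_mlp(tab, TrainConfig(seed=11, learning_rate=1e20))


class TestMonthlyUpdate:
    def test_provenance_accumulates_in_order(self, small_world):
        from fjordsdm import projection

        cfg = TrainConfig(seed=12, max_iterations=30)
        model = None
        months = ["2018-05", "2018-06"]
        for mid in months:
            tab = projection.month_training_table(small_world[mid], seed=13)
            model = update_monthly(model, tab, cfg)
        assert model.provenance == months
        assert len(model.seed_chain) >= 2

    def test_empty_month_returns_previous(self):
        import pandas as pd

        from fjordsdm.covariates import COVARIATES
        from fjordsdm.maxent import TrainingTable

        tab = separable_table()
        prev = train_mlp(tab, TrainConfig(seed=14, max_iterations=20))
        empty = TrainingTable(pd.DataFrame(columns=[*COVARIATES, "label"]))
        out = update_monthly(prev, empty, TrainConfig(seed=15))
        assert out is prev

    def test_standardization_frozen_across_updates(self, small_world):
        from fjordsdm import projection

        cfg = TrainConfig(seed=16, max_iterations=20)
        tab1 = projection.month_training_table(small_world["2018-05"], seed=17)
        m1 = update_monthly(None, tab1, cfg)
        tab2 = projection.month_training_table(small_world["2018-06"], seed=17)
        m2 = update_monthly(m1, tab2, cfg)
        assert np.array_equal(m1.standardization[0], m2.standardization[0])
        assert np.array_equal(m1.standardization[1], m2.standardization[1])


class TestPredictStack:
    def test_constant_stack_constant_map(self, constant_stack, month_table):
        stack, _ = constant_stack
        model = train_mlp(month_table, TrainConfig(seed=18, max_iterations=20))
        out = neural.predict_mlp(model, stack)
        assert np.allclose(out.values, out.values.flat[0])
        assert 0.0 < out.values.flat[0] < 1.0

    def test_map_agrees_with_rowwise_forward(self, small_world):
        from fjordsdm import projection

        md = small_world["2018-05"]
        tab = projection.month_training_table(md, seed=19)
        model = train_mlp(tab, TrainConfig(seed=20, max_iterations=30))
        out = neural.predict_mlp(model, md.stack)
        arr = md.stack.as_array()
        nodata = md.stack.combined_nodata()
        rng = np.random.default_rng(21)
        valid_cells = np.argwhere(~nodata)
        for r, c in valid_cells[rng.choice(len(valid_cells), 5, replace=False)]:
            row = neural._standardize(arr[r, c], model.standardization)
            assert out.values[r, c] == pytest.approx(forward(model, row), abs=1e-12)

    def test_untrained_model_rejected(self, constant_stack):
        stack, _ = constant_stack
        with pytest.raises(RuntimeError):
            neural.predict_mlp(init_mlp(0), stack)


def test_serialization_round_trip_bit_exact(tmp_path):
    tab = separable_table(30, seed=22)
    model = train_mlp(tab, TrainConfig(seed=23, max_iterations=40))
    model.provenance = ["2018-05"]
    path = tmp_path / "mlp.json"
    save_mlp(model, path)
    back = load_mlp(path)
    assert all(np.array_equal(a, b) for a, b in zip(model.weights, back.weights))
    assert all(np.array_equal(a, b) for a, b in zip(model.biases, back.biases))
    assert np.array_equal(model.standardization[0], back.standardization[0])
    assert back.provenance == ["2018-05"]


def test_cross_check_against_sklearn_mlp():
    """An independent MLP implementation reaches a similar training AUC on
    the same separable data (sanity check, not weight equality)."""
    from sklearn.neural_network import MLPClassifier

    from fjordsdm.evaluation import auc

    tab = separable_table(60, seed=24)
    ours = train_mlp(tab, TrainConfig(seed=25, learning_rate=0.3, l1_strength=0.0))
    s = neural.predict_rows(ours, tab.X)
    ref = MLPClassifier(hidden_layer_sizes=(16, 32, 64), max_iter=2000, random_state=0)
    Xz = neural._standardize(tab.X, ours.standardization)
    ref.fit(Xz, tab.y)
    s_ref = ref.predict_proba(Xz)[:, 1]
    a_ours = auc(s[tab.y == 1], s[tab.y == 0])
    a_ref = auc(s_ref[tab.y == 1], s_ref[tab.y == 0])
    assert abs(a_ours - a_ref) < 0.05
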