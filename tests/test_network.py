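"""MLP and the five batch trainers: gradient oracle, LM limits, convergence."""

import numpy as np
import pytest

from piezopose import (NetworkError, TrainerConfig, TrainingDivergedError,
                       forward, hidden_neuron_heuristic, init_mlp,
                       loss_and_gradient, mse_loss, predict, train)
from piezopose.network import MlpModel, lm_step, residual_jacobian

CLASSES = ("normal", "slight_hunchback", "severe_hunchback")


def _toy_three_class(n_per=12, seed=0):
    """Well-separated 3-class point cloud in the unit 4-cube."""
    rng = np.random.default_rng(seed)
    centers = np.array([[0.1, 0.1, 0.2, 0.1],
                        [0.5, 0.5, 0.5, 0.5],
                        [0.9, 0.9, 0.8, 0.9]])
    X, y = [], []
    for ci, c in enumerate(centers):
        X.append(c + rng.normal(0, 0.03, (n_per, 4)))
        y += [CLASSES[ci]] * n_per
    return np.vstack(X), np.array(y, dtype=object)


def _xor_set():
    """XOR embedded in 4-D (two redundant coordinates), two classes."""
    X = np.array([[0, 0, 0, 0], [0, 1, 0, 1], [1, 0, 1, 0], [1, 1, 1, 1]], float)
    y = np.array(["normal", "slight_hunchback", "slight_hunchback", "normal"],
                 dtype=object)
    return X, y


class TestHiddenNeuronHeuristic:
    def test_default_slack_reproduces_four_neurons(self):
        assert hidden_neuron_heuristic(4, 3, 1) == 4  # round(sqrt(7)) + 1

    def test_max_slack(self):
        assert hidden_neuron_heuristic(4, 3, 10) == 13

    @pytest.mark.parametrize("slack", [0, 11])
    def test_slack_out_of_range(self, slack):
        with pytest.raises(NetworkError):
            hidden_neuron_heuristic(4, 3, slack)


class TestInitForward:
    def test_seed_determinism(self):
        a, b = init_mlp(seed=5), init_mlp(seed=5)
        np.testing.assert_array_equal(a.w1, b.w1)
        assert not np.array_equal(init_mlp(seed=6).w1, a.w1)

    def test_zero_hidden_layer_rejected(self):
        with pytest.raises(NetworkError):
            init_mlp(4, 0, 3)

    def test_zero_weights_give_half_scores(self):
        m = MlpModel(np.zeros((4, 4)), np.zeros(4), np.zeros((3, 4)), np.zeros(3))
        np.testing.assert_allclose(forward(m, np.zeros(4)), [0.5] * 3)

    def test_wrong_input_width_rejected(self):
        with pytest.raises(NetworkError):
            forward(init_mlp(seed=0), np.zeros(5))

    def test_scores_bounded_for_extreme_inputs(self):
        m = init_mlp(seed=1)
        for x in (np.full(4, 1e6), np.full(4, -1e6), np.zeros(4)):
            y = forward(m, x)
            assert np.all((y > 0) & (y < 1))


class TestGradientOracle:
    def test_backprop_matches_central_finite_differences(self):
        rng = np.random.default_rng(2)
        model = init_mlp(4, 5, 3, seed=2)
        X = rng.uniform(0, 1, (7, 4))
        T = np.eye(3)[rng.integers(0, 3, 7)]
        _, grad = loss_and_gradient(model, X, T)
        theta = model.pack()
        h = 1e-6
        fd = np.empty_like(theta)
        probe = model.copy()
        for i in range(len(theta)):
            tp = theta.copy(); tp[i] += h
            probe.unpack(tp); lp = mse_loss(probe, X, T)
            tm = theta.copy(); tm[i] -= h
            probe.unpack(tm); lmi = mse_loss(probe, X, T)
            fd[i] = (lp - lmi) / (2 * h)
        np.testing.assert_allclose(grad, fd, rtol=1e-6, atol=1e-10)

    def test_residual_jacobian_consistent_with_gradient(self):
        # grad(MSE) = 2/(n*m) * J^T r links the two derivative routes
        rng = np.random.default_rng(3)
        model = init_mlp(4, 4, 3, seed=3)
        X = rng.uniform(0, 1, (6, 4))
        T = np.eye(3)[rng.integers(0, 3, 6)]
        _, grad = loss_and_gradient(model, X, T)
        r, J = residual_jacobian(model, X, T)
        np.testing.assert_allclose(grad, 2.0 / r.size * (J.T @ r), rtol=1e-10)


class TestLevenbergMarquardt:
    def test_huge_damping_approaches_gradient_direction(self):
        rng = np.random.default_rng(4)
        model = init_mlp(4, 4, 3, seed=4)
        X = rng.uniform(0, 1, (10, 4))
        T = np.eye(3)[rng.integers(0, 3, 10)]
        _, grad = loss_and_gradient(model, X, T)
        step = lm_step(model, X, T, mu=1e9)
        cos = np.dot(step, grad) / (np.linalg.norm(step) * np.linalg.norm(grad))
        assert cos > 0.999

    def test_undamped_step_matches_independent_least_squares(self):
        # mu = 0 must reproduce the Gauss-Newton step solved by an
        # independent QR-based least-squares route
        rng = np.random.default_rng(5)
        model = init_mlp(4, 3, 3, seed=5)
        X = rng.uniform(0, 1, (20, 4))
        T = np.eye(3)[rng.integers(0, 3, 20)]
        r, J = residual_jacobian(model, X, T)
        expected, *_ = np.linalg.lstsq(J, r, rcond=None)
        got = lm_step(model, X, T, mu=0.0)
        np.testing.assert_allclose(got, expected, rtol=1e-6, atol=1e-9)

    def test_solves_xor_within_budget(self):
        X, y = _xor_set()
        model = init_mlp(4, 4, 3, seed=0)
        cfg = TrainerConfig(algorithm="lm", goal_mse=1e-3, max_epochs=200,
                            validation_fraction=0.0)
        fitted, hist = train(model, X, y, cfg, classes=CLASSES)
        assert hist.train_mse[-1] < 1e-3


class TestTraining:
    @pytest.mark.parametrize("algorithm", ["gda", "rp", "lm"])
    def test_loss_non_increasing_for_rejection_trainers(self, algorithm):
        X, y = _toy_three_class()
        cfg = TrainerConfig(algorithm=algorithm, learning_rate=0.05,
                            max_epochs=150, validation_fraction=0.0)
        _, hist = train(init_mlp(seed=1), X, y, cfg)
        mse = np.array(hist.train_mse)
        assert np.all(np.diff(mse) <= 1e-15)

    @pytest.mark.parametrize("algorithm", ["gd", "gdm", "gda", "rp", "lm"])
    def test_all_algorithms_fit_separable_data(self, algorithm):
        X, y = _toy_three_class()
        lr = 0.5 if algorithm in ("gd", "gdm") else 0.05
        cfg = TrainerConfig(algorithm=algorithm, learning_rate=lr,
                            goal_mse=0.02, max_epochs=6000,
                            validation_fraction=0.0)
        fitted, hist = train(init_mlp(seed=1), X, y, cfg)
        assert np.mean(predict(fitted, X) == y) == 1.0

    def test_bit_reproducible_given_seed_config_data(self):
        X, y = _toy_three_class()
        cfg = TrainerConfig(algorithm="lm", max_epochs=30, seed=9,
                            validation_fraction=0.15)
        m1, h1 = train(init_mlp(seed=9), X, y, cfg)
        m2, h2 = train(init_mlp(seed=9), X, y, cfg)
        np.testing.assert_array_equal(m1.pack(), m2.pack())
        assert h1.train_mse == h2.train_mse

    def test_single_class_data_rejected(self):
        X = np.random.default_rng(0).uniform(size=(10, 4))
        with pytest.raises(NetworkError):
            train(init_mlp(seed=0), X, ["normal"] * 10,
                  TrainerConfig(validation_fraction=0.0))

    def test_non_finite_loss_raises_with_history(self):
        X, y = _toy_three_class()
        X[0, 0] = np.nan  # poisons the forward pass -> non-finite loss
        cfg = TrainerConfig(algorithm="gd", max_epochs=50,
                            validation_fraction=0.0)
        with pytest.raises(TrainingDivergedError) as exc:
            train(init_mlp(seed=0), X, y, cfg)
        assert exc.value.history is not None

    def test_validation_patience_stops_early(self):
        X, y = _toy_three_class(n_per=20)
        cfg = TrainerConfig(algorithm="lm", max_epochs=500, goal_mse=0.0,
                            validation_fraction=0.2, patience=6, seed=0)
        _, hist = train(init_mlp(seed=0), X, y, cfg)
        assert hist.stop_reason in ("patience", "mu_overflow")
        assert hist.n_epochs < 500


class TestPredict:
    def test_argmax_and_tie_break(self):
        m = MlpModel(np.zeros((4, 4)), np.zeros(4), np.zeros((3, 4)), np.zeros(3))
        # all scores exactly 0.5 -> tie -> lowest class index
        assert predict(m, np.zeros(4)) == "normal"

    def test_training_set_recall_on_separable_toy(self):
        X, y = _toy_three_class()
        cfg = TrainerConfig(algorithm="lm", goal_mse=1e-3, max_epochs=200,
                            validation_fraction=0.0)
        fitted, _ = train(init_mlp(seed=3), X, y, cfg)
        assert np.mean(predict(fitted, X) == y) == 1.0

    def test_agrees_with_reference_classifier_on_easy_data(self):
        # independent baseline: a standard library MLP reaches the same
        # (perfect) decisions on clearly separated clusters
        sklearn = pytest.importorskip("sklearn.neural_network")
        X, y = _toy_three_class(n_per=20, seed=7)
        cfg = TrainerConfig(algorithm="lm", goal_mse=1e-3, max_epochs=200,
                            validation_fraction=0.0)
        ours, _ = train(init_mlp(seed=7), X, y, cfg)
        ref = sklearn.MLPClassifier(hidden_layer_sizes=(8,), random_state=0,
                                    max_iter=2000).fit(X, y.astype(str))
        np.testing.assert_array_equal(predict(ours, X).astype(str), ref.predict(X))
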