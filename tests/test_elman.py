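import numpy as np
import pytest

from plsca_elman.elman import (
    ElmanNet,
    TrainConfig,
    _sigmoid,
    decode_labels,
    hidden_size,
    make_bp_net,
    make_elman_net,
    predict_labels,
    sse,
    train_gdm,
    train_lm,
)


class TestHiddenSize:
    @pytest.mark.parametrize("n,m,expect", [(14, 1, 7), (6, 1, 5), (1, 1, 3)])
    def test_formula_values(self, n, m, expect):
        assert hidden_size(n, m) == expect

    def test_positive_sizes_required(self):
        with pytest.raises(ValueError):
            hidden_size(0, 1)


class TestForward:
    def test_zero_weight_net(self):
        net = make_elman_net(3, 1, 1, seed=0)
        net.set_params(np.zeros(net.n_params))
        net.w3 = np.array([[1.0]])
        y, x = net.forward([5.0, -2.0, 0.3])
        assert x[0] == pytest.approx(0.5)  # f(0)
        assert y[0] == pytest.approx(0.5)

    def test_context_stores_hidden_state(self, rng):
        net = make_elman_net(4, 3, 1, seed=1)
        _, x = net.forward(rng.normal(size=4))
        np.testing.assert_array_equal(net.context, x)

    def test_zero_w2_equals_feedforward(self, rng):
        elman = make_elman_net(5, 4, 2, seed=3)
        elman.w2 = np.zeros((4, 4))
        bp = make_bp_net(5, 4, 2, seed=3)
        for _ in range(4):
            u = rng.normal(size=5)
            ye, _ = elman.forward(u)
            yb, _ = bp.forward(u)
            np.testing.assert_allclose(ye, yb, atol=1e-12)

    def test_identity_context_feedback(self):
        net = make_elman_net(2, 3, 1, seed=0)
        net.w1 = np.zeros((3, 2))
        net.w2 = np.eye(3)
        net.b_hidden = np.zeros(3)
        net.context = np.ones(3)
        _, x = net.forward([0.0, 0.0])
        np.testing.assert_allclose(x, 1 / (1 + np.exp(-1.0)))

    def test_seed_identical_init_across_variants(self):
        a = make_elman_net(4, 3, 1, seed=9)
        b = make_bp_net(4, 3, 1, seed=9)
        np.testing.assert_array_equal(a.w1, b.w1)
        np.testing.assert_array_equal(a.w3, b.w3)
        np.testing.assert_array_equal(a.b_hidden, b.b_hidden)
        assert np.all(b.w2 == 0)


class TestSSE:
    @pytest.mark.parametrize(
        "t,y,expect", [([1, 0], [0.5, 0.5], 0.5), ([1, 2], [1, 2], 0.0), ([2], [-1], 9.0)]
    )
    def test_values(self, t, y, expect):
        assert sse(np.array(t, float), np.array(y, float)) == pytest.approx(expect)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            sse(np.ones(3), np.ones(4))


def truncated_outputs(net, theta, X, contexts):
    """Forward pass with frozen contexts at parameter vector theta (the
    model the Jacobian differentiates)."""
    saved = net.get_params()
    net.set_params(theta)
    H = _sigmoid(X @ net.w1.T + contexts @ net.w2.T + net.b_hidden)
    out = (H @ net.w3.T + net.b_output).ravel()
    net.set_params(saved)
    return out


class TestJacobian:
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_central_finite_differences(self, seed):
        g = np.random.default_rng(seed)
        sizes = [(3, 2, 1), (4, 3, 2), (2, 5, 1)][seed % 3]
        net = ElmanNet(*sizes, seed=seed, recurrent=bool(seed % 2))
        X = g.normal(size=(5, sizes[0]))
        contexts = net._batch_contexts(X, "reset")
        J, _ = net.jacobian(X, contexts)
        theta = net.get_params()
        h = 1e-6
        for i in range(len(theta)):
            tp, tm = theta.copy(), theta.copy()
            tp[i] += h
            tm[i] -= h
            fd = (
                truncated_outputs(net, tp, X, contexts)
                - truncated_outputs(net, tm, X, contexts)
            ) / (2 * h)
            scale = max(np.abs(fd).max(), 1e-8)
            assert np.abs(J[:, i] - fd).max() / scale < 1e-4


class TestTrainLM:
    def test_xor_learnable(self):
        X = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=float)
        T = np.array([[0.0], [1.0], [1.0], [0.0]])
        wins = 0
        for seed in range(10):
            net = make_elman_net(2, 3, 1, seed=seed)
            rep = train_lm(net, X, T, TrainConfig(max_epochs=200, goal_sse=0.005, seed=seed))
            wins += rep.final_sse < 0.01
        assert wins >= 8

    def test_accepted_sse_monotone(self, rng):
        X = rng.normal(size=(20, 3))
        T = rng.normal(size=(20, 1))
        net = make_elman_net(3, 4, 1, seed=0)
        rep = train_lm(net, X, T, TrainConfig(max_epochs=50))
        assert np.all(np.diff(rep.sse_trace) <= 0)

    def test_goal_already_met_returns_immediately(self, rng):
        X = rng.normal(size=(5, 2))
        net = make_elman_net(2, 2, 1, seed=1)
        T = net.predict(X)  # targets equal current outputs: SSE = 0
        rep = train_lm(net, X, T, TrainConfig(goal_sse=1e-6))
        assert rep.epochs_run == 0

    def test_deterministic_given_seed(self, rng):
        X = rng.normal(size=(10, 2))
        T = rng.normal(size=(10, 1))
        reps = []
        for _ in range(2):
            net = make_elman_net(2, 3, 1, seed=5)
            reps.append(train_lm(net, X, T, TrainConfig(max_epochs=30, seed=5)))
        assert reps[0].final_sse == reps[1].final_sse
        np.testing.assert_array_equal(reps[0].sse_trace, reps[1].sse_trace)

    def test_bp_net_trains_separable_problem(self):
        g = np.random.default_rng(0)
        X = np.vstack([g.normal(size=(20, 2)) - 3, g.normal(size=(20, 2)) + 3])
        T = np.repeat([[1.0], [2.0]], 20, axis=0)
        net = make_bp_net(2, 3, 1, seed=0)
        train_lm(net, X, T, TrainConfig(max_epochs=300))
        labels = predict_labels(net, X, np.array([1.0, 2.0]))
        assert np.mean(labels == T.ravel()) == 1.0


class TestTrainGDM:
    def test_single_step_matches_analytic_gradient(self):
        net = ElmanNet(1, 1, 1, seed=2, recurrent=False)
        X = np.array([[0.7]])
        T = np.array([[2.0]])
        w1, w3 = net.w1[0, 0], net.w3[0, 0]
        bh, bo = net.b_hidden[0], net.b_output[0]
        z = w1 * 0.7 + bh
        hsig = 1 / (1 + np.exp(-z))
        y = w3 * hsig + bo
        e = 2.0 - y
        # hand gradient of (t - y)^2 wrt each parameter
        gy = -2 * e
        grads = {
            "w1": gy * w3 * hsig * (1 - hsig) * 0.7,
            "w3": gy * hsig,
            "bh": gy * w3 * hsig * (1 - hsig),
            "bo": gy,
        }
        lr = 1e-4
        train_gdm(net, X, T, lr=lr, momentum=0.0, epochs=1)
        assert net.w1[0, 0] == pytest.approx(w1 - lr * grads["w1"], rel=1e-10)
        assert net.w3[0, 0] == pytest.approx(w3 - lr * grads["w3"], rel=1e-10)
        assert net.b_hidden[0] == pytest.approx(bh - lr * grads["bh"], rel=1e-10)
        assert net.b_output[0] == pytest.approx(bo - lr * grads["bo"], rel=1e-10)

    def test_zero_learning_rate_keeps_weights(self, rng):
        net = make_elman_net(2, 2, 1, seed=0)
        before = net.get_params()
        train_gdm(net, rng.normal(size=(6, 2)), rng.normal(size=(6, 1)), lr=0.0, epochs=5)
        np.testing.assert_array_equal(net.get_params(), before)

    def test_descent_for_small_lr(self, rng):
        net = make_elman_net(3, 3, 1, seed=4)
        X = rng.normal(size=(15, 3))
        T = rng.normal(size=(15, 1))
        rep = train_gdm(net, X, T, lr=1e-3, momentum=0.0, epochs=20)
        assert np.all(np.diff(rep.sse_trace) <= 1e-12)


class TestDecode:
    @pytest.mark.parametrize(
        "out,classes,expect",
        [
            (1.4, [1, 2, 3], 1),
            (1.5, [1, 2], 1),  # tie goes to the lower class
            (-7.0, [1, 2, 3], 1),  # clamped to nearest
            (2.6, [1, 2, 3], 3),
        ],
    )
    def test_nearest_class(self, out, classes, expect):
        got = decode_labels(np.array([out]), np.array(classes, dtype=float))
        assert got[0] == expect

    def test_empty_class_set(self):
        with pytest.raises(ValueError):
            decode_labels(np.array([1.0]), np.array([]))
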