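import numpy as np
import pytest

from petbpnn.bpnn import (
    NetworkConfig,
    NetworkState,
    _epoch_python,
    backprop_step,
    forward,
    init_state,
    load_model,
    predict,
    save_model,
    train,
)
from petbpnn.exceptions import ShapeError, ValidationError

try:
    from petbpnn.bpnn import _epoch_jit
except ImportError:
    _epoch_jit = None


def small_cfg(**kw):
    defaults = dict(n_input=3, n_hidden=4, n_output=2, learning_rate=0.1,
                    momentum=0.0, seed=1)
    defaults.update(kw)
    return NetworkConfig(**defaults)


def squared_error(state, x, t):
    o = forward(state, x)
    return 0.5 * np.sum((t - o) ** 2)


def numeric_gradient(state, x, t, h=1e-5):
    """Central-difference gradient of 0.5*sum((t-o)^2) wrt every weight."""
    grads = []
    for w in (state.w_ih, state.w_ho):
        g = np.zeros_like(w)
        it = np.nditer(w, flags=["multi_index"])
        while not it.finished:
            idx = it.multi_index
            orig = w[idx]
            w[idx] = orig + h
            ep = squared_error(state, x, t)
            w[idx] = orig - h
            em = squared_error(state, x, t)
            w[idx] = orig
            g[idx] = (ep - em) / (2 * h)
            it.iternext()
        grads.append(g)
    return grads


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            dict(n_hidden=0),
            dict(learning_rate=0.0),
            dict(momentum=1.0),
            dict(momentum=-0.1),
            dict(min_rms=0.0),
            dict(activation="tanh"),
            dict(max_epochs=0),
        ],
    )
    def test_invalid(self, kw):
        with pytest.raises(ValidationError):
            NetworkConfig(**kw)


class TestInitState:
    def test_deterministic(self):
        cfg = NetworkConfig(seed=42)
        a, b = init_state(cfg), init_state(cfg)
        assert np.array_equal(a.w_ih, b.w_ih)
        assert np.array_equal(a.w_ho, b.w_ho)

    def test_default_topology_shapes(self):
        s = init_state(NetworkConfig())
        assert s.w_ih.shape == (401, 45)
        assert s.w_ho.shape == (46, 2)

    def test_momentum_buffers_zero(self):
        s = init_state(NetworkConfig(seed=3))
        assert not s.prev_delta_ih.any()
        assert not s.prev_delta_ho.any()

    def test_weight_range(self):
        s = init_state(NetworkConfig(seed=7))
        for w in (s.w_ih, s.w_ho):
            assert w.min() >= -0.5 and w.max() <= 0.5

    def test_no_bias_rows_zero(self):
        s = init_state(NetworkConfig(use_bias=False, seed=0))
        assert not s.w_ih[-1].any() and not s.w_ho[-1].any()


class TestForward:
    def test_zero_weights_give_half(self):
        s = init_state(small_cfg())
        s.w_ih[:] = 0.0
        s.w_ho[:] = 0.0
        assert np.allclose(forward(s, np.ones(3)), 0.5)

    def test_1_1_1_hand_evaluation(self):
        cfg = NetworkConfig(n_input=1, n_hidden=1, n_output=1, seed=0)
        s = init_state(cfg)
        s.w_ih[:] = [[1.0], [0.0]]  # w=1, b=0
        s.w_ho[:] = [[1.0], [0.0]]  # v=1, c=0
        out = forward(s, np.array([0.0]))
        # hidden = sigma(0) = 0.5; output = sigma(0.5)
        assert np.allclose(out, 0.6224593312018546)

    def test_outputs_strictly_inside_unit_interval(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            s = init_state(small_cfg(seed=int(rng.integers(1000))))
            o = forward(s, rng.uniform(-2, 2, 3))
            assert np.all((o > 0) & (o < 1))

    def test_shape_mismatch(self):
        s = init_state(small_cfg())
        with pytest.raises(ShapeError):
            forward(s, np.ones(5))


class TestPredict:
    def test_argmax(self):
        s = init_state(small_cfg())
        s.w_ih[:] = 0.0
        s.w_ho[:] = 0.0
        s.w_ho[-1] = [2.0, -2.0]  # outputs (0.88, 0.12)
        assert predict(s, np.zeros(3)) == 0
        s.w_ho[-1] = [-2.0, 2.0]
        assert predict(s, np.zeros(3)) == 1

    def test_tie_goes_to_lower_index(self):
        s = init_state(small_cfg())
        s.w_ih[:] = 0.0
        s.w_ho[:] = 0.0  # both outputs exactly 0.5
        assert predict(s, np.zeros(3)) == 0


class TestBackpropStep:
    def test_zero_error_fixed_point(self):
        s = init_state(small_cfg())
        s.w_ih[:] = 0.0
        s.w_ho[:] = 0.0  # outputs exactly (0.5, 0.5)
        new = backprop_step(s, np.array([0.3, -0.2, 0.1]), [0.5, 0.5], small_cfg())
        assert np.array_equal(new.w_ih, s.w_ih)
        assert np.array_equal(new.w_ho, s.w_ho)

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(123)
        cfg = small_cfg(learning_rate=0.01)
        for _ in range(10):
            s = init_state(small_cfg(seed=int(rng.integers(10_000))))
            x = rng.uniform(0, 1, 3)
            t = np.zeros(2)
            t[rng.integers(2)] = 1.0
            new = backprop_step(s, x, t, cfg)
            for w_new, w_old, g_num in zip(
                (new.w_ih, new.w_ho), (s.w_ih, s.w_ho), numeric_gradient(s, x, t)
            ):
                g_analytic = -(w_new - w_old) / cfg.learning_rate
                assert np.linalg.norm(g_analytic - g_num) <= 1e-6 * np.linalg.norm(g_num)

    def test_relu_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(99)
        cfg = small_cfg(learning_rate=0.01, activation="relu")
        for _ in range(10):
            s = init_state(small_cfg(seed=int(rng.integers(10_000)), activation="relu"))
            x = rng.uniform(0.1, 1, 3)
            t = np.array([1.0, 0.0])
            new = backprop_step(s, x, t, cfg)
            for w_new, w_old, g_num in zip(
                (new.w_ih, new.w_ho), (s.w_ih, s.w_ho), numeric_gradient(s, x, t)
            ):
                g_analytic = -(w_new - w_old) / cfg.learning_rate
                assert np.linalg.norm(g_analytic - g_num) <= 1e-5 * max(
                    np.linalg.norm(g_num), 1e-8
                )

    def test_momentum_recurrence(self):
        # second of two identical updates carries 0.9x the first step
        cfg = small_cfg(learning_rate=0.05, momentum=0.9)
        x = np.array([0.5, 0.1, 0.9])
        t = np.array([1.0, 0.0])
        s0 = init_state(cfg)
        s1 = backprop_step(s0, x, t, cfg)
        d1_ih = s1.w_ih - s0.w_ih
        d1_ho = s1.w_ho - s0.w_ho
        # plain-gradient part of the second step, from a momentum-free state
        s1_nomom = s1.copy()
        s1_nomom.prev_delta_ih[:] = 0.0
        s1_nomom.prev_delta_ho[:] = 0.0
        g2_ih = backprop_step(s1_nomom, x, t, small_cfg(learning_rate=0.05)).w_ih - s1.w_ih
        g2_ho = backprop_step(s1_nomom, x, t, small_cfg(learning_rate=0.05)).w_ho - s1.w_ho
        s2 = backprop_step(s1, x, t, cfg)
        assert np.allclose(s2.w_ih - s1.w_ih, g2_ih + 0.9 * d1_ih, atol=1e-12)
        assert np.allclose(s2.w_ho - s1.w_ho, g2_ho + 0.9 * d1_ho, atol=1e-12)

    def test_descent_on_single_pattern(self):
        rng = np.random.default_rng(21)
        cfg = small_cfg(learning_rate=0.01)
        for _ in range(10):
            s = init_state(small_cfg(seed=int(rng.integers(10_000))))
            x = rng.uniform(0, 1, 3)
            t = np.array([0.0, 1.0])
            before = squared_error(s, x, t)
            after = squared_error(backprop_step(s, x, t, cfg), x, t)
            assert after < before

    def test_shape_errors(self):
        s = init_state(small_cfg())
        with pytest.raises(ShapeError):
            backprop_step(s, np.ones(7), [1, 0], small_cfg())
        with pytest.raises(ShapeError):
            backprop_step(s, np.ones(3), [1, 0, 0], small_cfg())


@pytest.mark.skipif(_epoch_jit is None, reason="numba unavailable")
class TestEpochKernels:
    def test_jit_matches_python_reference(self):
        rng = np.random.default_rng(8)
        for relu in (False, True):
            for use_bias in (True, False):
                X = rng.uniform(0, 1, (6, 5))
                T = np.zeros((6, 2))
                T[np.arange(6), rng.integers(0, 2, 6)] = 1.0
                cfg = NetworkConfig(
                    n_input=5, n_hidden=3, learning_rate=0.1, momentum=0.7,
                    activation="relu" if relu else "logistic_sigmoid",
                    use_bias=use_bias, seed=2,
                )
                order = rng.permutation(6)
                args = []
                for fn in (_epoch_python, _epoch_jit):
                    s = init_state(cfg)
                    fn(X, T, s.w_ih, s.w_ho, s.prev_delta_ih, s.prev_delta_ho,
                       order, cfg.learning_rate, cfg.momentum, relu, use_bias)
                    args.append(s)
                assert np.allclose(args[0].w_ih, args[1].w_ih, atol=1e-12)
                assert np.allclose(args[0].w_ho, args[1].w_ho, atol=1e-12)
                assert np.allclose(args[0].prev_delta_ih, args[1].prev_delta_ih, atol=1e-12)


def toy_blobs(n=40, sep=10.0, seed=0):
    """Two Gaussian blobs separated by sep standard deviations."""
    rng = np.random.default_rng(seed)
    sigma = 0.03
    xs, ys = [], []
    for cls, mu in ((0, 0.3), (1, 0.3 + sep * sigma)):
        for _ in range(n // 2):
            xs.append(rng.normal(mu, sigma, 2))
            ys.append(cls)
    return list(zip(xs, ys))


class TestTrain:
    def test_converges_on_separable_blobs(self):
        data = toy_blobs()
        cfg = NetworkConfig(
            n_input=2, n_hidden=8, learning_rate=0.5, momentum=0.9,
            min_rms=0.003, max_epochs=20_000, seed=4,
        )
        result = train(data, cfg)
        assert result.converged
        assert result.final_rms <= 0.003
        preds = [predict(result.state, x) for x, _ in data]
        assert preds == [y for _, y in data]  # 100% training accuracy

    def test_rms_history_reproducible(self):
        data = toy_blobs(seed=3)
        cfg = NetworkConfig(n_input=2, n_hidden=5, learning_rate=0.3,
                            momentum=0.5, max_epochs=50, min_rms=1e-9, seed=11)
        a = train(data, cfg)
        b = train(data, cfg)
        assert a.rms_history == b.rms_history
        assert a.epochs_run == b.epochs_run

    def test_invariants_of_result(self):
        data = toy_blobs(seed=5)
        cfg = NetworkConfig(n_input=2, n_hidden=5, learning_rate=0.3,
                            momentum=0.5, max_epochs=30, min_rms=1e-9, seed=1)
        r = train(data, cfg)
        assert r.epochs_run <= cfg.max_epochs
        assert r.converged == (r.final_rms <= cfg.min_rms)
        assert len(r.rms_history) == r.epochs_run

    def test_relu_hidden_trains(self):
        data = toy_blobs(seed=6)
        cfg = NetworkConfig(n_input=2, n_hidden=8, learning_rate=0.1,
                            momentum=0.9, activation="relu",
                            max_epochs=5_000, min_rms=0.05, seed=2)
        r = train(data, cfg)
        o = forward(r.state, data[0][0])
        assert np.all((o > 0) & (o < 1))  # output layer stays sigmoid
        preds = [predict(r.state, x) for x, _ in data]
        acc = np.mean([p == y for p, (_, y) in zip(preds, data)])
        assert acc >= 0.9

    def test_empty_data_rejected(self):
        with pytest.raises(ValidationError):
            train([], small_cfg())

    def test_single_class_rejected(self):
        data = [(np.ones(3), 0), (np.zeros(3), 0)]
        with pytest.raises(ValidationError):
            train(data, small_cfg())

    def test_model_persistence_round_trip(self, tmp_path):
        data = toy_blobs(seed=8)
        cfg = NetworkConfig(n_input=2, n_hidden=4, learning_rate=0.3,
                            momentum=0.5, max_epochs=20, min_rms=1e-9, seed=9)
        r = train(data, cfg)
        path = tmp_path / "model.json"
        save_model(r, cfg, path)
        state, cfg2 = load_model(path)
        assert cfg2 == cfg
        x = data[0][0]
        assert np.array_equal(forward(state, x), forward(r.state, x))
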