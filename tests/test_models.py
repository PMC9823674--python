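"""Network regressors: parameter counts, gradients, training, persistence."""

import numpy as np
import pytest

from myogait.nn import (
    FNNEstimator,
    LSTMEstimator,
    ModelConfig,
    build_estimator,
    load_estimator,
    train,
)

N_IN_FLAT = 101 * 24


def _cfg(**kw):
    base = dict(architecture="fnn", hidden_layers=2, hidden_units=16,
                dropout_rate=0.0, learning_rate=3e-3, batch_size=16,
                max_epochs=30, early_stop_patience=30, seed=0)
    base.update(kw)
    return ModelConfig(**base)


class _FNN64(FNNEstimator):
    dtype = np.float64


class _LSTM64(LSTMEstimator):
    dtype = np.float64


class TestConfig:
    def test_validation(self):
        with pytest.raises(ValueError, match="architecture"):
            ModelConfig(architecture="cnn")
        with pytest.raises(ValueError, match="dropout"):
            ModelConfig(dropout_rate=1.0)
        with pytest.raises(ValueError, match="activations"):
            ModelConfig(hidden_activation="relu")
        with pytest.raises(ValueError, match="optimizer"):
            ModelConfig(optimizer="sgd")
        with pytest.raises(ValueError, match="hidden_layers"):
            ModelConfig(hidden_layers=0)

    def test_build_dispatch(self):
        assert isinstance(build_estimator(_cfg(), (N_IN_FLAT,)), FNNEstimator)
        assert isinstance(
            build_estimator(_cfg(architecture="lstm"), (101, 24)), LSTMEstimator
        )


class TestParameterCounts:
    def test_fnn_closed_form(self):
        # dims 2424 -> 64 -> 64 -> 101, dense layers with biases
        est = FNNEstimator(_cfg(hidden_layers=2, hidden_units=64), (N_IN_FLAT,))
        expected = (N_IN_FLAT * 64 + 64) + (64 * 64 + 64) + (64 * 101 + 101)
        assert est.num_params == expected

    def test_lstm_closed_form(self):
        # one layer, H=8, 24 inputs: 4 gates x (24*8 + 8*8 + 8), plus output head
        est = LSTMEstimator(_cfg(architecture="lstm", hidden_layers=1,
                                 hidden_units=8), (101, 24))
        expected = 4 * (24 * 8 + 8 * 8 + 8) + (8 * 101 + 101)
        assert est.num_params == expected

    def test_lstm_stacked_second_layer_input_is_hidden(self):
        est = LSTMEstimator(_cfg(architecture="lstm", hidden_layers=2,
                                 hidden_units=8), (101, 24))
        per_layer1 = 4 * (24 * 8 + 8 * 8 + 8)
        per_layer2 = 4 * (8 * 8 + 8 * 8 + 8)
        assert est.num_params == per_layer1 + per_layer2 + (8 * 101 + 101)

    def test_lstm_forget_gate_bias_one(self):
        est = LSTMEstimator(_cfg(architecture="lstm", hidden_units=8), (101, 24))
        b = est.params["b0"]
        np.testing.assert_array_equal(b[8:16], 1.0)   # forget-gate block
        np.testing.assert_array_equal(b[:8], 0.0)


def _numerical_grad_check(est, x, y, n_probe=60, tol=1e-5):
    """Analytic gradients vs central finite differences on random entries."""
    rng = np.random.default_rng(0)
    y_hat, cache = est._forward(x, train=False)
    dy = 2.0 * (y_hat - y) / y_hat.size
    grads = est._backward(cache, dy)
    eps = 1e-6
    worst = 0.0
    for _ in range(n_probe):
        key = rng.choice(sorted(grads))
        flat_idx = rng.integers(est.params[key].size)
        idx = np.unravel_index(flat_idx, est.params[key].shape)
        orig = est.params[key][idx]
        est.params[key][idx] = orig + eps
        lp = est._loss(est._forward(x, train=False)[0], y)
        est.params[key][idx] = orig - eps
        lm = est._loss(est._forward(x, train=False)[0], y)
        est.params[key][idx] = orig
        num = (lp - lm) / (2 * eps)
        ana = grads[key][idx]
        rel = abs(num - ana) / max(abs(num), abs(ana), 1e-8)
        worst = max(worst, rel)
    assert worst < tol, f"max relative gradient error {worst:.2e}"


class TestGradients:
    def test_fnn_matches_finite_differences(self, rng):
        est = _FNN64(_cfg(hidden_units=8), (30,))
        x = rng.normal(size=(5, 30))
        y = rng.uniform(0.2, 0.8, size=(5, 101))
        _numerical_grad_check(est, x, y)

    def test_lstm_matches_finite_differences(self, rng):
        est = _LSTM64(_cfg(architecture="lstm", hidden_layers=2,
                           hidden_units=6), (12, 4))
        x = rng.normal(size=(4, 12, 4))
        y = rng.uniform(0.2, 0.8, size=(4, 101))
        _numerical_grad_check(est, x, y)


class TestTraining:
    def test_output_in_unit_interval(self, rng):
        est = FNNEstimator(_cfg(), (N_IN_FLAT,))
        out = est.predict(rng.normal(size=(3, N_IN_FLAT)))
        assert np.all(out > 0.0) and np.all(out < 1.0)

    def test_fits_constant_target(self, rng):
        est = FNNEstimator(_cfg(max_epochs=250, learning_rate=1e-2), (10,))
        x = rng.normal(size=(64, 10))
        y = np.full((64, 101), 0.3)
        est.fit(x[:48], y[:48], x[48:], y[48:])
        np.testing.assert_allclose(est.predict(x[:48]), 0.3, atol=0.02)

    @pytest.mark.parametrize("arch,shape", [("fnn", (8, 3)), ("lstm", (8, 3))])
    def test_val_loss_drops_tenfold_on_learnable_map(self, arch, shape, rng):
        """Noiseless smooth target of the channel means over the sequence:
        training must reduce validation MSE by at least 10x from its initial
        value, for both architectures."""
        n = 160
        x = rng.normal(size=(n, *shape))
        w = rng.normal(size=(shape[-1], 101))
        y = 1.0 / (1.0 + np.exp(-3.0 * x.mean(axis=1) @ w))
        est = build_estimator(
            _cfg(architecture=arch, hidden_units=24, max_epochs=200,
                 learning_rate=5e-3), shape if arch == "lstm" else
            (int(np.prod(shape)),)
        )
        if arch == "fnn":
            x = x.reshape(n, -1)
        xv, yv = x[128:], y[128:]
        initial = est._loss(est.predict(xv), yv)
        est.fit(x[:128], y[:128], xv, yv)
        final = est._loss(est.predict(xv), yv)
        assert final < initial / 10.0

    def test_deterministic_under_seed(self, rng):
        x = rng.normal(size=(40, 10))
        y = rng.uniform(0.2, 0.8, size=(40, 101))

        def fit_once():
            est = FNNEstimator(_cfg(max_epochs=5, dropout_rate=0.2), (10,))
            est.fit(x[:32], y[:32], x[32:], y[32:])
            return est.predict(x[32:])

        np.testing.assert_array_equal(fit_once(), fit_once())

    def test_predict_single_equals_batch(self, rng):
        est = LSTMEstimator(_cfg(architecture="lstm", hidden_units=8), (101, 24))
        x = rng.normal(size=(6, 101, 24))
        batch = est.predict(x)
        assert batch.shape == (6, 101)
        single = est.predict(x[2])
        assert single.shape == (101,)
        np.testing.assert_allclose(single, batch[2], rtol=1e-5, atol=1e-7)

    def test_non_finite_loss_raises_informative_error(self, rng):
        # bounded activations keep the loss finite under any learning rate,
        # so the guard is exercised with non-finite inputs instead
        est = FNNEstimator(_cfg(max_epochs=5), (10,))
        x = rng.normal(size=(40, 10))
        x[3, 4] = np.nan
        y = rng.uniform(size=(40, 101))
        with pytest.raises(RuntimeError, match="non-finite loss"):
            est.fit(x[:32], y[:32], x[32:], y[32:])

    def test_early_stopping_restores_best_weights(self, rng):
        est = FNNEstimator(_cfg(max_epochs=40, early_stop_patience=3), (10,))
        x = rng.normal(size=(60, 10))
        y = rng.uniform(0.3, 0.7, size=(60, 101))  # pure noise target
        est.fit(x[:48], y[:48], x[48:], y[48:])
        val = est.history["val_loss"]
        final = est._loss(est.predict(x[48:]), y[48:])
        assert final == pytest.approx(min(val), rel=1e-5)

    def test_train_helper_on_split(self, small_samples):
        from myogait.datasets import split_dataset

        split = split_dataset(small_samples, seed=0)
        est = build_estimator(
            _cfg(architecture="lstm", hidden_units=8, max_epochs=2), (101, 24)
        )
        train(est, split, "soleus")
        assert est.muscle == "soleus"
        assert len(est.history["val_loss"]) >= 1


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path, rng):
        est = LSTMEstimator(_cfg(architecture="lstm", hidden_units=8), (101, 24))
        est.muscle = "soleus"
        x = rng.normal(size=(3, 101, 24))
        est.save(tmp_path / "model")
        back = load_estimator(tmp_path / "model")
        assert isinstance(back, LSTMEstimator)
        assert back.muscle == "soleus"
        assert back.config == est.config
        np.testing.assert_array_equal(back.predict(x), est.predict(x))
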