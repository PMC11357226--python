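"""Surrogate network: initialization, gradients, training, prediction."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import extraopt as eo
from extraopt.ann import (DivergenceError, MinMaxScaler, NotFittedError,
                          _gradients, _split_indices)


def small_design(n=20, seed=0):
    """1-factor dataset with a linear target y = 2x."""
    rng = np.random.default_rng(seed)
    x = np.linspace(-1, 1, n).reshape(-1, 1)
    factors = [eo.FactorSpec("x", -1, 0, 1)]
    return eo.DesignTable.from_coded(factors, x, response=2.0 * x[:, 0])


class TestInit:
    def test_seeded_determinism(self):
        cfg = eo.AnnConfig(seed=42)
        m1, m2 = eo.init_network(cfg), eo.init_network(cfg)
        for w1, w2 in zip(m1.weights, m2.weights):
            np.testing.assert_array_equal(w1, w2)

    def test_zero_weights_output_is_bias(self):
        m = eo.init_network(eo.AnnConfig(seed=0))
        m.w_hidden[:] = 0
        m.b_hidden[:] = 0
        m.w_out[:] = 0
        m.b_out[:] = 0.37
        out = m.forward_scaled(np.zeros((3, 4)))
        np.testing.assert_allclose(out, 0.37)

    def test_fan_in_bound_over_seeds(self):
        for seed in range(100):
            m = eo.init_network(eo.AnnConfig(seed=seed))
            assert np.max(np.abs(m.w_hidden)) <= 1 / np.sqrt(4)
            assert np.max(np.abs(m.b_hidden)) <= 1 / np.sqrt(4)
            assert np.max(np.abs(m.w_out)) <= 1 / np.sqrt(9)


@pytest.mark.parametrize("shape", [(2, 3, 1), (4, 9, 1), (3, 5, 2)])
def test_gradients_match_finite_differences(shape, rng):
    """Analytic backprop vs central differences on random small networks."""
    ni, nh, no = shape
    cfg = eo.AnnConfig(n_inputs=ni, n_hidden=nh, n_outputs=no, seed=3)
    model = eo.init_network(cfg)
    xs = rng.uniform(-1, 1, (7, ni))
    ts = rng.uniform(-1, 1, (7, no))
    grads, _ = _gradients(model, xs, ts)

    def loss():
        return float(np.mean((model.forward_scaled(xs) - ts) ** 2))

    h = 1e-6
    for g, w in zip(grads, model.weights):
        it = np.nditer(w, flags=["multi_index"])
        for _ in it:
            ix = it.multi_index
            orig = w[ix]
            w[ix] = orig + h
            up = loss()
            w[ix] = orig - h
            down = loss()
            w[ix] = orig
            fd = (up - down) / (2 * h)
            assert g[ix] == pytest.approx(fd, rel=1e-5, abs=1e-8)


def test_single_step_is_gradient_descent(table1):
    """With zero momentum one epoch moves weights by exactly -lr * grad."""
    cfg = eo.AnnConfig(seed=5, momentum=0.0, max_epochs=1, split=(1.0, 0.0, 0.0),
                       learning_rate=0.1)
    m0 = eo.init_network(cfg)
    trained = eo.train(m0, table1, cfg)
    # recompute the expected gradient on the scaled full batch
    xs = trained.input_scaler.transform(table1.coded)
    ts = trained.output_scaler.transform(table1.response.reshape(-1, 1))
    grads, _ = _gradients(m0, xs, ts)
    for w0, w1, g in zip(m0.weights, trained.weights, grads):
        np.testing.assert_allclose(w1 - w0, -cfg.learning_rate * g,
                                   rtol=1e-12, atol=1e-12)


def test_small_step_descent_property(table1):
    """Momentum 0, tiny learning rate: the training MSE never increases."""
    cfg = eo.AnnConfig(seed=2, momentum=0.0, learning_rate=1e-3,
                       max_epochs=300, split=(1.0, 0.0, 0.0))
    model = eo.fit_surrogate(table1, cfg)
    mse = model.history["mse_train"].to_numpy()
    assert np.all(np.diff(mse) <= 1e-12)


def test_linear_target_is_learned():
    d = small_design()
    cfg = eo.AnnConfig(n_inputs=1, seed=1, max_epochs=5000, split=(1.0, 0.0, 0.0))
    model = eo.fit_surrogate(d, cfg)
    assert model.history["mse_train"].iloc[-1] < 1e-3


def test_training_determinism(table1):
    cfg = eo.AnnConfig(seed=11, max_epochs=50)
    m1 = eo.fit_surrogate(table1, cfg)
    m2 = eo.fit_surrogate(table1, cfg)
    for w1, w2 in zip(m1.weights, m2.weights):
        np.testing.assert_array_equal(w1, w2)
    pd.testing.assert_frame_equal(m1.history, m2.history)


def test_early_stopping_restores_best(table1):
    cfg = eo.AnnConfig(seed=0, max_epochs=5000, patience=6)
    model = eo.fit_surrogate(table1, cfg)
    hist = model.history
    assert len(hist) < 5000  # stopped early
    # returned weights correspond to the best recorded validation MSE
    xs = model.input_scaler.transform(table1.coded)
    ts = model.output_scaler.transform(table1.response.reshape(-1, 1))
    rng = np.random.default_rng(cfg.seed)
    _, va, _ = _split_indices(29, cfg.split, rng)
    mse_va = float(np.mean((model.forward_scaled(xs[va]) - ts[va]) ** 2))
    assert mse_va == pytest.approx(hist["mse_val"].min(), rel=1e-9)


def test_full_data_training_fits_reference(table1):
    """Trained on all 29 runs the 4-9-1 network nearly interpolates."""
    cfg = eo.AnnConfig(seed=0, max_epochs=1000, split=(1.0, 0.0, 0.0))
    model = eo.fit_surrogate(table1, cfg)
    r2 = eo.fit_metrics(table1, eo.predict_ann(model, table1.coded))["r_squared"]
    assert r2 >= 0.98


@pytest.mark.filterwarnings("ignore:overflow")
def test_divergence_error(table1):
    cfg = eo.AnnConfig(seed=0, learning_rate=1e3, max_epochs=2000,
                       split=(1.0, 0.0, 0.0))
    with pytest.raises(DivergenceError):
        eo.fit_surrogate(table1, cfg)


def test_unfitted_model_refuses_to_predict():
    m = eo.init_network(eo.AnnConfig())
    with pytest.raises(NotFittedError):
        eo.predict_ann(m, np.zeros(4))


def test_scaler_round_trip(rng):
    x = rng.uniform(-5, 30, (40, 4))
    sc = MinMaxScaler().fit(x)
    np.testing.assert_allclose(sc.inverse(sc.transform(x)), x, atol=1e-12)
    assert sc.transform(x).min() == pytest.approx(-1)
    assert sc.transform(x).max() == pytest.approx(1)


def test_linear_network_equals_affine_composition(table1, rng):
    """With identity activations the network is the explicit affine map."""
    cfg = eo.AnnConfig(seed=4, hidden_activation="identity",
                       output_activation="identity", max_epochs=5)
    model = eo.fit_surrogate(table1, cfg)
    pts = rng.uniform(-1, 1, (6, 4))
    xs = model.input_scaler.transform(pts)
    expect = (xs @ model.w_hidden + model.b_hidden) @ model.w_out + model.b_out
    np.testing.assert_allclose(model.forward_scaled(xs), expect, rtol=1e-12)


class TestFrozenFixture:
    def test_center_prediction_regression(self, frozen_ann):
        """Golden value recorded when the fixture was frozen."""
        assert eo.predict_ann(frozen_ann, np.zeros(4)) == pytest.approx(
            121.518, abs=1e-6)

    def test_fit_quality(self, table1, frozen_ann):
        r2 = eo.fit_metrics(
            table1, eo.predict_ann(frozen_ann, table1.coded))["r_squared"]
        assert r2 >= 0.98

    def test_json_round_trip_bit_exact(self, frozen_ann, tmp_path, rng):
        path = tmp_path / "m.json"
        eo.save_model(frozen_ann, path)
        loaded = eo.load_model(path)
        pts = rng.uniform(-1, 1, (10, 4))
        np.testing.assert_array_equal(eo.predict_ann(frozen_ann, pts),
                                      eo.predict_ann(loaded, pts))


def test_invalid_configs():
    with pytest.raises(ValueError):
        eo.AnnConfig(learning_rate=0.0)
    with pytest.raises(ValueError):
        eo.AnnConfig(momentum=1.0)
    with pytest.raises(ValueError):
        eo.AnnConfig(split=(0.5, 0.5, 0.5))
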