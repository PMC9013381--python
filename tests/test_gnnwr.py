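import numpy as np
import pandas as pd
import pytest

from downwood import data_core, glm, simulate
from downwood.diagnostics import coefficient_summary
from downwood.gnnwr import (
    GNNWRFit,
    SWNNConfig,
    SWNNModel,
    TrainConfig,
    build_swnn,
    default_swnn_config,
    default_train_config,
    local_coefficients,
    predict_gnnwr,
    swnn_weights,
    train_gnnwr,
)


def _tiny_split(seed=0, n=90, n_train=70):
    cfg = simulate.StudyConfig(n_units=n, n_train=n_train, extent=3000.0)
    ds, truth = simulate.generate_study(cfg, seed)
    train, val = data_core.split_train_validation(ds, n_train, seed)
    train_std, p = data_core.standardize(train)
    val_std, _ = data_core.standardize(val, p)
    return train_std, val_std, truth, train


FAST = TrainConfig(learning_rate=0.003, batch_size=16, max_epoch=30,
                   patience=10, seed=0)
SMALL = SWNNConfig(input_dim=70, hidden=(16, 8), dropout=0.2, output_dim=6)


class TestDefaults:
    def test_binary_model_architecture(self):
        cfg = default_swnn_config("logistic")
        widths = [cfg.input_dim, *cfg.hidden, cfg.output_dim]
        assert widths == [443, 512, 512, 256, 128, 64, 6]
        assert cfg.dropout == 0.2

    def test_count_model_architecture(self):
        cfg = default_swnn_config("poisson")
        assert cfg.hidden == (512, 128, 64, 32)

    def test_training_defaults(self):
        lr_cfg = default_train_config("logistic")
        assert (lr_cfg.learning_rate, lr_cfg.batch_size, lr_cfg.max_epoch) == (0.0005, 10, 20000)
        pr_cfg = default_train_config("poisson")
        assert (pr_cfg.learning_rate, pr_cfg.batch_size) == (0.0008, 20)

    def test_invalid_configs(self):
        with pytest.raises(ValueError):
            SWNNConfig(dropout=1.0)
        with pytest.raises(ValueError):
            TrainConfig(learning_rate=0.0)


class TestForward:
    def test_empty_hidden_is_single_linear_map(self):
        cfg = SWNNConfig(input_dim=4, hidden=(), dropout=0.0, output_dim=3)
        m = build_swnn(cfg, seed=1)
        assert m.n_layers == 1
        rng = np.random.default_rng(0)
        X = rng.normal(size=(5, 4))
        out = m.forward(X)
        np.testing.assert_allclose(out, X @ m.weights[0] + m.biases[0], atol=1e-12)

    def test_zero_weights_unit_offsets_give_all_ones(self):
        cfg = SWNNConfig(input_dim=10, hidden=(7, 5), dropout=0.2, output_dim=6)
        m = build_swnn(cfg, seed=0)
        for W in m.weights:
            W[:] = 0.0
        for b in m.biases[:-1]:
            b[:] = 0.0
        m.biases[-1][:] = 1.0
        out = swnn_weights(m, np.random.default_rng(1).random((4, 10)))
        np.testing.assert_array_equal(out, 1.0)

    def test_eval_mode_deterministic(self):
        cfg = SWNNConfig(input_dim=8, hidden=(12,), dropout=0.5, output_dim=6)
        m = build_swnn(cfg, seed=2)
        m.weights[-1][:] = np.random.default_rng(3).normal(size=m.weights[-1].shape)
        x = np.random.default_rng(4).random((3, 8))
        np.testing.assert_array_equal(m.forward(x), m.forward(x))

    def test_dropout_requires_rng_in_train_mode(self):
        m = build_swnn(SWNNConfig(input_dim=3, hidden=(4,), dropout=0.3, output_dim=2), 0)
        with pytest.raises(ValueError, match="rng"):
            m.forward(np.zeros((1, 3)), train_mode=True)

    def test_wrong_input_width_errors(self):
        m = build_swnn(SWNNConfig(input_dim=5, hidden=(4,), output_dim=2), 0)
        with pytest.raises(ValueError, match="width"):
            m.forward(np.zeros((2, 7)))

    def test_gradient_matches_finite_differences(self):
        """Backprop oracle: numerical gradient of a scalar loss."""
        cfg = SWNNConfig(input_dim=3, hidden=(5,), dropout=0.0, output_dim=2)
        m = build_swnn(cfg, seed=5)
        m.weights[-1][:] = np.random.default_rng(6).normal(size=m.weights[-1].shape)
        X = np.random.default_rng(7).normal(size=(4, 3))
        T = np.random.default_rng(8).normal(size=(4, 2))

        def loss():
            return 0.5 * np.sum((m.forward(X) - T) ** 2)

        m.forward(X, train_mode=True)
        grads = m.backward(m.forward(X) - T)
        eps = 1e-6
        for li in range(m.n_layers):
            W = m.weights[li]
            idx = (0, 0)
            orig = W[idx]
            W[idx] = orig + eps
            up = loss()
            W[idx] = orig - eps
            dn = loss()
            W[idx] = orig
            assert grads[li][0][idx] == pytest.approx((up - dn) / (2 * eps), rel=1e-4, abs=1e-7)


class TestTraining:
    @pytest.mark.parametrize("family", ["logistic", "poisson"])
    def test_initial_model_equals_global_glm(self, family):
        """With the output layer at zero weights / unit offsets (the
        initialization), predictions coincide exactly with the global GLM."""
        train_std, val_std, _, _ = _tiny_split()
        cfg = TrainConfig(learning_rate=1e-9, batch_size=16, max_epoch=1,
                          patience=1, seed=0)
        fit = train_gnnwr(train_std, val_std, family, swnn_cfg=SMALL, train_cfg=cfg)
        # rebuild an untouched model to probe the initialization itself
        fresh = build_swnn(fit.swnn.config, seed=0)
        fit2 = GNNWRFit(family=family, global_fit=fit.global_fit, swnn=fresh,
                        ref_coords=fit.ref_coords, dist_scale=fit.dist_scale,
                        covariate_names=fit.covariate_names)
        pred = predict_gnnwr(fit2, train_std.coords, train_std.X)
        gpred = glm.predict_glm(fit.global_fit, train_std.X)
        np.testing.assert_allclose(pred, gpred, atol=1e-12)

    def test_training_is_deterministic(self):
        train_std, val_std, _, _ = _tiny_split()
        f1 = train_gnnwr(train_std, val_std, "poisson", swnn_cfg=SMALL, train_cfg=FAST)
        f2 = train_gnnwr(train_std, val_std, "poisson", swnn_cfg=SMALL, train_cfg=FAST)
        pd.testing.assert_frame_equal(f1.history, f2.history)
        for a, b in zip(f1.swnn.get_params(), f2.swnn.get_params()):
            np.testing.assert_array_equal(a, b)

    def test_early_stopping_invariants(self):
        train_std, val_std, _, _ = _tiny_split(seed=3)
        fit = train_gnnwr(train_std, val_std, "poisson", swnn_cfg=SMALL, train_cfg=FAST)
        h = fit.history
        assert fit.stopped_epoch <= FAST.max_epoch
        assert list(h.columns) == ["epoch", "train_loss", "val_mae"]
        assert fit.best_val_mae <= h["val_mae"].iloc[-1] + 1e-12
        assert fit.best_val_mae == pytest.approx(h["val_mae"].min())
        # restored checkpoint reproduces the best validation MAE
        pred = predict_gnnwr(fit, val_std.coords, val_std.X)
        mae = np.mean(np.abs(val_std.response("ndw") - pred))
        assert mae == pytest.approx(fit.best_val_mae, abs=1e-10)

    def test_empty_validation_set_errors(self):
        train_std, val_std, _, _ = _tiny_split()
        empty = val_std.subset(np.array([], dtype=int))
        with pytest.raises(ValueError, match="validation"):
            train_gnnwr(train_std, empty, "poisson", swnn_cfg=SMALL, train_cfg=FAST)


class TestPredict:
    def _fit(self, family="poisson", seed=0):
        train_std, val_std, truth, train = _tiny_split(seed)
        fit = train_gnnwr(train_std, val_std, family, swnn_cfg=SMALL, train_cfg=FAST)
        return fit, train_std, val_std

    def test_prediction_matches_hand_formula(self):
        fit, train_std, val_std = self._fit()
        i = 3
        d = np.sqrt(((val_std.coords[i] - fit.ref_coords) ** 2).sum(axis=1)) / fit.dist_scale
        w = fit.swnn.forward(d[None, :])[0]
        x = np.concatenate([[1.0], val_std.X.iloc[i].to_numpy()])
        eta = float(np.sum(fit.global_fit.beta * w * x))
        pred = predict_gnnwr(fit, val_std.coords, val_std.X)
        assert pred[i] == pytest.approx(np.exp(eta), rel=1e-10)

    def test_repeated_calls_identical(self):
        fit, train_std, val_std = self._fit()
        p1 = predict_gnnwr(fit, val_std.coords, val_std.X)
        p2 = predict_gnnwr(fit, val_std.coords, val_std.X)
        np.testing.assert_array_equal(p1, p2)

    def test_logistic_output_strictly_inside_unit_interval(self):
        fit, train_std, val_std = self._fit(family="logistic")
        X = val_std.X * 50.0  # extreme standardized covariates
        p = predict_gnnwr(fit, val_std.coords, X)
        assert np.all((p > 0) & (p < 1))

    def test_dimension_mismatch_errors(self):
        fit, train_std, val_std = self._fit()
        with pytest.raises(ValueError):
            predict_gnnwr(fit, val_std.coords[:3], val_std.X)


class TestLocalCoefficients:
    def test_all_ones_weights_reproduce_global_beta(self):
        train_std, val_std, _, _ = _tiny_split()
        cfg = TrainConfig(learning_rate=1e-12, batch_size=16, max_epoch=1, patience=1, seed=0)
        fit = train_gnnwr(train_std, val_std, "poisson", swnn_cfg=SMALL, train_cfg=cfg)
        fit.swnn = build_swnn(fit.swnn.config, seed=0)  # untrained: all-ones output
        lc = local_coefficients(fit, train_std.coords)
        np.testing.assert_allclose(lc.B, np.tile(fit.global_fit.beta, (train_std.n, 1)),
                                   atol=1e-12)

    def test_rows_are_elementwise_products(self):
        train_std, val_std, _, _ = _tiny_split(seed=5)
        fit = train_gnnwr(train_std, val_std, "poisson", swnn_cfg=SMALL, train_cfg=FAST)
        coords = train_std.coords[:7]
        W = fit.swnn.forward(
            np.sqrt(((coords[:, None, :] - fit.ref_coords[None]) ** 2).sum(-1)) / fit.dist_scale)
        lc = local_coefficients(fit, coords)
        np.testing.assert_allclose(lc.B, W * fit.global_fit.beta[None, :], atol=1e-12)

    def test_summary_column_order(self):
        train_std, val_std, _, _ = _tiny_split()
        fit = train_gnnwr(train_std, val_std, "poisson", swnn_cfg=SMALL, train_cfg=FAST)
        lc = local_coefficients(fit, train_std.coords)
        table = coefficient_summary(lc)
        assert list(table.columns) == ["Mean", "Min", "Q1", "Median", "Q3", "Max"]
        assert list(table.index) == ["Intercept", *train_std.X.columns]
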