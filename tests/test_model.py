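"""Estimator contract, fusion semantics, ablations, ensembling, checkpoints."""

import numpy as np
import pytest
from sklearn.base import clone
from sklearn.exceptions import NotFittedError

from ddgfuse import (DDGRegressor, FoldEnsemble, VersionMismatchError,
                     load_checkpoint, save_checkpoint, train_cv)
from ddgfuse.model import _Network
from ddgfuse.nn import hswish


def _toy_xy(n=80, d=8, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 25 + d))
    w = rng.normal(size=25 + d)
    y = X @ w / np.sqrt(25 + d)
    return X, y


FAST = dict(hidden_global=16, hidden_local=8, conv_channels=(2, 3),
            fc_hidden=8, max_epochs=15, patience=5, batch_size=16)


class TestNetworkForward:
    def test_encode_branch_degenerate_parameters(self):
        # zero weights and a constant bias on the last layer give a
        # constant encoding regardless of input
        net = _Network(8, 6, 4, "linear_combination", (2, 2), 3, 4,
                       np.random.default_rng(0))
        for layer in net.enc_g.layers:
            for p in layer.parameters():
                p.value[...] = 0.0
        net.enc_g.layers[-1].b.value[...] = 2.5
        g = net.enc_g.forward(np.random.default_rng(1).normal(size=(5, 8)),
                              train=False)
        assert g.shape == (5, 128)
        assert np.all(g == 2.5)

    def test_encode_branch_linear_regime(self):
        # with all pre-activations >= 3, H-swish is the identity and the
        # branch reduces to the affine map w2 (w1 x + b1) + b2
        rng = np.random.default_rng(0)
        net = _Network(4, 3, 4, "linear_combination", (2, 2), 3, 4, rng)
        lin1, _, lin2 = net.enc_g.layers
        lin1.W.value[...] = 0.0
        lin1.b.value[...] = 5.0      # pre-activations all 5 > 3
        x = rng.normal(size=(6, 4))
        expected = hswish(x @ lin1.W.value + lin1.b.value) \
            @ lin2.W.value + lin2.b.value
        assert np.allclose(net.enc_g.forward(x, train=False), expected)
        assert np.allclose(hswish(np.full(3, 5.0)), 5.0)

    @pytest.mark.parametrize("fusion,width", [
        ("linear_combination", 128),
        ("concatenation", 256),
        ("outer_product", 128 * 128),
    ])
    def test_fusion_widths(self, fusion, width):
        net = _Network(4, 3, 4, fusion, (2, 2), 3, 4,
                       np.random.default_rng(0))
        assert net.fused_dim == width

    def test_fusion_masking_and_addition(self):
        net = _Network(4, 3, 4, "linear_combination", (2, 2), 3, 4,
                       np.random.default_rng(0))
        rng = np.random.default_rng(1)
        xg, xl = rng.normal(size=(5, 4)), rng.normal(size=(5, 25))
        g = net.enc_g.forward(xg, train=False)
        r = net.enc_l.forward(xl, train=False)
        # g_weight = 1, r_weight = 0 masks the local branch entirely
        net.r_weight.value[...] = 0.0
        fused_masked = g * net.g_weight.value + r * net.r_weight.value
        assert np.array_equal(fused_masked, g)
        # both all-ones gives the plain sum
        net.r_weight.value[...] = 1.0
        net.g_weight.value[...] = 1.0
        assert np.allclose(g * net.g_weight.value + r * net.r_weight.value,
                           g + r)


class TestEstimatorContract:
    def test_sklearn_clone_and_get_params(self):
        model = DDGRegressor(lr=5e-4, fusion="concatenation")
        cloned = clone(model)
        assert cloned.get_params() == model.get_params()

    def test_predict_before_fit_raises(self):
        with pytest.raises(NotFittedError):
            DDGRegressor().predict(np.zeros((1, 33)))

    def test_too_few_columns_rejected(self):
        with pytest.raises(ValueError):
            DDGRegressor(**FAST).fit(np.zeros((10, 20)), np.zeros(10))

    def test_fit_predict_reproducible(self):
        X, y = _toy_xy()
        preds = []
        for _ in range(2):
            m = DDGRegressor(random_state=3, **FAST).fit(X, y)
            preds.append(m.predict(X))
        assert np.array_equal(preds[0], preds[1])

    def test_eval_prediction_pure_function(self):
        X, y = _toy_xy()
        m = DDGRegressor(random_state=0, **FAST).fit(X, y)
        a, b = m.predict(X[:7]), m.predict(X[:7])
        assert np.array_equal(a, b)
        # batch decomposition agrees with the full batch (running-stats BN)
        stacked = np.concatenate([m.predict(X[:3]), m.predict(X[3:7])])
        assert np.allclose(a, stacked)

    def test_loss_history_recorded(self):
        X, y = _toy_xy()
        m = DDGRegressor(random_state=0, **FAST).fit(X, y)
        assert 1 <= m.n_iter_ <= FAST["max_epochs"]
        assert len(m.loss_history_) == m.n_iter_
        assert np.isfinite(m.best_val_rmse_)


class TestAblation:
    def test_wo_local_matches_r_weight_zero_surgery(self):
        """Zeroing r_weight in the full model must equal the wo_local
        ablation sharing the same parameters."""
        X, y = _toy_xy()
        m = DDGRegressor(random_state=1, **FAST).fit(X, y)
        m.network_.r_weight.value[...] = 0.0
        full_pred = m.predict(X[:10])
        m.ablation = "wo_local"
        assert np.allclose(full_pred, m.predict(X[:10]))

    def test_ablations_differ(self):
        X, y = _toy_xy()
        m = DDGRegressor(random_state=1, **FAST).fit(X, y)
        m.ablation = "wo_local"
        a = m.predict(X[:10])
        m.ablation = "wo_global"
        b = m.predict(X[:10])
        assert not np.allclose(a, b)


class TestEnsemble:
    def test_identical_members_idempotent(self):
        X, y = _toy_xy()
        m = DDGRegressor(random_state=0, **FAST).fit(X, y)
        ens = FoldEnsemble([m, m, m])
        assert np.allclose(ens.predict(X[:5]), m.predict(X[:5]))

    def test_arithmetic_mean(self):
        class Const:
            def __init__(self, c):
                self.c = c
                self.n_features_in_ = 33
                self.fusion = "linear_combination"
                self.conv_channels = (2, 3)
                self.fc_hidden = 8
                self.hidden_global = 16
                self.hidden_local = 8

            def predict(self, X):
                return np.full(len(X), self.c)

        ens = FoldEnsemble([Const(c) for c in [1, 2, 3, 4, 5]])
        assert np.allclose(ens.predict(np.zeros((4, 33))), 3.0)

    def test_architecture_mismatch_rejected(self):
        X, y = _toy_xy()
        a = DDGRegressor(random_state=0, **FAST).fit(X, y)
        b = DDGRegressor(random_state=0, **{**FAST, "fc_hidden": 4}).fit(X, y)
        with pytest.raises(ValueError):
            FoldEnsemble([a, b])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            FoldEnsemble([])


class TestTrainCV:
    def test_report_mean_and_checkpoints(self):
        X, y = _toy_xy(n=60)
        folds = np.repeat([1, 2], 30)
        ens, report = train_cv(X, y, folds, random_state=0, **FAST)
        assert len(ens.models) == 2
        per_fold = report[report["fold"] != "mean"]
        mean_row = report[report["fold"] == "mean"].iloc[0]
        assert mean_row["pcc"] == pytest.approx(per_fold["pcc"].mean())
        assert mean_row["rmse"] == pytest.approx(per_fold["rmse"].mean())

    def test_single_fold_rejected(self):
        X, y = _toy_xy(n=20)
        with pytest.raises(ValueError):
            train_cv(X, y, np.ones(20), **FAST)


class TestCheckpoint:
    def test_roundtrip_bit_identical(self, tmp_path):
        X, y = _toy_xy()
        m = DDGRegressor(random_state=0, **FAST).fit(X, y)
        path = tmp_path / "model.npz"
        save_checkpoint(m, path, feature_signature="sig-a")
        loaded = load_checkpoint(path, expect_feature_signature="sig-a")
        assert np.array_equal(m.predict(X), loaded.predict(X))

    def test_feature_signature_mismatch_is_error(self, tmp_path):
        X, y = _toy_xy()
        m = DDGRegressor(random_state=0, **FAST).fit(X, y)
        path = tmp_path / "model.npz"
        save_checkpoint(m, path, feature_signature="sig-a")
        with pytest.raises(VersionMismatchError):
            load_checkpoint(path, expect_feature_signature="sig-b")

    def test_unfitted_model_not_checkpointable(self, tmp_path):
        with pytest.raises(NotFittedError):
            save_checkpoint(DDGRegressor(), tmp_path / "x.npz")


def test_nonfinite_loss_aborts_with_diagnostic():
    X, y = _toy_xy()
    # an absurd step size drives the parameters to overflow within an epoch
    huge = DDGRegressor(lr=1e200, random_state=0,
                        **{**FAST, "max_epochs": 50})
    with pytest.raises(RuntimeError, match="non-finite"):
        huge.fit(X, y)
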