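"""The trainable stability-change regressor.

Architecture
------------
Two encoder branches map the mutation's feature blocks into a shared
128-dimensional latent space:

* global branch: the d-dimensional pooled-embedding difference through
  ``Linear(d, 256) -> H-swish -> Linear(256, 128)``;
* local branch: the 25-dimensional local descriptor through
  ``Linear(25, 64) -> H-swish -> Linear(64, 128)``.

The branches are fused (default: element-wise, ``G o g_w + R o r_w`` with two
learnable 128-vectors; alternatives: concatenation, flattened outer product)
and decoded by a small 1-D CNN head::

    ReLU(BN(Conv1d)) x 2 -> flatten -> Linear -> BN -> Linear -> ddG

Training minimises mean-squared error with Adam, mini-batches, and early
stopping on held-out RMSE.  Ablations zero one branch's fused contribution
while keeping the decoder width constant, so ablated and full models are
directly comparable.

The estimator follows the scikit-learn contract (``fit`` / ``predict`` /
``get_params``), composes with sklearn model selection, and is deterministic
given ``random_state``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.exceptions import NotFittedError
from sklearn.utils.validation import check_array, check_X_y

from . import nn
from .local_features import N_LOCAL_FEATURES

FORMAT_VERSION = 1
LATENT_DIM = 128

FUSION_MODES = ("linear_combination", "concatenation", "outer_product")
ABLATIONS = ("full", "wo_local", "wo_global")


class VersionMismatchError(RuntimeError):
    """Checkpoint feature/format version does not match expectations."""


class _Network:
    """Parameter container + forward/backward for the two-branch head."""

    def __init__(self, n_global: int, hidden_global: int, hidden_local: int,
                 fusion: str, conv_channels: tuple[int, int],
                 kernel_size: int, fc_hidden: int,
                 rng: np.random.Generator):
        self.fusion = fusion
        self.enc_g = nn.Sequential(
            nn.Linear(n_global, hidden_global, rng), nn.HSwish(),
            nn.Linear(hidden_global, LATENT_DIM, rng))
        self.enc_l = nn.Sequential(
            nn.Linear(N_LOCAL_FEATURES, hidden_local, rng), nn.HSwish(),
            nn.Linear(hidden_local, LATENT_DIM, rng))
        if fusion == "linear_combination":
            self.fused_dim = LATENT_DIM
            # neutral start: both branches pass through unchanged
            self.g_weight = nn.Parameter(np.ones(LATENT_DIM))
            self.r_weight = nn.Parameter(np.ones(LATENT_DIM))
        elif fusion == "concatenation":
            self.fused_dim = 2 * LATENT_DIM
        elif fusion == "outer_product":
            self.fused_dim = LATENT_DIM * LATENT_DIM
        else:
            raise ValueError(f"unknown fusion mode {fusion!r}")
        c1, c2 = conv_channels
        self.decoder = nn.Sequential(
            nn.Conv1d(1, c1, kernel_size, kernel_size // 2, rng),
            nn.BatchNorm(c1), nn.ReLU(),
            nn.Conv1d(c1, c2, kernel_size, kernel_size // 2, rng),
            nn.BatchNorm(c2), nn.ReLU(),
            nn.Flatten(),
            nn.Linear(c2 * self.fused_dim, fc_hidden, rng),
            nn.BatchNorm(fc_hidden),
            nn.Linear(fc_hidden, 1, rng),
        )

    def parameters(self) -> list[nn.Parameter]:
        params = self.enc_g.parameters() + self.enc_l.parameters()
        if self.fusion == "linear_combination":
            params += [self.g_weight, self.r_weight]
        return params + self.decoder.parameters()

    def state(self) -> list[np.ndarray]:
        return self.decoder.state()

    def _masks(self, ablation: str) -> tuple[float, float]:
        if ablation == "full":
            return 1.0, 1.0
        if ablation == "wo_local":
            return 1.0, 0.0
        if ablation == "wo_global":
            return 0.0, 1.0
        raise ValueError(f"unknown ablation {ablation!r}")

    def forward(self, x_global: np.ndarray, x_local: np.ndarray,
                ablation: str, train: bool) -> np.ndarray:
        mg, ml = self._masks(ablation)
        g = self.enc_g.forward(x_global, train) * mg
        r = self.enc_l.forward(x_local, train) * ml
        if self.fusion == "linear_combination":
            fused = g * self.g_weight.value + r * self.r_weight.value
        elif self.fusion == "concatenation":
            fused = np.concatenate([g, r], axis=1)
        else:  # outer_product
            fused = (g[:, :, None] * r[:, None, :]).reshape(len(g), -1)
        if train:
            self._g, self._r, self._mg, self._ml = g, r, mg, ml
        out = self.decoder.forward(fused[:, None, :], train)
        return out[:, 0]

    def backward(self, dy: np.ndarray) -> None:
        dfused = self.decoder.backward(dy[:, None])[:, 0, :]
        g, r, mg, ml = self._g, self._r, self._mg, self._ml
        if self.fusion == "linear_combination":
            self.g_weight.grad += (dfused * g).sum(axis=0)
            self.r_weight.grad += (dfused * r).sum(axis=0)
            dg = dfused * self.g_weight.value
            dr = dfused * self.r_weight.value
        elif self.fusion == "concatenation":
            dg, dr = dfused[:, :LATENT_DIM], dfused[:, LATENT_DIM:]
        else:
            dmat = dfused.reshape(len(g), LATENT_DIM, LATENT_DIM)
            dg = np.einsum("bij,bj->bi", dmat, r)
            dr = np.einsum("bij,bi->bj", dmat, g)
        self.enc_g.backward(dg * mg)
        self.enc_l.backward(dr * ml)


class DDGRegressor(RegressorMixin, BaseEstimator):
    """Two-branch fusion regressor for stability change upon point mutation.

    ``X`` rows are ``[local descriptor (25) | global embedding delta (d)]``.
    ``y`` is the experimental ddG in kcal/mol (positive = stabilizing).

    Parameters
    ----------
    fusion : {"linear_combination", "concatenation", "outer_product"}
        How the two 128-dimensional branch representations are combined.
    ablation : {"full", "wo_local", "wo_global"}
        Zero one branch's fused contribution (decoder width unchanged).
    hidden_global, hidden_local : int
        Encoder hidden widths.
    conv_channels, kernel_size, fc_hidden
        Decoder shape.
    lr, batch_size, max_epochs, patience, validation_fraction
        Optimisation: Adam on mean-squared error with early stopping on
        held-out RMSE (an explicit validation set can be passed to ``fit``).
    standardize : bool
        Standardise features column-wise on the training set.
    random_state : int or None
        Single seed for initialisation and batch shuffling.
    """

    def __init__(self, *, fusion: str = "linear_combination",
                 ablation: str = "full", hidden_global: int = 256,
                 hidden_local: int = 64, conv_channels: tuple[int, int] = (16, 32),
                 kernel_size: int = 3, fc_hidden: int = 64, lr: float = 1e-3,
                 batch_size: int = 64, max_epochs: int = 500,
                 patience: int = 20, validation_fraction: float = 0.1,
                 standardize: bool = True, random_state: int | None = None,
                 verbose: int = 0):
        self.fusion = fusion
        self.ablation = ablation
        self.hidden_global = hidden_global
        self.hidden_local = hidden_local
        self.conv_channels = conv_channels
        self.kernel_size = kernel_size
        self.fc_hidden = fc_hidden
        self.lr = lr
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.validation_fraction = validation_fraction
        self.standardize = standardize
        self.random_state = random_state
        self.verbose = verbose

    # -- internals ---------------------------------------------------------

    def _split_blocks(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return X[:, N_LOCAL_FEATURES:], X[:, :N_LOCAL_FEATURES]

    def _scale(self, X: np.ndarray) -> np.ndarray:
        if not self.standardize:
            return X
        return (X - self.feature_mean_) / self.feature_scale_

    def _snapshot(self) -> list[np.ndarray]:
        net = self.network_
        return ([p.value.copy() for p in net.parameters()]
                + [s.copy() for s in net.state()])

    def _restore(self, snap: list[np.ndarray]) -> None:
        net = self.network_
        params = net.parameters()
        for p, v in zip(params, snap[:len(params)]):
            p.value[...] = v
        for s, v in zip(net.state(), snap[len(params):]):
            s[...] = v

    # -- sklearn API -------------------------------------------------------

    def fit(self, X, y, X_val=None, y_val=None):
        """Fit on (X, y); early-stop on (X_val, y_val) when given, else on a
        ``validation_fraction`` split of the training data."""
        X, y = check_X_y(X, y, y_numeric=True)
        if self.fusion not in FUSION_MODES:
            raise ValueError(f"unknown fusion mode {self.fusion!r}")
        if self.ablation not in ABLATIONS:
            raise ValueError(f"unknown ablation {self.ablation!r}")
        if X.shape[1] <= N_LOCAL_FEATURES:
            raise ValueError(
                f"expected > {N_LOCAL_FEATURES} feature columns "
                f"(local block + embedding delta), got {X.shape[1]}"
            )
        self.n_features_in_ = X.shape[1]
        n_global = X.shape[1] - N_LOCAL_FEATURES

        rng = np.random.default_rng(self.random_state)
        if X_val is None:
            n_val = max(1, int(round(self.validation_fraction * len(X))))
            if n_val >= len(X):
                raise ValueError("validation split leaves no training data")
            perm = rng.permutation(len(X))
            val_idx, tr_idx = perm[:n_val], perm[n_val:]
            X_tr, y_tr, X_va, y_va = X[tr_idx], y[tr_idx], X[val_idx], y[val_idx]
        else:
            X_va, y_va = check_X_y(X_val, y_val, y_numeric=True)
            X_tr, y_tr = X, y
        if len(X_tr) == 0:
            raise ValueError("empty training set")

        if self.standardize:
            self.feature_mean_ = X_tr.mean(axis=0)
            scale = X_tr.std(axis=0)
            scale[scale < 1e-8] = 1.0
            self.feature_scale_ = scale
        Xs_tr, Xs_va = self._scale(X_tr), self._scale(X_va)

        self.network_ = _Network(
            n_global, self.hidden_global, self.hidden_local, self.fusion,
            tuple(self.conv_channels), self.kernel_size, self.fc_hidden, rng)
        opt = nn.Adam(self.network_.parameters(), lr=self.lr)

        best_rmse, best_snap, best_epoch = np.inf, None, 0
        self.loss_history_ = []
        for epoch in range(self.max_epochs):
            order = rng.permutation(len(Xs_tr))
            epoch_loss = 0.0
            for start in range(0, len(order), self.batch_size):
                idx = order[start:start + self.batch_size]
                xb_g, xb_l = self._split_blocks(Xs_tr[idx])
                yb = y_tr[idx]
                opt.zero_grad()
                pred = self.network_.forward(xb_g, xb_l, self.ablation,
                                             train=True)
                resid = pred - yb
                loss = float(np.mean(resid ** 2))
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite training loss at epoch {epoch}; "
                        "lower the learning rate or check the features"
                    )
                epoch_loss += loss * len(idx)
                self.network_.backward(2.0 * resid / len(idx))
                opt.step()
            val_pred = self._predict_scaled(Xs_va)
            val_rmse = float(np.sqrt(np.mean((val_pred - y_va) ** 2)))
            self.loss_history_.append(
                (epoch_loss / len(Xs_tr), val_rmse))
            if self.verbose:
                print(f"epoch {epoch:3d} train_mse={epoch_loss/len(Xs_tr):.4f}"
                      f" val_rmse={val_rmse:.4f}")
            if val_rmse < best_rmse - 1e-6:
                best_rmse, best_snap, best_epoch = val_rmse, self._snapshot(), epoch
            elif epoch - best_epoch >= self.patience:
                break
        if best_snap is not None:
            self._restore(best_snap)
        self.best_val_rmse_ = best_rmse
        self.n_iter_ = len(self.loss_history_)
        return self

    def _predict_scaled(self, Xs: np.ndarray,
                        chunk: int = 1024) -> np.ndarray:
        out = []
        for start in range(0, len(Xs), chunk):
            xg, xl = self._split_blocks(Xs[start:start + chunk])
            out.append(self.network_.forward(xg, xl, self.ablation,
                                             train=False))
        return np.concatenate(out) if out else np.empty(0)

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "network_"):
            raise NotFittedError("DDGRegressor is not fitted yet")
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, expected {self.n_features_in_}"
            )
        return self._predict_scaled(self._scale(X))

    def fusion_weights(self) -> tuple[np.ndarray, np.ndarray]:
        """The learned element-wise fusion weight vectors (g, r)."""
        if not hasattr(self, "network_"):
            raise NotFittedError("DDGRegressor is not fitted yet")
        if self.fusion != "linear_combination":
            raise ValueError(
                "fusion weights exist only for linear_combination fusion"
            )
        return (self.network_.g_weight.value.copy(),
                self.network_.r_weight.value.copy())


class FoldEnsemble:
    """Arithmetic mean over the k cross-validation models."""

    def __init__(self, models: list[DDGRegressor]):
        if not models:
            raise ValueError("ensemble needs at least one model")
        dims = {m.n_features_in_ for m in models}
        archs = {(m.fusion, tuple(m.conv_channels), m.fc_hidden,
                  m.hidden_global, m.hidden_local) for m in models}
        if len(dims) != 1 or len(archs) != 1:
            raise ValueError("ensemble members must share an architecture")
        self.models = list(models)

    def predict(self, X) -> np.ndarray:
        return np.mean([m.predict(X) for m in self.models], axis=0)


def train_cv(X, y, fold_labels, k: int | None = None,
             **model_params) -> tuple[FoldEnsemble, pd.DataFrame]:
    """Homology-aware k-fold cross-validation.

    For each fold f: train on all other folds, early-stop and evaluate on
    fold f.  Returns the fold ensemble and a per-fold report (PCC and RMSE
    on the held-out fold, plus their means in a final row).
    """
    from .metrics import pcc, rmse

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    fold_labels = np.asarray(fold_labels)
    folds = sorted(int(f) for f in np.unique(fold_labels))
    if k is not None and len(folds) != k:
        raise ValueError(f"expected {k} folds, found {len(folds)}")
    if len(folds) < 2:
        raise ValueError("cross-validation needs at least 2 folds")

    models, rows = [], []
    base_seed = model_params.pop("random_state", 0) or 0
    for f in folds:
        held = fold_labels == f
        if held.all() or not held.any():
            raise ValueError(f"fold {f} is empty or covers the whole dataset")
        model = DDGRegressor(random_state=base_seed + f, **model_params)
        model.fit(X[~held], y[~held], X_val=X[held], y_val=y[held])
        pred = model.predict(X[held])
        rows.append({"fold": f, "n": int(held.sum()),
                     "pcc": pcc(pred, y[held]), "rmse": rmse(pred, y[held])})
        models.append(model)
    report = pd.DataFrame(rows)
    mean_row = {"fold": "mean", "n": int(report["n"].sum()),
                "pcc": report["pcc"].mean(), "rmse": report["rmse"].mean()}
    report = pd.concat([report, pd.DataFrame([mean_row])], ignore_index=True)
    return FoldEnsemble(models), report


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: DDGRegressor, path: str | Path,
                    feature_signature: str = "unversioned") -> None:
    """Serialise a fitted model: hyperparameters, scaler, every parameter and
    batch-norm statistic, plus a feature signature (embedding provider id +
    property-table version) checked on load."""
    if not hasattr(model, "network_"):
        raise NotFittedError("cannot checkpoint an unfitted model")
    net = model.network_
    arrays = {f"param_{i:03d}": p.value
              for i, p in enumerate(net.parameters())}
    arrays.update({f"state_{i:03d}": s for i, s in enumerate(net.state())})
    if model.standardize:
        arrays["feature_mean"] = model.feature_mean_
        arrays["feature_scale"] = model.feature_scale_
    meta = {
        "format_version": FORMAT_VERSION,
        "feature_signature": feature_signature,
        "n_features_in": int(model.n_features_in_),
        "params": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in model.get_params().items()},
    }
    np.savez(path, meta=np.array(json.dumps(meta)), **arrays)


def load_checkpoint(path: str | Path,
                    expect_feature_signature: str | None = None
                    ) -> DDGRegressor:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        if meta["format_version"] != FORMAT_VERSION:
            raise VersionMismatchError(
                f"checkpoint format {meta['format_version']} != "
                f"{FORMAT_VERSION}"
            )
        if (expect_feature_signature is not None
                and meta["feature_signature"] != expect_feature_signature):
            raise VersionMismatchError(
                f"checkpoint was built with features "
                f"{meta['feature_signature']!r}, expected "
                f"{expect_feature_signature!r}"
            )
        params = dict(meta["params"])
        params["conv_channels"] = tuple(params["conv_channels"])
        model = DDGRegressor(**params)
        model.n_features_in_ = meta["n_features_in"]
        n_global = model.n_features_in_ - N_LOCAL_FEATURES
        rng = np.random.default_rng(0)  # shapes only; values overwritten
        model.network_ = _Network(
            n_global, model.hidden_global, model.hidden_local, model.fusion,
            model.conv_channels, model.kernel_size, model.fc_hidden, rng)
        for i, p in enumerate(model.network_.parameters()):
            p.value[...] = data[f"param_{i:03d}"]
        for i, s in enumerate(model.network_.state()):
            s[...] = data[f"state_{i:03d}"]
        if model.standardize:
            model.feature_mean_ = data["feature_mean"]
            model.feature_scale_ = data["feature_scale"]
        model.feature_signature_ = meta["feature_signature"]
    return model
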