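"""Geographically neural-network-weighted regression (GNNWLR / GNNWPR).

A spatially weighted neural network (SWNN) maps each location's vector of
distances to the reference (training) locations onto k+1 non-stationarity
weights w_0(u,v)..w_k(u,v), one per regression coefficient. The local
linear predictor multiplies the *global* maximum-likelihood coefficients
by these weights,

    eta_i = sum_k  beta_k * w_k(u_i, v_i) * x_ik      (x_i0 = 1),

and passes through the family's inverse link (logit for the binary
occurrence model, log for the count model). Only the SWNN is trained —
the global coefficients stay frozen — by minibatch Adam on a Huber loss
computed on the response scale, with early stopping on validation MAE.

The network is a plain fully connected stack: LeakyReLU and (inverted)
dropout after every hidden layer, linear output so weights may be
negative. The output layer is initialized at zero weights with unit
offsets, so training starts exactly at the stationary global model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_core import SpatialDataset, cross_distances, distance_matrix
from .glm import (
    FAMILY_RESPONSE,
    GlobalFit,
    _check_family,
    _design,
    fit_glm,
    inverse_link,
    mean_derivative,
)
from .gwr import LocalFit


@dataclass(frozen=True)
class SWNNConfig:
    """Architecture of the distance-to-weights network.

    ``input_dim`` is the number of reference locations (one distance per
    reference point); ``output_dim`` is k+1, one weight per coefficient
    including the intercept. An empty ``hidden`` list degenerates to a
    single linear map.
    """

    input_dim: int = 443
    hidden: tuple[int, ...] = (512, 512, 256, 128, 64)
    dropout: float = 0.2
    leaky_slope: float = 0.01
    output_dim: int = 6

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if self.input_dim < 1 or self.output_dim < 1:
            raise ValueError("input_dim and output_dim must be positive")
        if any(h < 1 for h in self.hidden):
            raise ValueError("hidden layer widths must be positive")


@dataclass(frozen=True)
class TrainConfig:
    """SWNN training hyperparameters."""

    learning_rate: float = 0.0005
    batch_size: int = 10
    max_epoch: int = 20000
    patience: int = 500
    huber_delta: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1 or self.max_epoch < 1 or self.patience < 1:
            raise ValueError("batch_size, max_epoch and patience must be >= 1")


def default_swnn_config(family: str, input_dim: int | None = None, output_dim: int = 6) -> SWNNConfig:
    """Published default architectures for the binary and count models."""
    _check_family(family)
    hidden = (512, 512, 256, 128, 64) if family == "logistic" else (512, 128, 64, 32)
    return SWNNConfig(input_dim=443 if input_dim is None else input_dim,
                      hidden=hidden, dropout=0.2, output_dim=output_dim)


def default_train_config(family: str, seed: int = 0) -> TrainConfig:
    """Published default training settings for the binary and count models."""
    _check_family(family)
    if family == "logistic":
        return TrainConfig(learning_rate=0.0005, batch_size=10, max_epoch=20000, seed=seed)
    return TrainConfig(learning_rate=0.0008, batch_size=20, max_epoch=20000, seed=seed)


class SWNNModel:
    """Fully connected distance-to-weights network with manual backprop.

    Parameters are plain numpy arrays; the forward pass in evaluation mode
    is deterministic (dropout disabled), and training uses inverted
    dropout so evaluation needs no rescaling.
    """

    def __init__(self, config: SWNNConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        dims = [config.input_dim, *config.hidden, config.output_dim]
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for i in range(len(dims) - 1):
            fan_in, fan_out = dims[i], dims[i + 1]
            if i == len(dims) - 2:
                # linear output starts at the identity weighting (all-ones output)
                W = np.zeros((fan_in, fan_out))
                b = np.ones(fan_out)
            else:
                W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out))
                b = np.zeros(fan_out)
            self.weights.append(W)
            self.biases.append(b)
        self.history: list[dict] = []
        self.stopped_epoch: int | None = None
        self._adam_m = None
        self._adam_v = None
        self._adam_t = 0

    @property
    def n_layers(self) -> int:
        return len(self.weights)

    def forward(self, X: np.ndarray, train_mode: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        """Map distance rows to weight vectors; caches activations in train mode."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.config.input_dim:
            raise ValueError(f"expected input of width {self.config.input_dim}, got {X.shape[1]}")
        slope, p = self.config.leaky_slope, self.config.dropout
        cache = {"inputs": [], "pre": [], "masks": []}
        h = X
        for i in range(self.n_layers):
            cache["inputs"].append(h)
            a = h @ self.weights[i] + self.biases[i]
            if i < self.n_layers - 1:
                cache["pre"].append(a)
                h = np.where(a > 0, a, slope * a)
                if train_mode and p > 0:
                    if rng is None:
                        raise ValueError("train_mode requires an rng for dropout")
                    mask = (rng.random(h.shape) >= p) / (1.0 - p)
                    h = h * mask
                    cache["masks"].append(mask)
                else:
                    cache["masks"].append(None)
            else:
                h = a
        if train_mode:
            self._cache = cache
        return h

    def backward(self, grad_out: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
        """Gradients of the loss w.r.t. every (W, b), given dL/d(output)."""
        cache = self._cache
        slope = self.config.leaky_slope
        grads: list[tuple[np.ndarray, np.ndarray]] = [None] * self.n_layers
        g = grad_out
        for i in reversed(range(self.n_layers)):
            h_in = cache["inputs"][i]
            grads[i] = (h_in.T @ g, g.sum(axis=0))
            if i > 0:
                g = g @ self.weights[i].T
                mask = cache["masks"][i - 1]
                if mask is not None:
                    g = g * mask
                a = cache["pre"][i - 1]
                g = g * np.where(a > 0, 1.0, slope)
        return grads

    def adam_step(self, grads, lr: float, beta1: float = 0.9, beta2: float = 0.999,
                  eps: float = 1e-8, clip: float = 5.0) -> None:
        if self._adam_m is None:
            self._adam_m = [(np.zeros_like(W), np.zeros_like(b))
                            for W, b in zip(self.weights, self.biases)]
            self._adam_v = [(np.zeros_like(W), np.zeros_like(b))
                            for W, b in zip(self.weights, self.biases)]
        # global-norm gradient clipping guards the exp link's large gradients
        total = np.sqrt(sum(float((g ** 2).sum()) + float((gb ** 2).sum()) for g, gb in grads))
        scale = min(1.0, clip / (total + 1e-12))
        self._adam_t += 1
        t = self._adam_t
        for i, (gW, gb) in enumerate(grads):
            gW, gb = gW * scale, gb * scale
            mW, mb = self._adam_m[i]
            vW, vb = self._adam_v[i]
            mW[:] = beta1 * mW + (1 - beta1) * gW
            mb[:] = beta1 * mb + (1 - beta1) * gb
            vW[:] = beta2 * vW + (1 - beta2) * gW ** 2
            vb[:] = beta2 * vb + (1 - beta2) * gb ** 2
            corr1, corr2 = 1 - beta1 ** t, 1 - beta2 ** t
            self.weights[i] -= lr * (mW / corr1) / (np.sqrt(vW / corr2) + eps)
            self.biases[i] -= lr * (mb / corr1) / (np.sqrt(vb / corr2) + eps)

    def get_params(self) -> list[np.ndarray]:
        return [a.copy() for a in (*self.weights, *self.biases)]

    def set_params(self, params: list[np.ndarray]) -> None:
        L = self.n_layers
        self.weights = [p.copy() for p in params[:L]]
        self.biases = [p.copy() for p in params[L:]]


def build_swnn(cfg: SWNNConfig, seed: int = 0) -> SWNNModel:
    """Construct a reproducibly initialized SWNN."""
    return SWNNModel(cfg, seed=seed)


def swnn_weights(model: SWNNModel, dist_rows: np.ndarray, train_mode: bool = False,
                 rng: np.random.Generator | None = None) -> np.ndarray:
    """Per-coefficient weight vectors for (already normalized) distance rows."""
    return model.forward(dist_rows, train_mode=train_mode, rng=rng)


def _huber(r: np.ndarray, delta: float) -> np.ndarray:
    a = np.abs(r)
    return np.where(a <= delta, 0.5 * r ** 2, delta * (a - 0.5 * delta))


def _huber_grad(r: np.ndarray, delta: float) -> np.ndarray:
    return np.clip(r, -delta, delta)


@dataclass
class GNNWRFit:
    """A trained neural-network-weighted regression model."""

    family: str
    global_fit: GlobalFit
    swnn: SWNNModel
    ref_coords: np.ndarray
    dist_scale: float
    covariate_names: list[str]
    history: pd.DataFrame | None = None
    stopped_epoch: int | None = None
    best_val_mae: float | None = None

    def _weights_at(self, coords: np.ndarray) -> np.ndarray:
        d = cross_distances(np.atleast_2d(coords), self.ref_coords) / self.dist_scale
        return self.swnn.forward(d, train_mode=False)


def train_gnnwr(
    train: SpatialDataset,
    val: SpatialDataset,
    family: str,
    swnn_cfg: SWNNConfig | None = None,
    train_cfg: TrainConfig | None = None,
    response: str | None = None,
    reference: np.ndarray | None = None,
) -> GNNWRFit:
    """Train a GNNWLR (logistic) or GNNWPR (poisson) model.

    ``train`` and ``val`` must carry covariates standardized with the
    training parameters. The global GLM is fitted on ``train`` first and
    its coefficients frozen; the SWNN alone is trained. ``reference``
    overrides the distance-vector reference set (default: the training
    locations). The returned model is the checkpoint with the best
    validation MAE.
    """
    _check_family(family)
    if val.n == 0:
        raise ValueError("validation set must be non-empty")
    response = FAMILY_RESPONSE[family] if response is None else response
    train_cfg = default_train_config(family) if train_cfg is None else train_cfg

    ref = train.coords if reference is None else np.asarray(reference, dtype=float)
    dist_scale = float(distance_matrix(train.coords).max())
    if dist_scale <= 0:
        raise ValueError("training locations are all coincident")

    if swnn_cfg is None:
        swnn_cfg = default_swnn_config(family, input_dim=len(ref),
                                       output_dim=train.X.shape[1] + 1)
    elif swnn_cfg.input_dim != len(ref):
        swnn_cfg = SWNNConfig(input_dim=len(ref), hidden=swnn_cfg.hidden,
                              dropout=swnn_cfg.dropout, leaky_slope=swnn_cfg.leaky_slope,
                              output_dim=swnn_cfg.output_dim)

    global_fit = fit_glm(train, family, response)
    beta = global_fit.beta
    Xd, names = _design(train.X)
    y = train.response(response)
    Dtr = cross_distances(train.coords, ref) / dist_scale

    Xd_val, _ = _design(val.X, names)
    y_val = val.response(response)
    Dval = cross_distances(val.coords, ref) / dist_scale

    model = build_swnn(swnn_cfg, seed=train_cfg.seed)
    rng = np.random.default_rng(train_cfg.seed + 1)
    delta = train_cfg.huber_delta
    bx = beta[None, :] * Xd  # beta_k * x_ik, fixed throughout training

    best_mae = np.inf
    best_params = model.get_params()
    best_epoch = 0
    epochs_since_best = 0
    history = []
    n = train.n

    for epoch in range(1, train_cfg.max_epoch + 1):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, train_cfg.batch_size):
            idx = order[start:start + train_cfg.batch_size]
            W = model.forward(Dtr[idx], train_mode=True, rng=rng)
            eta = np.sum(W * bx[idx], axis=1)
            mu = inverse_link(eta, family)
            r = y[idx] - mu
            loss = float(np.mean(_huber(r, delta)))
            if not np.isfinite(loss):
                raise RuntimeError(
                    "non-finite training loss; try a lower learning rate or smaller huber_delta"
                )
            epoch_loss += loss * len(idx)
            # dL/dW_k = -huber'(r) * dmu/deta * beta_k x_ik / batch
            dmu = mean_derivative(eta, family)
            grad_out = (-_huber_grad(r, delta) * dmu)[:, None] * bx[idx] / len(idx)
            grads = model.backward(grad_out)
            model.adam_step(grads, lr=train_cfg.learning_rate)

        Wv = model.forward(Dval, train_mode=False)
        mu_val = inverse_link(np.sum(Wv * (beta[None, :] * Xd_val), axis=1), family)
        val_mae = float(np.mean(np.abs(y_val - mu_val)))
        history.append({"epoch": epoch, "train_loss": epoch_loss / n, "val_mae": val_mae})

        if val_mae < best_mae - 1e-12:
            best_mae = val_mae
            best_params = model.get_params()
            best_epoch = epoch
            epochs_since_best = 0
        else:
            epochs_since_best += 1
            if epochs_since_best >= train_cfg.patience:
                break

    model.set_params(best_params)
    model.stopped_epoch = epoch
    model.history = history
    return GNNWRFit(
        family=family,
        global_fit=global_fit,
        swnn=model,
        ref_coords=ref,
        dist_scale=dist_scale,
        covariate_names=names,
        history=pd.DataFrame(history),
        stopped_epoch=epoch,
        best_val_mae=best_mae if np.isfinite(best_mae) else None,
    )


def predict_gnnwr(fit: GNNWRFit, coords: np.ndarray, X) -> np.ndarray:
    """Deterministic predictions at arbitrary locations.

    ``X`` must be standardized with the training parameters; distances to
    the reference set are normalized by the stored training constant.
    """
    Xd, _ = _design(X, fit.covariate_names if hasattr(X, "columns") else None)
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if len(coords) != len(Xd):
        raise ValueError("coords and X must have the same number of rows")
    if Xd.shape[1] != len(fit.global_fit.beta):
        raise ValueError("covariate dimension mismatch with fitted model")
    W = fit._weights_at(coords)
    eta = np.sum(W * (fit.global_fit.beta[None, :] * Xd), axis=1)
    return inverse_link(eta, fit.family)


def local_coefficients(fit: GNNWRFit, coords: np.ndarray) -> LocalFit:
    """Effective local coefficients beta_k * w_k(u_i, v_i) at each location."""
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    W = fit._weights_at(coords)
    B = W * fit.global_fit.beta[None, :]
    return LocalFit(
        family=fit.family,
        B=B,
        covariate_names=fit.covariate_names,
        converged=np.ones(len(B), dtype=bool),
    )
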