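"""Shallow 1-D U-Net autoencoder with an in-line dense feature bottleneck.

The network maps stacked predictor channels (PPG and optionally its two
derivatives and ECG, each 1024 samples, unit-scaled) to the globally
normalized pressure waveform.  It is a standard U-Net encoder/decoder with
one twist: at the bottom, the pooled feature map is flattened through a
dense layer of ``n_features`` units — the *feature layer* whose activations
are handed to the second-stage regressors — and a second dense layer
projects back to the pooled map shape before the bottom convolution block
and the decoder resume.

Architecture per level (depth ``d``, first-level width ``w``, kernel ``k``):
encoder block = two same-padded convolutions + ReLU, channel width doubling
per level, factor-2 max pooling; bottom block widens ``w 2^(d-1) ->
w 2^d``; decoder level = x2 upsampling (transposed convolution by default),
skip concatenation, two convolutions; final 1x1 convolution to a single
linear output channel.  With depth 1, width 128, kernel 3, 4 input channels
and 1024 features this reproduces the published layout: a 512 x 128 pooled
bottleneck, a 512*128*1024 = 67,108,864-weight feature layer, and a
~0.55 M-parameter convolutional backbone (exactly 559,873).

Training: MSE loss, Adam, early stopping on validation mean-absolute error
with best-weight restoration.  Everything is seeded and float32, so reruns
are bitwise identical.

``UNetFeatureExtractor`` wraps the model as a scikit-learn transformer
(``fit`` trains the autoencoder, ``transform`` returns the feature matrix),
so it composes with sklearn pipelines and model selection.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass, field
from typing import Literal

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.exceptions import NotFittedError

from . import nn
from .nn import F32


@dataclass(frozen=True)
class UNetConfig:
    """Architecture grid for the autoencoder.

    ``in_channels`` counts stacked predictor channels in the declared order
    PPG, VPG, APG, ECG (subsets keep that order).  ``target`` selects the
    reconstruction target: the pressure waveform (default) or the PPG
    itself (the self-reconstruction ablation).
    """

    depth: int = 1
    width: int = 128
    kernel: int = 3
    in_channels: int = 4
    n_features: int = 1024
    target: Literal["ABP", "PPG"] = "ABP"
    upsample: Literal["transpose-conv", "nearest+conv"] = "transpose-conv"
    convs_per_block: int = 2
    input_length: int = 1024
    feature_activation: Literal["relu", "linear"] = "relu"

    def __post_init__(self) -> None:
        if not (1 <= self.depth <= 4):
            raise ValueError("depth must be in 1..4")
        if self.kernel % 2 != 1 or not (1 <= self.kernel <= 11):
            raise ValueError("kernel must be odd, in 1..11")
        if self.input_length % (2**self.depth) != 0:
            raise ValueError(
                f"input_length {self.input_length} not divisible by 2^depth = {2**self.depth}"
            )
        if self.width < 1 or self.n_features < 1 or not (1 <= self.in_channels <= 4):
            raise ValueError("width, n_features >= 1 and 1 <= in_channels <= 4 required")

    @property
    def bottleneck_length(self) -> int:
        return self.input_length // (2**self.depth)

    @property
    def bottleneck_channels(self) -> int:
        return self.width * 2 ** (self.depth - 1)


@dataclass(frozen=True)
class TrainConfig:
    """Autoencoder training setup (loss MSE, optimizer Adam, monitored
    metric validation MAE with early stopping and best-weight restore)."""

    batch_size: int = 64
    max_epochs: int = 100
    patience: int = 15
    lr: float = 1e-3
    val_fraction: float = 0.20
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.val_fraction < 1):
            raise ValueError("val_fraction must lie in (0, 1)")
        if self.patience > self.max_epochs:
            raise ValueError("patience must not exceed max_epochs")


class UNet1d:
    """The wired network: owns layer instances and the forward/backward pass."""

    def __init__(self, cfg: UNetConfig, rng: np.random.Generator):
        self.cfg = cfg
        k = cfg.kernel
        w = cfg.width
        self.enc: list[list[nn.Layer]] = []
        self.pools: list[nn.MaxPool1d] = []
        ch = cfg.in_channels
        for i in range(cfg.depth):
            wi = w * 2**i
            self.enc.append(
                [nn.Conv1d(ch, wi, k, rng), nn.ReLU(), nn.Conv1d(wi, wi, k, rng), nn.ReLU()]
            )
            self.pools.append(nn.MaxPool1d())
            ch = wi
        lb, cb = cfg.bottleneck_length, cfg.bottleneck_channels
        flat = lb * cb
        self.dense_feat = nn.Dense(flat, cfg.n_features, rng)
        self.feat_act = nn.LeakyReLU() if cfg.feature_activation == "relu" else None
        self.dense_back = nn.Dense(cfg.n_features, flat, rng)
        self.back_act = nn.LeakyReLU()
        wbot = w * 2**cfg.depth
        self.bottom = [
            nn.Conv1d(cb, wbot, k, rng), nn.ReLU(), nn.Conv1d(wbot, wbot, k, rng), nn.ReLU()
        ]
        self.dec: list[dict] = []
        ch = wbot
        for i in reversed(range(cfg.depth)):
            wi = w * 2**i
            if cfg.upsample == "transpose-conv":
                up: list[nn.Layer] = [nn.ConvTranspose1d(ch, wi, rng)]
            else:
                up = [nn.NearestUp(), nn.Conv1d(ch, wi, k, rng)]
            block = [nn.Conv1d(2 * wi, wi, k, rng), nn.ReLU(), nn.Conv1d(wi, wi, k, rng), nn.ReLU()]
            self.dec.append({"up": up, "block": block, "width": wi})
            ch = wi
        self.head = nn.Conv1d(w, 1, 1, rng)

    # -- plumbing -----------------------------------------------------------

    def layers(self) -> list[nn.Layer]:
        out: list[nn.Layer] = []
        for block in self.enc:
            out.extend(block)
        out.extend(self.pools)
        out.append(self.dense_feat)
        if self.feat_act is not None:
            out.append(self.feat_act)
        out.extend([self.dense_back, self.back_act])
        out.extend(self.bottom)
        for level in self.dec:
            out.extend(level["up"])
            out.extend(level["block"])
        out.append(self.head)
        return out

    def backbone_layers(self) -> list[nn.Layer]:
        """Convolutional layers only (dense bottleneck pair excluded)."""
        return [l for l in self.layers() if l not in (self.dense_feat, self.dense_back)]

    def n_params(self) -> int:
        return sum(l.n_params for l in self.layers())

    # -- passes -------------------------------------------------------------

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (reconstruction (n, L), feature activations (n, F))."""
        h = np.ascontiguousarray(x, dtype=F32)
        skips = []
        for block, pool in zip(self.enc, self.pools):
            for layer in block:
                h = layer.forward(h)
            skips.append(h)
            h = pool.forward(h)
        n = h.shape[0]
        self._bshape = h.shape
        h = h.reshape(n, -1)
        f = self.dense_feat.forward(h)
        if self.feat_act is not None:
            f = self.feat_act.forward(f)
        h = self.back_act.forward(self.dense_back.forward(f))
        h = h.reshape(self._bshape)
        for layer in self.bottom:
            h = layer.forward(h)
        for level, skip in zip(self.dec, reversed(skips)):
            for layer in level["up"]:
                h = layer.forward(h)
            h = np.concatenate([h, skip], axis=2)
            for layer in level["block"]:
                h = layer.forward(h)
        y = self.head.forward(h)
        return y[:, :, 0], f

    def backward(self, dy: np.ndarray) -> None:
        """Backpropagate loss gradient w.r.t. the reconstruction."""
        h = self.head.backward(dy[:, :, None].astype(F32, copy=False))
        dskips = []
        for level in reversed(self.dec):
            for layer in reversed(level["block"]):
                h = layer.backward(h)
            wi = level["width"]
            h, dskip = h[:, :, :wi], h[:, :, wi:]
            dskips.append(dskip)
            for layer in reversed(level["up"]):
                h = layer.backward(h)
        for layer in reversed(self.bottom):
            h = layer.backward(h)
        n = h.shape[0]
        h = self.dense_back.backward(self.back_act.backward(h.reshape(n, -1)))
        if self.feat_act is not None:
            h = self.feat_act.backward(h)
        h = self.dense_feat.backward(h)
        h = h.reshape(self._bshape)
        # decoder runs deepest-first, so walking it in reverse collected the
        # skip gradients already ordered by encoder level: dskips[i] <-> enc[i]
        for i in reversed(range(len(self.enc))):
            h = self.pools[i].backward(h)
            h = h + dskips[i]
            for layer in reversed(self.enc[i]):
                h = layer.backward(h)


def build_autoencoder(cfg: UNetConfig, seed: int = 0) -> "ModelHandle":
    """Instantiate an untrained model for the given architecture."""
    rng = np.random.default_rng(seed)
    return ModelHandle(cfg, UNet1d(cfg, rng), history=[])


def count_parameters(cfg: UNetConfig) -> tuple[int, int, int]:
    """Closed-form trainable-parameter counts for an architecture.

    Returns ``(backbone_weights, feature_dense_weights, total)`` where the
    backbone covers every convolutional layer (weights + biases), the
    feature-dense count is the weight matrix of the bottleneck dense layer
    alone (no bias, no back-projection — the figure quoted for the dense
    layer's size), and the total is every trainable parameter in the model.
    """
    k, w, d = cfg.kernel, cfg.width, cfg.depth
    backbone = 0
    ch = cfg.in_channels
    for i in range(d):
        wi = w * 2**i
        backbone += k * ch * wi + wi + k * wi * wi + wi
        ch = wi
    cb = cfg.bottleneck_channels
    wbot = w * 2**d
    backbone += k * cb * wbot + wbot + k * wbot * wbot + wbot
    ch = wbot
    for i in reversed(range(d)):
        wi = w * 2**i
        if cfg.upsample == "transpose-conv":
            backbone += 2 * ch * wi + wi
        else:
            backbone += k * ch * wi + wi
        backbone += k * (2 * wi) * wi + wi + k * wi * wi + wi
        ch = wi
    backbone += 1 * w * 1 + 1  # 1x1 head
    flat = cfg.bottleneck_length * cb
    feature_dense = flat * cfg.n_features
    total = (
        backbone
        + feature_dense + cfg.n_features          # bottleneck dense (+bias)
        + cfg.n_features * flat + flat            # back-projection dense (+bias)
    )
    return backbone, feature_dense, total


@dataclass
class ModelHandle:
    """A (config, network, history) bundle; ``history`` holds per-epoch
    train/validation loss and the monitored validation MAE."""

    config: UNetConfig
    net: UNet1d
    history: list[dict] = field(default_factory=list)
    trained: bool = False

    def save(self, path: str) -> None:
        state = nn.get_state(self.net.layers())
        flat = {f"l{i}_{k}": v for i, layer in enumerate(state) for k, v in layer.items()}
        np.savez(
            path,
            __config__=np.frombuffer(repr(asdict(self.config)).encode(), dtype=np.uint8),
            __trained__=np.array([self.trained]),
            **flat,
        )

    @classmethod
    def load(cls, path: str) -> "ModelHandle":
        data = np.load(path)
        cfg_repr = bytes(data["__config__"]).decode()
        cfg = UNetConfig(**eval(cfg_repr, {"__builtins__": {}}, {}))
        handle = build_autoencoder(cfg)
        layers = handle.net.layers()
        for i, layer in enumerate(layers):
            for k in layer.params:
                layer.params[k][...] = data[f"l{i}_{k}"]
        handle.trained = bool(data["__trained__"][0])
        return handle


class TrainingFailure(RuntimeError):
    pass


def _check_inputs(cfg: UNetConfig, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=F32)
    if X.ndim == 2:
        X = X[:, :, None]
    if X.ndim != 3 or X.shape[1] != cfg.input_length or X.shape[2] != cfg.in_channels:
        raise ValueError(
            f"expected inputs of shape (n, {cfg.input_length}, {cfg.in_channels}), got {X.shape}"
        )
    return X


def train_autoencoder(
    model: ModelHandle, X: np.ndarray, Y: np.ndarray, tcfg: TrainConfig | None = None
) -> ModelHandle:
    """Train in place with MSE loss, Adam, and MAE-monitored early stopping.

    The seed fixes the validation split, the initial weights are whatever
    the handle carries (seeded at build time), and the per-epoch batch
    order; reruns from the same handle state are bitwise identical.
    Stops when the epochs elapsed since the best validation MAE reach
    ``patience`` (so patience 0 trains exactly one epoch), then restores
    the best epoch's weights.
    """
    tcfg = tcfg or TrainConfig()
    cfg = model.config
    X = _check_inputs(cfg, X)
    Y = np.asarray(Y, dtype=F32)
    if Y.shape != (X.shape[0], cfg.input_length):
        raise ValueError(f"targets must be (n, {cfg.input_length}), got {Y.shape}")
    n = X.shape[0]
    rng = np.random.default_rng(tcfg.seed)
    perm = rng.permutation(n)
    n_val = max(1, int(round(tcfg.val_fraction * n)))
    if n_val >= n:
        raise ValueError("too few segments to carve out a validation split")
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    batch = tcfg.batch_size
    if batch > len(train_idx):
        batch = max(1, len(train_idx))
        warnings.warn(f"batch size reduced to {batch} (only {len(train_idx)} training segments)")

    layers = model.net.layers()
    opt = nn.Adam(layers, lr=tcfg.lr)
    best_metric = np.inf
    best_state = nn.get_state(layers)
    since_best = 0
    for epoch in range(tcfg.max_epochs):
        order = rng.permutation(train_idx)
        train_loss = 0.0
        n_batches = 0
        for start in range(0, len(order), batch):
            idx = order[start : start + batch]
            xb, yb = X[idx], Y[idx]
            pred, _ = model.net.forward(xb)
            err = pred - yb
            loss = float(np.mean(err**2))
            if not np.isfinite(loss):
                raise TrainingFailure(f"non-finite loss at epoch {epoch + 1}")
            model.net.backward((2.0 / err.size) * err)
            opt.step()
            train_loss += loss
            n_batches += 1
        val_pred = _predict_batched(model.net, X[val_idx])[0]
        val_err = val_pred - Y[val_idx]
        val_loss = float(np.mean(val_err**2))
        val_mae = float(np.mean(np.abs(val_err)))
        model.history.append(
            {
                "epoch": epoch + 1,
                "train_loss": train_loss / max(n_batches, 1),
                "val_loss": val_loss,
                "val_mae": val_mae,
                "lr": tcfg.lr,
                "optimizer": "adam",
            }
        )
        if val_mae < best_metric:
            best_metric = val_mae
            best_state = nn.get_state(layers)
            since_best = 0
        else:
            since_best += 1
        if since_best >= tcfg.patience:
            break
    nn.set_state(layers, best_state)
    model.trained = True
    return model


def _predict_batched(
    net: UNet1d, X: np.ndarray, batch: int = 128
) -> tuple[np.ndarray, np.ndarray]:
    recons, feats = [], []
    for start in range(0, X.shape[0], batch):
        r, f = net.forward(X[start : start + batch])
        recons.append(r)
        feats.append(f)
    return np.concatenate(recons), np.concatenate(feats)


def extract_features(model: ModelHandle, X: np.ndarray) -> np.ndarray:
    """Feature-layer activations, one row per input segment."""
    if not model.trained:
        raise NotFittedError("autoencoder has not been trained")
    X = _check_inputs(model.config, X)
    return _predict_batched(model.net, X)[1]


def reconstruct(model: ModelHandle, X: np.ndarray) -> np.ndarray:
    """Predicted target waveforms, shape (n, input_length)."""
    X = _check_inputs(model.config, X)
    return _predict_batched(model.net, X)[0]


class UNetFeatureExtractor(TransformerMixin, BaseEstimator):
    """Scikit-learn transformer facade over the U-Net autoencoder.

    ``fit(X, Y)`` trains the reconstruction network (X: ``(n, length,
    channels)`` predictors, Y: ``(n, length)`` normalized target
    waveforms); ``transform(X)`` returns the ``(n, n_features)`` bottleneck
    feature matrix.  All architecture fields of :class:`UNetConfig` and the
    training fields of :class:`TrainConfig` are exposed as estimator
    parameters so the transformer composes with sklearn model selection.
    """

    def __init__(
        self,
        depth: int = 1,
        width: int = 128,
        kernel: int = 3,
        in_channels: int = 4,
        n_features: int = 1024,
        target: str = "ABP",
        upsample: str = "transpose-conv",
        input_length: int = 1024,
        feature_activation: str = "relu",
        batch_size: int = 64,
        max_epochs: int = 100,
        patience: int = 15,
        lr: float = 1e-3,
        val_fraction: float = 0.20,
        random_state: int = 0,
    ):
        self.depth = depth
        self.width = width
        self.kernel = kernel
        self.in_channels = in_channels
        self.n_features = n_features
        self.target = target
        self.upsample = upsample
        self.input_length = input_length
        self.feature_activation = feature_activation
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.lr = lr
        self.val_fraction = val_fraction
        self.random_state = random_state

    def _configs(self) -> tuple[UNetConfig, TrainConfig]:
        ucfg = UNetConfig(
            depth=self.depth,
            width=self.width,
            kernel=self.kernel,
            in_channels=self.in_channels,
            n_features=self.n_features,
            target=self.target,
            upsample=self.upsample,
            input_length=self.input_length,
            feature_activation=self.feature_activation,
        )
        tcfg = TrainConfig(
            batch_size=self.batch_size,
            max_epochs=self.max_epochs,
            patience=self.patience,
            lr=self.lr,
            val_fraction=self.val_fraction,
            seed=self.random_state,
        )
        return ucfg, tcfg

    def fit(self, X: np.ndarray, y: np.ndarray) -> "UNetFeatureExtractor":
        ucfg, tcfg = self._configs()
        self.model_ = build_autoencoder(ucfg, seed=self.random_state)
        train_autoencoder(self.model_, X, y, tcfg)
        self.history_ = self.model_.history
        self.n_features_out_ = ucfg.n_features
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise NotFittedError("call fit before transform")
        return extract_features(self.model_, X)

    def reconstruct(self, X: np.ndarray) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise NotFittedError("call fit before reconstruct")
        return reconstruct(self.model_, X)
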