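"""Sliding-window LSTM-autoencoder and channel-wise reconstruction error.

The model compresses a (window x channel) block through two recurrent
layers (64, 32 units, ReLU) and two dense layers (32, 16) into a
16-dimensional latent vector, repeats the latent along the time axis, and
decodes through a per-step dense layer, a 32-unit recurrent layer, and a
per-step linear map back to the channel dimension.  The decoder output is
linear because targets are z-scored and can be negative.

One multivariate model is trained over all channels jointly; channel-wise
errors are obtained by decomposing the MSE over the output channels:

    error(w, c) = (1/W) * sum_t (y[t, c] - yhat[t, c])**2

so the mean over channels of ``error(w, :)`` equals the plain MSE of the
whole window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import nn
from .preprocess import WindowTensor


class GuardError(ValueError):
    """Training input violates the score-task-only training contract."""


@dataclass(frozen=True)
class ModelSpec:
    """Architecture hyperparameters of the sequence autoencoder."""

    window_len: int
    n_channels: int
    encoder_recurrent_units: tuple = (64, 32)
    encoder_dense_units: tuple = (32, 16)
    decoder_dense_units: tuple = (32,)
    decoder_recurrent_units: tuple = (32,)
    activation: str = "relu"

    def __post_init__(self) -> None:
        if self.window_len <= 0 or self.n_channels <= 0:
            raise ValueError("window_len and n_channels must be positive")
        for group in (
            self.encoder_recurrent_units,
            self.encoder_dense_units,
            self.decoder_dense_units,
            self.decoder_recurrent_units,
        ):
            if any(u <= 0 for u in group):
                raise ValueError("all unit counts must be positive")

    @property
    def latent_dim(self) -> int:
        return self.encoder_dense_units[-1]


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 200
    batch_size: int = 1024
    learning_rate: float = 1e-3
    validation_fraction: float = 0.2
    grad_clip_norm: float = 5.0
    seed: int = 0
    split_by_subject: bool = False

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must be in (0, 1)")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class TrainingHistory:
    """Per-epoch mean-squared-error losses on normalized data."""

    train_loss: list
    val_loss: list
    val_index: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": np.arange(1, len(self.train_loss) + 1),
                "train_loss": self.train_loss,
                "val_loss": self.val_loss,
            }
        )


class _SequenceAutoencoder:
    """NumPy realization of the encoder/repeat/decoder stack."""

    def __init__(self, spec: ModelSpec, seed: int):
        rng = np.random.default_rng(seed)
        self.spec = spec
        act = spec.activation
        layers_in = spec.n_channels
        self.enc_rec = []
        for k, units in enumerate(spec.encoder_recurrent_units):
            last = k == len(spec.encoder_recurrent_units) - 1
            self.enc_rec.append(nn.LSTM(rng, layers_in, units, activation=act, return_sequences=not last))
            layers_in = units
        self.enc_dense = []
        for units in spec.encoder_dense_units:
            self.enc_dense.append(nn.Dense(rng, layers_in, units, activation=act))
            layers_in = units
        self.dec_dense = []
        for units in spec.decoder_dense_units:
            self.dec_dense.append(nn.Dense(rng, layers_in, units, activation=act))
            layers_in = units
        self.dec_rec = []
        for units in spec.decoder_recurrent_units:
            self.dec_rec.append(nn.LSTM(rng, layers_in, units, activation=act, return_sequences=True))
            layers_in = units
        self.out = nn.Dense(rng, layers_in, spec.n_channels, activation=None)
        self.layers = self.enc_rec + self.enc_dense + self.dec_dense + self.dec_rec + [self.out]

    @property
    def params(self):
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self):
        return [g for layer in self.layers for g in layer.grads]

    def encode(self, x: np.ndarray) -> np.ndarray:
        h = x
        for layer in self.enc_rec:
            h = layer.forward(h)
        for layer in self.enc_dense:
            h = layer.forward(h)
        return h

    def forward(self, x: np.ndarray) -> np.ndarray:
        latent = self.encode(x)
        T = x.shape[1]
        h = np.repeat(latent[:, None, :], T, axis=1)  # RepeatVector
        for layer in self.dec_dense:
            h = layer.forward(h)
        for layer in self.dec_rec:
            h = layer.forward(h)
        return self.out.forward(h)

    def backward(self, dy: np.ndarray) -> None:
        d = self.out.backward(dy)
        for layer in reversed(self.dec_rec):
            d = layer.backward(d)
        for layer in reversed(self.dec_dense):
            d = layer.backward(d)
        d = d.sum(axis=1)  # undo RepeatVector
        for layer in reversed(self.enc_dense):
            d = layer.backward(d)
        for layer in reversed(self.enc_rec):
            d = layer.backward(d)


@dataclass
class ModelHandle:
    """Opaque trained-model reference plus the spec it realizes."""

    model: _SequenceAutoencoder
    spec: ModelSpec
    seed: int
    history: TrainingHistory | None = None

    def reconstruct(self, x: np.ndarray, batch_size: int = 4096) -> np.ndarray:
        x = np.asarray(x, dtype=nn.DTYPE)
        if x.ndim != 3 or x.shape[1] != self.spec.window_len or x.shape[2] != self.spec.n_channels:
            raise ValueError(
                f"expected (n, {self.spec.window_len}, {self.spec.n_channels}) input, got {x.shape}"
            )
        out = np.empty_like(x)
        for lo in range(0, x.shape[0], batch_size):
            out[lo : lo + batch_size] = self.model.forward(x[lo : lo + batch_size])
        return out

    def encode(self, x: np.ndarray) -> np.ndarray:
        return self.model.encode(np.asarray(x, dtype=nn.DTYPE))


def build_autoencoder(spec: ModelSpec, seed: int = 0) -> ModelHandle:
    """Untrained model with deterministic (seeded) weight initialization."""
    return ModelHandle(model=_SequenceAutoencoder(spec, seed), spec=spec, seed=seed)


def _mse(y: np.ndarray, yhat: np.ndarray) -> float:
    d = (y.astype(np.float64) - yhat.astype(np.float64)).ravel()
    return float(d @ d / d.size)


def train_autoencoder(
    handle: ModelHandle, windows: WindowTensor, cfg: TrainConfig, allow_non_score: bool = False
) -> TrainingHistory:
    """Train on score-task windows with Adam / MSE; returns the loss history.

    The score-task-only contract is enforced through window provenance
    (``allow_non_score`` overrides).  The validation split is a seeded
    random ``validation_fraction`` of windows, or of whole subjects when
    ``cfg.split_by_subject``.
    """
    tasks = set(windows.provenance["task"])
    if tasks - {"score"} and not allow_non_score:
        raise GuardError(
            f"training windows include non-score tasks {sorted(tasks - {'score'})}; "
            "pass allow_non_score=True to override"
        )
    x = np.asarray(windows.data, dtype=nn.DTYPE)
    n, W, C = x.shape
    if W != handle.spec.window_len or C != handle.spec.n_channels:
        raise ValueError(
            f"window shape ({W}, {C}) does not match spec "
            f"({handle.spec.window_len}, {handle.spec.n_channels})"
        )
    rng = np.random.default_rng(cfg.seed)
    if cfg.split_by_subject:
        subjects = np.asarray(windows.provenance["subject_id"])
        uniq = pd.unique(subjects)
        n_val_subj = max(1, int(round(cfg.validation_fraction * len(uniq))))
        val_subjects = set(rng.permutation(uniq)[:n_val_subj])
        val_mask = np.isin(subjects, list(val_subjects))
        val_idx = np.flatnonzero(val_mask)
        train_idx = np.flatnonzero(~val_mask)
    else:
        perm = rng.permutation(n)
        n_val = max(1, int(round(cfg.validation_fraction * n)))
        val_idx, train_idx = perm[:n_val], perm[n_val:]
    if train_idx.size == 0:
        raise ValueError("validation split leaves no training windows")

    model = handle.model
    opt = nn.Adam(model.params, lr=cfg.learning_rate)
    x_val = x[val_idx]
    train_losses: list[float] = []
    val_losses: list[float] = []
    for _ in range(cfg.epochs):
        order = rng.permutation(train_idx)
        epoch_sse = 0.0
        epoch_n = 0
        for lo in range(0, order.size, cfg.batch_size):
            xb = x[order[lo : lo + cfg.batch_size]]
            yhat = model.forward(xb)
            resid = yhat - xb
            epoch_sse += float(np.sum(resid.astype(np.float64) ** 2))
            epoch_n += resid.size
            model.backward(resid.astype(nn.DTYPE) * (2.0 / resid.size))
            nn.clip_global_norm(model.grads, cfg.grad_clip_norm)
            opt.step(model.grads)
        train_losses.append(epoch_sse / epoch_n)
        val_losses.append(_mse(x_val, handle.reconstruct(x_val)))
    history = TrainingHistory(train_loss=train_losses, val_loss=val_losses, val_index=val_idx)
    handle.history = history
    return history


def channelwise_mse(y: np.ndarray, yhat: np.ndarray) -> np.ndarray:
    """Per-window, per-channel mean squared error.

    ``y`` and ``yhat`` have shape (n, W, C) (or (W, C) for one window); the
    result has shape (n, C), with the mean taken over the window's time
    axis.  The mean over channels of each row equals the window's plain MSE.
    """
    y = np.asarray(y, dtype=np.float64)
    yhat = np.asarray(yhat, dtype=np.float64)
    if y.shape != yhat.shape:
        raise ValueError(f"shape mismatch: {y.shape} vs {yhat.shape}")
    single = y.ndim == 2
    if single:
        y, yhat = y[None], yhat[None]
    err = np.mean((y - yhat) ** 2, axis=1)
    return err[0] if single else err


def reconstruction_errors(handle: ModelHandle, windows: WindowTensor) -> np.ndarray:
    """(n_windows, n_channels) reconstruction-error matrix for a window stack."""
    yhat = handle.reconstruct(windows.data)
    return channelwise_mse(windows.data, yhat)


@dataclass
class ChannelErrorMap:
    """Per-(subject, task, channel) mean reconstruction error (tidy table)."""

    table: pd.DataFrame  # columns: subject_id, task, channel, mean_error
    channel_ids: tuple

    def grand_means(self, task: str) -> pd.Series:
        """Per-channel mean across subjects for one task (the bar-chart values)."""
        sub = self.table[self.table["task"] == task]
        if sub.empty:
            raise ValueError(f"no subjects with task {task!r}")
        return sub.groupby("channel")["mean_error"].mean()

    def subject_means(self, task: str) -> pd.DataFrame:
        sub = self.table[self.table["task"] == task]
        return sub.pivot(index="subject_id", columns="channel", values="mean_error")


def subject_channel_error(errors: np.ndarray, provenance: pd.DataFrame, channel_ids: Sequence[int]) -> ChannelErrorMap:
    """Average window errors per (subject, task, channel)."""
    errors = np.asarray(errors)
    if len(provenance) != errors.shape[0]:
        raise ValueError("provenance rows must match error rows")
    if len(provenance) == 0:
        raise ValueError("empty error matrix")
    frame = provenance[["subject_id", "task"]].copy()
    for j, ch in enumerate(channel_ids):
        frame[ch] = errors[:, j]
    tidy = (
        frame.groupby(["subject_id", "task"], sort=True)
        .mean()
        .reset_index()
        .melt(id_vars=["subject_id", "task"], var_name="channel", value_name="mean_error")
    )
    tidy["channel"] = tidy["channel"].astype(int)
    tidy = tidy.sort_values(["subject_id", "task", "channel"]).reset_index(drop=True)
    return ChannelErrorMap(table=tidy, channel_ids=tuple(int(c) for c in channel_ids))
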