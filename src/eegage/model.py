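"""Temporal convolutional age regressor with cropped decoding.

The decoder is a stack of dilated residual convolution blocks (dilation
2**i, valid convolutions, no padding) followed by a 1x1 convolution and a
sigmoid, so its output lives in [0, 1] and is mapped to years through the
training split's min-max age scaling. Because the convolutions are unpadded,
running the network over a full recording emits one output per maximally
overlapping crop of receptive-field length (one-sample stride) in a single
pass — the cropped-decoding trick. The per-recording brain age is the mean
of the per-crop sigmoid outputs, unscaled to years.

Training uses L1 loss on scaled targets, AdamW, cosine-annealed learning
rate, and channel-dropout augmentation; only non-pathological recordings are
used to fit the model, while pathological recordings are predicted for
analysis. Cross-validation splits subject-wise so no subject leaks between
folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ClassError, ConfigError, LeakageError, TooShortError
from .nn import AdamW, Conv1d, ResidualBlock, cosine_lr, sigmoid
from .preproc import (NormalizationStats, apply_normalization,
                      fit_normalization, scale_age, unscale_age)

__all__ = [
    "ModelConfig", "TrainConfig", "TCNRegressor",
    "make_crops", "channel_dropout", "train", "loss_history_mae",
    "predict_recording", "predict_crop_outputs", "subject_folds",
    "run_cv", "run_final_evaluation",
]


@dataclass
class ModelConfig:
    """Architecture of the dilated-convolution age regressor."""

    n_channels: int = 8
    n_blocks: int = 4
    kernel_size: int = 5
    n_filters: int = 32
    dropout: float = 0.1

    def validate(self) -> None:
        if not 0 <= self.dropout < 1:
            raise ConfigError("dropout must be in [0, 1)")
        if min(self.n_blocks, self.kernel_size, self.n_filters,
               self.n_channels) < 1:
            raise ConfigError("architecture sizes must be >= 1")

    @property
    def receptive_field(self) -> int:
        """Crop length: samples one output value depends on."""
        span = sum(2 * (self.kernel_size - 1) * 2 ** i
                   for i in range(self.n_blocks))
        return span + 1


@dataclass
class TrainConfig:
    """Optimization settings (clinical-scale defaults)."""

    epochs: int = 35
    batch_size: int = 128
    lr: float = 2e-3
    weight_decay: float = 1e-4
    channel_dropout_p: float = 0.1
    crops_per_recording: int = 16
    seed: int = 0

    def validate(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ConfigError("epochs and batch_size must be >= 1")
        if not 0 <= self.channel_dropout_p < 1:
            raise ConfigError("channel_dropout_p must be in [0, 1)")


class TCNRegressor:
    """Dilated residual convnet emitting a sigmoid age estimate per crop."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        config.validate()
        self.config = config
        rng = np.random.default_rng(seed)
        self.blocks = []
        in_ch = config.n_channels
        for i in range(config.n_blocks):
            self.blocks.append(ResidualBlock(
                in_ch, config.n_filters, config.kernel_size, 2 ** i,
                config.dropout, rng))
            in_ch = config.n_filters
        self.head = Conv1d(in_ch, 1, 1, 1, rng)
        # small head init keeps the pre-sigmoid output near 0 regardless of
        # the residual stack's activation scale; a saturated sigmoid at
        # initialization would zero the L1 gradient and freeze training
        self.head.W *= 0.05
        self._sig = None

    @property
    def receptive_field(self) -> int:
        return self.config.receptive_field

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None,
                cache: bool = True) -> np.ndarray:
        """(N, C, L) -> (N, L - RF + 1) sigmoid outputs, one per crop."""
        if x.shape[-1] < self.receptive_field:
            raise TooShortError(
                f"input of {x.shape[-1]} samples is shorter than the "
                f"receptive field ({self.receptive_field})")
        # float32 for speed, but honor float64 inputs (gradient checking,
        # saliency) where precision matters
        h = x if x.dtype == np.float64 else x.astype(np.float32, copy=False)
        for blk in self.blocks:
            h = blk.forward(h, training, rng, cache=cache)
        z = self.head.forward(h, cache=cache)
        y = sigmoid(z)
        if cache:
            self._sig = y
        return y[:, 0, :]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        """Backprop d(loss)/d(outputs) (N, L_out) down to the input."""
        gz = gy[:, None, :] * self._sig * (1.0 - self._sig)
        gh = self.head.backward(np.ascontiguousarray(gz))
        for blk in reversed(self.blocks):
            gh = blk.backward(gh)
        self._sig = None
        return gh

    def input_gradient(self, x: np.ndarray) -> np.ndarray:
        """Gradient of the summed per-crop sigmoid outputs w.r.t. the input."""
        y = self.forward(x, training=False, cache=True)
        return self.backward(np.ones_like(y))

    def params(self):
        out = []
        for blk in self.blocks:
            out += blk.params()
        out += self.head.params()
        return out


def make_crops(signal: np.ndarray, crop_len: int) -> np.ndarray:
    """All maximally overlapping crops (one-sample stride): (n, C, crop_len)."""
    n_samp = signal.shape[-1]
    if n_samp < crop_len:
        raise TooShortError(f"signal of {n_samp} samples < crop length {crop_len}")
    from numpy.lib.stride_tricks import sliding_window_view
    crops = sliding_window_view(signal, crop_len, axis=-1)
    return np.moveaxis(crops, -2, 0)


def channel_dropout(crops: np.ndarray, p: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Zero each channel of each crop independently with probability p."""
    if not 0 <= p < 1:
        raise ConfigError("channel dropout probability must be in [0, 1)")
    if p == 0:
        return crops
    mask = (rng.random(crops.shape[:-1]) >= p).astype(crops.dtype)
    return crops * mask[..., None]


def train(
    signals: list[np.ndarray],
    targets_scaled: np.ndarray,
    model_config: ModelConfig,
    train_config: TrainConfig,
) -> tuple[TCNRegressor, list[float]]:
    """Fit the regressor on standardized signals and [0, 1]-scaled targets.

    Each epoch draws ``crops_per_recording`` random receptive-field-length
    crops per recording, applies channel-dropout augmentation, and minimizes
    the L1 loss with AdamW under cosine learning-rate annealing. Returns the
    model and the per-epoch mean training loss.
    """
    model_config.validate()
    train_config.validate()
    rf = model_config.receptive_field
    for s in signals:
        if s.shape[-1] < rf:
            raise TooShortError("a training recording is shorter than the "
                                f"receptive field ({rf} samples)")
    targets_scaled = np.asarray(targets_scaled, dtype=np.float32)
    rng = np.random.default_rng(train_config.seed)
    model = TCNRegressor(model_config, seed=int(rng.integers(2 ** 31)))
    opt = AdamW(model.params(), lr=train_config.lr,
                weight_decay=train_config.weight_decay)

    n_rec = len(signals)
    cpr = train_config.crops_per_recording
    steps_per_epoch = max(1, (n_rec * cpr) // train_config.batch_size)
    total_steps = steps_per_epoch * train_config.epochs
    history: list[float] = []
    step = 0
    for _epoch in range(train_config.epochs):
        xs = np.empty((n_rec * cpr, signals[0].shape[0], rf), dtype=np.float32)
        ys = np.empty(n_rec * cpr, dtype=np.float32)
        pos = 0
        for i, sig in enumerate(signals):
            starts = rng.integers(0, sig.shape[-1] - rf + 1, size=cpr)
            for st in starts:
                xs[pos] = sig[:, st:st + rf]
                ys[pos] = targets_scaled[i]
                pos += 1
        order = rng.permutation(pos)
        xs, ys = xs[order], ys[order]

        epoch_losses = []
        for b0 in range(0, pos, train_config.batch_size):
            xb = xs[b0:b0 + train_config.batch_size]
            yb = ys[b0:b0 + train_config.batch_size]
            xb = channel_dropout(xb, train_config.channel_dropout_p, rng)
            out = model.forward(xb, training=True, rng=rng)[:, 0]
            resid = out - yb
            loss = float(np.abs(resid).mean())
            epoch_losses.append(loss)
            gy = (np.sign(resid) / len(yb)).astype(np.float32)
            opt.zero_grad()
            model.backward(gy[:, None])
            opt.step(lr=cosine_lr(step, total_steps, train_config.lr))
            step += 1
        history.append(float(np.mean(epoch_losses)))
    return model, history


def loss_history_mae(history: list[float], stats: NormalizationStats) -> list[float]:
    """Loss history converted from scaled units to years."""
    span = stats.age_max - stats.age_min
    return [h * span for h in history]


def predict_crop_outputs(model: TCNRegressor, signal: np.ndarray) -> np.ndarray:
    """Per-crop sigmoid outputs for a full standardized recording."""
    return model.forward(signal[None, :, :], training=False, cache=False)[0]


def predict_recording(model: TCNRegressor, signal: np.ndarray,
                      stats: NormalizationStats) -> float:
    """Brain age in years: mean per-crop output, unscaled via ``stats``."""
    return float(unscale_age(stats, float(predict_crop_outputs(model, signal).mean())))


def subject_folds(subject_ids: list[str], k: int, seed: int) -> list[list[str]]:
    """Shuffle subjects and partition them into k folds (subject-wise CV)."""
    unique = sorted(set(subject_ids))
    if len(unique) < k:
        raise ClassError(f"need at least {k} subjects for {k}-fold CV")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(unique))
    folds: list[list[str]] = [[] for _ in range(k)]
    for pos, idx in enumerate(order):
        folds[pos % k].append(unique[idx])
    return folds


def _fit_fold(train_recs, model_config, train_config, fold_seed):
    """Fit normalization + model on the non-pathological training recordings."""
    np_train = [r for r in train_recs if not r["pathology"]]
    if not np_train:
        raise ClassError("no non-pathological recordings available for training")
    stats = fit_normalization([r["signal"] for r in np_train],
                              [r["age"] for r in np_train])
    signals = [apply_normalization(stats, r["signal"]).astype(np.float32)
               for r in np_train]
    targets = scale_age(stats, np.array([r["age"] for r in np_train]))
    tc = TrainConfig(**{**train_config.__dict__, "seed": fold_seed})
    model, history = train(signals, targets, model_config, tc)
    return model, stats, history


def _as_records(recordings, preprocessed):
    return [{
        "recording_id": r.recording_id,
        "subject_id": r.subject_id,
        "date_days": r.date_days,
        "age": r.age_header,
        "pathology": bool(r.pathology),
        "signal": sig,
    } for r, sig in zip(recordings, preprocessed)]


def run_cv(
    recordings,
    preprocessed: list[np.ndarray],
    model_config: ModelConfig,
    train_config: TrainConfig,
    k: int = 5,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[dict]]:
    """Subject-wise k-fold cross-validation.

    Every recording is predicted exactly once as part of a validation fold;
    training within each fold uses only the non-pathological recordings of
    the other folds. Returns the prediction table and per-fold artifacts
    (model, normalization stats, loss history).
    """
    recs = _as_records(recordings, preprocessed)
    folds = subject_folds([r["subject_id"] for r in recs], k, seed)
    rows = []
    artifacts = []
    for fi, val_subjects in enumerate(folds):
        val_set = set(val_subjects)
        train_recs = [r for r in recs if r["subject_id"] not in val_set]
        val_recs = [r for r in recs if r["subject_id"] in val_set]
        model, stats, history = _fit_fold(train_recs, model_config,
                                          train_config, seed + 1000 * (fi + 1))
        for r in val_recs:
            ba = predict_recording(model, apply_normalization(stats, r["signal"]),
                                   stats)
            rows.append({
                "recording_id": r["recording_id"], "subject_id": r["subject_id"],
                "date_days": r["date_days"], "split": f"cv_fold_{fi}",
                "chronological_age": r["age"], "brain_age_raw": ba,
                "pathology": r["pathology"],
            })
        artifacts.append({"model": model, "stats": stats, "history": history,
                          "fold": fi})
    return pd.DataFrame(rows), artifacts


def run_final_evaluation(
    train_recordings,
    train_preprocessed: list[np.ndarray],
    eval_recordings,
    eval_preprocessed: list[np.ndarray],
    model_config: ModelConfig,
    train_config: TrainConfig,
    n_runs: int = 5,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[dict]]:
    """Final evaluation: train on all training data, predict held-out data.

    Repeated ``n_runs`` times with varying seeds to average out weight
    initialization; the reported brain age per recording is the mean over
    runs. Train and evaluation subject sets must be disjoint.
    """
    train_subjects = {r.subject_id for r in train_recordings}
    eval_subjects = {r.subject_id for r in eval_recordings}
    overlap = train_subjects & eval_subjects
    if overlap:
        raise LeakageError(f"subjects in both splits: {sorted(overlap)[:5]}")

    train_recs = _as_records(train_recordings, train_preprocessed)
    eval_recs = _as_records(eval_recordings, eval_preprocessed)
    per_run = np.zeros((n_runs, len(eval_recs)))
    artifacts = []
    for run in range(n_runs):
        model, stats, history = _fit_fold(train_recs, model_config,
                                          train_config, seed + run)
        for j, r in enumerate(eval_recs):
            per_run[run, j] = predict_recording(
                model, apply_normalization(stats, r["signal"]), stats)
        artifacts.append({"model": model, "stats": stats, "history": history,
                          "run": run})
    rows = [{
        "recording_id": r["recording_id"], "subject_id": r["subject_id"],
        "date_days": r["date_days"], "split": "final_eval",
        "chronological_age": r["age"],
        "brain_age_raw": float(per_run[:, j].mean()),
        "pathology": r["pathology"],
    } for j, r in enumerate(eval_recs)]
    return pd.DataFrame(rows), artifacts
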