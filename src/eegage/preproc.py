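"""Preprocessing chain and training-time normalization.

The chain applied to every recording, in order: channel selection ->
amplitude clipping (+/-800 uV) -> common average reference -> resampling to
100 Hz -> dropping the first minute. Channel-wise standardization statistics
and the min-max age scaling are fit on the training split only and carried
as :class:`NormalizationStats` with a provenance tag so leakage is
assertable.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

import numpy as np
import yaml
from scipy.signal import resample_poly

from .errors import ConfigError, DegenerateDataError, MontageError, TooShortError
from .synthetic import FULL_1020_CHANNELS, Recording

__all__ = [
    "PreprocConfig", "NormalizationStats",
    "select_channels", "clip_amplitudes", "common_average_reference",
    "resample", "drop_head", "preprocess_signal", "preprocess_recording",
    "fit_normalization", "apply_normalization", "scale_age", "unscale_age",
]

logger = logging.getLogger(__name__)


@dataclass
class PreprocConfig:
    """Preprocessing parameters (clinical-default values)."""

    channels: tuple[str, ...] = FULL_1020_CHANNELS
    clip_uv: float = 800.0
    target_sfreq: float = 100.0
    drop_head_s: float = 60.0
    min_duration_s: float = 120.0

    def validate(self) -> None:
        if self.clip_uv <= 0:
            raise ConfigError("clip_uv must be positive")
        if self.target_sfreq <= 0:
            raise ConfigError("target_sfreq must be positive")
        if self.drop_head_s < 0:
            raise ConfigError("drop_head_s must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PreprocConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown preprocessing keys: {sorted(unknown)}")
        if isinstance(raw.get("channels"), list):
            raw["channels"] = tuple(raw["channels"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg


def select_channels(
    signal: np.ndarray,
    labels: list[str] | tuple[str, ...],
    config: PreprocConfig,
) -> np.ndarray:
    """Restrict and reorder rows of ``signal`` to ``config.channels``.

    Extra channels (e.g. ECG, photic) are dropped; a missing required channel
    raises :class:`MontageError` naming it.
    """
    index = {lab: i for i, lab in enumerate(labels)}
    rows = []
    for ch in config.channels:
        if ch not in index:
            raise MontageError(f"required channel {ch!r} missing from {list(labels)}")
        rows.append(index[ch])
    return np.asarray(signal)[rows]


def clip_amplitudes(signal: np.ndarray, clip_uv: float) -> np.ndarray:
    if clip_uv <= 0:
        raise ConfigError("clip_uv must be positive")
    return np.clip(signal, -clip_uv, clip_uv)


def common_average_reference(signal: np.ndarray) -> np.ndarray:
    """Subtract the instantaneous mean over channels from every channel."""
    signal = np.asarray(signal, dtype=float)
    if signal.shape[0] < 2:
        raise ConfigError("common average reference needs >= 2 channels")
    return signal - signal.mean(axis=0, keepdims=True)


def resample(signal: np.ndarray, sfreq_in: float, sfreq_out: float) -> np.ndarray:
    """Band-limited polyphase resampling (Kaiser window, deterministic)."""
    if sfreq_in <= 0 or sfreq_out <= 0:
        raise ConfigError("sampling rates must be positive")
    if math.isclose(sfreq_in, sfreq_out):
        return np.asarray(signal, dtype=float).copy()
    frac = Fraction(sfreq_out / sfreq_in).limit_denominator(1000)
    out = resample_poly(signal, frac.numerator, frac.denominator, axis=-1)
    n_target = int(round(signal.shape[-1] * sfreq_out / sfreq_in))
    return out[..., :n_target]


def drop_head(signal: np.ndarray, sfreq: float, drop_head_s: float) -> np.ndarray:
    """Remove the first ``drop_head_s`` seconds (outlier-prone segment)."""
    n_drop = int(round(drop_head_s * sfreq))
    if signal.shape[-1] <= n_drop:
        raise TooShortError(
            f"recording of {signal.shape[-1] / sfreq:.1f} s is not longer than "
            f"the {drop_head_s:.1f} s head segment to drop"
        )
    return np.asarray(signal)[..., n_drop:]


def preprocess_signal(
    signal: np.ndarray,
    labels: list[str] | tuple[str, ...],
    sfreq: float,
    config: PreprocConfig,
) -> np.ndarray:
    """Full chain: select -> clip -> CAR -> resample -> drop head."""
    x = select_channels(signal, labels, config)
    x = clip_amplitudes(x, config.clip_uv)
    x = common_average_reference(x)
    x = resample(x, sfreq, config.target_sfreq)
    x = drop_head(x, config.target_sfreq, config.drop_head_s)
    return x


def preprocess_recording(rec: Recording, config: PreprocConfig) -> np.ndarray:
    if rec.signal is None:
        raise ValueError(f"recording {rec.recording_id} carries no signal")
    return preprocess_signal(rec.signal, rec.channel_names, rec.sfreq, config)


@dataclass
class NormalizationStats:
    """Channel standardization and age min-max scaling, fit on training data.

    ``source`` records which split the statistics came from, so tests can
    assert that validation/evaluation recordings never contributed.
    """

    mean: np.ndarray          # per channel, uV
    sd: np.ndarray            # per channel, uV
    age_min: float
    age_max: float
    source: str = "train"

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if np.any(self.sd <= 0):
            raise DegenerateDataError("per-channel sd must be > 0")
        if not self.age_min < self.age_max:
            raise DegenerateDataError("age_min must be < age_max")


def fit_normalization(
    signals: list[np.ndarray],
    ages: list[float] | np.ndarray,
    source: str = "train",
) -> NormalizationStats:
    """Pooled per-channel mean/sd over all training recordings + age range."""
    if not signals:
        raise DegenerateDataError("cannot fit normalization on an empty training set")
    n_total = sum(s.shape[1] for s in signals)
    mean = sum(s.sum(axis=1) for s in signals) / n_total
    ssq = sum(((s - mean[:, None]) ** 2).sum(axis=1) for s in signals)
    sd = np.sqrt(ssq / n_total)
    if np.any(sd <= 0):
        bad = int(np.argmin(sd))
        raise DegenerateDataError(f"channel {bad} has zero variance in training data")
    ages = np.asarray(ages, dtype=float)
    return NormalizationStats(mean, sd, float(ages.min()), float(ages.max()),
                              source=source)


def apply_normalization(stats: NormalizationStats, signal: np.ndarray) -> np.ndarray:
    return (signal - stats.mean[:, None]) / stats.sd[:, None]


def scale_age(stats: NormalizationStats, age: float | np.ndarray):
    """Min-max scale ages to [0, 1]; out-of-range values clamp with a warning."""
    span = stats.age_max - stats.age_min
    scaled = (np.asarray(age, dtype=float) - stats.age_min) / span
    if np.any(scaled < 0) or np.any(scaled > 1):
        logger.warning("age outside training range [%s, %s]; clamping to [0, 1]",
                       stats.age_min, stats.age_max)
        scaled = np.clip(scaled, 0.0, 1.0)
    return float(scaled) if np.isscalar(age) else scaled


def unscale_age(stats: NormalizationStats, value: float | np.ndarray):
    """Map model outputs in [0, 1] back to years (no clamping)."""
    out = np.asarray(value, dtype=float) * (stats.age_max - stats.age_min) + stats.age_min
    return float(out) if np.isscalar(value) else out
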