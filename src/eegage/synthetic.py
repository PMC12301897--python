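"""Synthetic clinical-EEG cohort generator.

Produces longitudinal cohorts with the statistical structure the brain-age
analysis assumes: an age-dependent EEG spectrum that a decoder can learn, a
stable per-subject ("trait") gap offset, an optional pathology-linked
("state") gap shift, repeated recordings per subject with month-scale
intervals, single-flip pathology-label transitions, dual age sources with
occasional mismatch, and keyword-bearing free-text reports.

The spectral aging model is deliberately simple and fully declared: pink
background noise plus an alpha oscillation whose peak frequency decreases
linearly with (effective) age and whose amplitude is strongest occipitally.
Pathological recordings additionally carry increased delta/theta power and
attenuated alpha — classic slowing. All coefficients are config fields.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError

__all__ = [
    "CohortConfig",
    "Recording",
    "SubjectLatents",
    "generate_cohort",
    "simulate_recording",
    "write_manifest",
    "read_manifest",
    "DESK_CHANNELS",
    "FULL_1020_CHANNELS",
    "MANIFEST_COLUMNS",
]

#: Desk-scale 8-channel montage (frontal, central, temporal, occipital).
DESK_CHANNELS = ("Fp1", "Fp2", "C3", "C4", "T5", "T6", "O1", "O2")

#: The full 21-electrode 10-20 set used clinically.
FULL_1020_CHANNELS = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "A1", "T3", "C3", "Cz", "C4", "T4", "A2",
    "T5", "P3", "Pz", "P4", "T6", "O1", "O2",
)

MANIFEST_COLUMNS = [
    "subject_id", "recording_id", "date_days", "age_header", "age_report",
    "sex", "pathology", "report", "edf_path", "duration_s",
]

# Occipital-dominant spatial weighting of the alpha rhythm by electrode site.
_ALPHA_SITE_WEIGHT = {"O": 1.0, "P": 0.7, "T": 0.55, "C": 0.4, "F": 0.25, "A": 0.2}


def _alpha_weight(label: str) -> float:
    key = label[0].upper()
    if label[:2].lower() == "fp":
        key = "F"
    return _ALPHA_SITE_WEIGHT.get(key, 0.4)


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort.

    Fractions are in [0, 1]; ages and gap offsets in years; intervals in
    months; signal parameters in Hz / seconds / microvolts.
    """

    n_subjects: int = 200
    age_range: tuple[float, float] = (18.0, 86.0)
    sex_ratio: float = 0.55                    # fraction female
    recordings_per_subject_mean: float = 2.5   # shifted-Poisson mean, >= 1
    interval_months_mean: float = 12.0         # lognormal mean gap between sessions
    interval_lognorm_sigma: float = 0.6
    pathology_fraction: float = 0.4
    transition_fraction: float = 0.1           # subjects whose label flips once
    trait_sd: float = 3.0                      # per-subject stable gap offset sigma
    state_effect: float = 0.0                  # gap shift while pathological
    n_channels: int = 8
    channels: tuple[str, ...] = DESK_CHANNELS
    sfreq: float = 100.0
    duration_s: float = 120.0
    age_mismatch_fraction: float = 0.05
    seed: int = 0

    # spectral aging model (all overridable)
    alpha_freq_young: float = 11.0             # Hz at effective age 0
    alpha_slope_per_year: float = 0.03         # Hz lost per year of effective age
    alpha_amp_uv: float = 20.0                 # occipital alpha amplitude
    pink_exponent: float = 1.0                 # 1/f^exponent background power
    pink_rms_uv: float = 10.0
    slow_boost: float = 0.5                    # +50% delta/theta power when pathological
    alpha_attenuation: float = 0.3             # -30% alpha amplitude when pathological
    keyword_fraction_path: float = 0.3         # pathological subjects with condition keyword
    keyword_fraction_np: float = 0.05

    def validate(self) -> None:
        for name in ("sex_ratio", "pathology_fraction", "transition_fraction",
                     "age_mismatch_fraction", "keyword_fraction_path",
                     "keyword_fraction_np"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} not in [0, 1]")
        if self.n_subjects < 0:
            raise ConfigError("n_subjects must be >= 0")
        lo, hi = self.age_range
        if not lo < hi:
            raise ConfigError(f"age_range must satisfy lo < hi, got {self.age_range}")
        if self.sfreq <= 0:
            raise ConfigError("sfreq must be positive")
        if self.duration_s <= 0:
            raise ConfigError("duration_s must be positive")
        if self.recordings_per_subject_mean < 1:
            raise ConfigError("recordings_per_subject_mean must be >= 1")
        if self.trait_sd < 0 or self.interval_months_mean <= 0:
            raise ConfigError("trait_sd must be >= 0 and interval_months_mean > 0")
        if len(self.channels) != self.n_channels:
            raise ConfigError(
                f"n_channels={self.n_channels} but {len(self.channels)} channel names"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown cohort config keys: {sorted(unknown)}")
        for key in ("age_range", "channels"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        cfg = cls(**raw)
        cfg.validate()
        return cfg


@dataclass
class Recording:
    """One EEG session: signal matrix plus the metadata the analysis uses."""

    subject_id: str
    recording_id: str
    date_days: int                 # days since cohort origin
    age_header: float              # years, from the file header
    age_report: float              # years, as stated in the medical report
    sex: str                       # "F" or "M"
    pathology: bool
    report: str
    signal: np.ndarray | None      # channels x samples, microvolts
    sfreq: float
    channel_names: tuple[str, ...]

    @property
    def duration_s(self) -> float:
        if self.signal is not None:
            return self.signal.shape[1] / self.sfreq
        return self._duration_s

    _duration_s: float = 0.0


@dataclass
class SubjectLatents:
    """Ground-truth latent structure of one synthetic subject."""

    subject_id: str
    trait_offset: float                       # years, constant across recordings
    state_offset_active: list[bool]           # per recording, date order
    effective_ages: list[float] = field(default_factory=list)
    chronological_ages: list[float] = field(default_factory=list)
    is_transition: bool = False


_REPORT_TEMPLATES_NP = [
    "Routine EEG. Normal awake record. No epileptiform discharges.",
    "EEG within normal limits for age. Follow-up as needed.",
]
_REPORT_TEMPLATES_P = [
    "Abnormal EEG due to diffuse background slowing.",
    "Abnormal record. Excess slow activity, attenuated posterior rhythm.",
]
_CONDITION_PHRASES = {
    "schizophrenia": ["Hx of schizoaffective disorder.", "Known SCHIZOPHRENIA."],
    "depression": ["History of depression.", "Treated for major DEPRESSION."],
    "stroke": ["Prior stroke in 2010.", "s/p left MCA STROKE."],
}


def simulate_recording(
    effective_age: float,
    pathological: bool,
    config: CohortConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Synthesize one multichannel EEG epoch in microvolts.

    The signal is pink noise plus an alpha oscillation whose peak frequency
    falls linearly with ``effective_age`` and is strongest occipitally;
    pathological recordings get extra delta/theta power and attenuated alpha.
    Deterministic given the generator state.
    """
    age = float(np.clip(effective_age, 0.0, 120.0))
    n = int(round(config.duration_s * config.sfreq))
    n_ch = config.n_channels
    t = np.arange(n) / config.sfreq

    # pink background: shape white noise in the frequency domain
    freqs = np.fft.rfftfreq(n, 1.0 / config.sfreq)
    amp_shape = np.ones_like(freqs)
    nonzero = freqs > 0
    amp_shape[nonzero] = freqs[nonzero] ** (-config.pink_exponent / 2.0)
    amp_shape[0] = 0.0
    spec = (rng.standard_normal((n_ch, freqs.size))
            + 1j * rng.standard_normal((n_ch, freqs.size))) * amp_shape
    pink = np.fft.irfft(spec, n=n, axis=1)
    pink *= config.pink_rms_uv / pink.std(axis=1, keepdims=True)

    f_alpha = max(config.alpha_freq_young - config.alpha_slope_per_year * age, 1.0)
    alpha_amp = config.alpha_amp_uv * (1.0 - config.alpha_attenuation * pathological)
    phases = rng.uniform(0, 2 * np.pi, size=n_ch)
    weights = np.array([_alpha_weight(ch) for ch in config.channels])
    alpha = alpha_amp * weights[:, None] * np.sin(
        2 * np.pi * f_alpha * t[None, :] + phases[:, None]
    )

    signal = pink + alpha
    if pathological:
        # diffuse slowing: one delta and one theta component on every channel
        for lo, hi in ((1.0, 3.5), (4.5, 7.5)):
            f = rng.uniform(lo, hi)
            ph = rng.uniform(0, 2 * np.pi, size=n_ch)
            amp = config.slow_boost * config.pink_rms_uv
            signal = signal + amp * np.sin(2 * np.pi * f * t[None, :] + ph[:, None])
    return signal


def _make_report(pathological: bool, condition: str | None,
                 rng: np.random.Generator) -> str:
    pool = _REPORT_TEMPLATES_P if pathological else _REPORT_TEMPLATES_NP
    text = pool[rng.integers(len(pool))]
    if condition is not None:
        text += " " + _CONDITION_PHRASES[condition][rng.integers(2)]
    return text


def generate_cohort(
    config: CohortConfig,
    signals: bool = True,
) -> tuple[list[Recording], list[SubjectLatents]]:
    """Generate a cohort of recordings plus the per-subject latent truth.

    ``signals=False`` produces metadata-only recordings (``signal=None``),
    useful for large statistical checks that never touch the waveforms.
    Deterministic for a fixed ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    lo, hi = config.age_range
    day_per_year = 365.25

    recordings: list[Recording] = []
    latents: list[SubjectLatents] = []
    for i in range(config.n_subjects):
        sid = f"S{i:05d}"
        sex = "F" if rng.random() < config.sex_ratio else "M"
        age0 = rng.uniform(lo, hi)
        trait = rng.normal(0.0, config.trait_sd) if config.trait_sd > 0 else 0.0
        is_transition = rng.random() < config.transition_fraction
        base_path = rng.random() < config.pathology_fraction

        n_rec = 1 + rng.poisson(config.recordings_per_subject_mean - 1.0)
        if is_transition:
            n_rec = max(n_rec, 2)

        # month-scale lognormal intervals with the configured mean
        mean_days = config.interval_months_mean * 30.4375
        sigma = config.interval_lognorm_sigma
        mu = math.log(mean_days) - sigma ** 2 / 2.0
        intervals = rng.lognormal(mu, sigma, size=max(n_rec - 1, 0))
        start = float(rng.uniform(0, 365))
        dates = np.floor(start + np.concatenate([[0.0], np.cumsum(intervals)])).astype(int)

        if is_transition:
            np_to_p = rng.random() < 0.5   # direction split 50/50
            flip_at = int(rng.integers(1, n_rec))
            labels = [
                (k >= flip_at) if np_to_p else (k < flip_at)
                for k in range(n_rec)
            ]
        else:
            labels = [base_path] * n_rec

        lat = SubjectLatents(sid, trait, list(labels), is_transition=is_transition)
        for k in range(n_rec):
            ca = age0 + (dates[k] - dates[0]) / day_per_year
            eff = ca + trait + (config.state_effect if labels[k] else 0.0)
            lat.effective_ages.append(eff)
            lat.chronological_ages.append(ca)

            age_header = ca
            age_report = ca
            if rng.random() < config.age_mismatch_fraction:
                age_report = ca + rng.choice([-1, 1]) * rng.uniform(1.01, 5.0)

            condition = None
            kw_frac = (config.keyword_fraction_path if labels[k]
                       else config.keyword_fraction_np)
            if rng.random() < kw_frac:
                condition = str(rng.choice(list(_CONDITION_PHRASES)))

            sig = None
            if signals:
                sig = simulate_recording(eff, labels[k], config, rng)
            recordings.append(Recording(
                subject_id=sid,
                recording_id=f"{sid}_R{k:02d}",
                date_days=int(dates[k]),
                age_header=age_header,
                age_report=max(age_report, 0.0),
                sex=sex,
                pathology=bool(labels[k]),
                report=_make_report(labels[k], condition, rng),
                signal=sig,
                sfreq=config.sfreq,
                channel_names=tuple(config.channels),
                _duration_s=config.duration_s,
            ))
        latents.append(lat)
    return recordings, latents


def write_manifest(recordings: list[Recording], path: str | Path) -> pd.DataFrame:
    """Write the cohort manifest (one CSV row per recording) and return it."""
    df = recordings_to_manifest(recordings)
    df.to_csv(path, index=False)
    return df


def recordings_to_manifest(recordings: list[Recording]) -> pd.DataFrame:
    rows = [{
        "subject_id": r.subject_id,
        "recording_id": r.recording_id,
        "date_days": r.date_days,
        "age_header": r.age_header,
        "age_report": r.age_report,
        "sex": r.sex,
        "pathology": bool(r.pathology),
        "report": r.report,
        "edf_path": "",
        "duration_s": r.duration_s,
    } for r in recordings]
    return pd.DataFrame(rows, columns=MANIFEST_COLUMNS)


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False, dtype={"subject_id": str,
                                                         "recording_id": str})
    df["pathology"] = df["pathology"].astype(str).str.lower().isin(("true", "1"))
    df["date_days"] = df["date_days"].astype(int)
    for col in ("age_header", "age_report", "duration_s"):
        df[col] = df[col].astype(float)
    return df
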