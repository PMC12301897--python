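"""Amplitude-gradient saliency: spectral-spatial model introspection.

Each crop is re-parameterized through its discrete Fourier transform as
amplitudes and phases; the gradient of the model output with respect to each
frequency-component amplitude (phases held fixed) is obtained from the
time-domain input gradient via the chain rule. Signed bin gradients are then
averaged into the classic frequency bands per channel, and aggregated
crop -> recording -> subject -> group -> run. Negative values mean that
increasing amplitude at that channel/frequency lowers the predicted age.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import TCNRegressor, make_crops

__all__ = [
    "BandDefinition", "DEFAULT_BANDS",
    "amplitude_gradients", "band_aggregate", "recording_saliency",
    "group_saliency",
]


@dataclass(frozen=True)
class BandDefinition:
    name: str
    lo: float   # Hz, inclusive
    hi: float   # Hz, exclusive


DEFAULT_BANDS = (
    BandDefinition("delta", 0.5, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 12.0),
    BandDefinition("beta", 12.0, 30.0),
    BandDefinition("gamma", 30.0, 50.0),
)


def _amp_factors(n: int) -> np.ndarray:
    """d(time signal)/d(amplitude) scale per rfft bin (numpy convention)."""
    n_bins = n // 2 + 1
    fac = np.full(n_bins, 2.0 / n)
    fac[0] = 1.0 / n
    if n % 2 == 0:
        fac[-1] = 1.0 / n
    return fac


def amplitude_gradients_from_time(g_time: np.ndarray,
                                  x: np.ndarray) -> np.ndarray:
    """Chain rule from time-domain gradients to per-bin amplitude gradients.

    ``g_time`` and ``x`` have shape (..., n_samples); returns
    (..., n_bins) signed gradients d(output)/d(A_f) with phases fixed at the
    crop's own DFT phases.
    """
    n = x.shape[-1]
    phases = np.angle(np.fft.rfft(x, axis=-1))
    g_spec = np.conj(np.fft.rfft(g_time, axis=-1))
    return _amp_factors(n) * np.real(np.exp(1j * phases) * g_spec)


def amplitude_gradients(model: TCNRegressor, crop: np.ndarray) -> np.ndarray:
    """Channel x frequency-bin gradients of the model output for one crop."""
    g = model.input_gradient(np.asarray(crop, dtype=np.float64)[None])[0]
    return amplitude_gradients_from_time(g, np.asarray(crop, float))


def band_aggregate(bin_gradients: np.ndarray, n_samples: int, sfreq: float,
                   bands=DEFAULT_BANDS) -> np.ndarray:
    """Mean signed bin gradient per band: (..., n_bins) -> (..., n_bands)."""
    freqs = np.fft.rfftfreq(n_samples, 1.0 / sfreq)
    out = np.full(bin_gradients.shape[:-1] + (len(bands),), np.nan)
    for bi, band in enumerate(bands):
        if band.hi > sfreq / 2 + 1e-9:
            raise ValueError(f"band {band.name} exceeds the Nyquist frequency")
        mask = (freqs >= band.lo) & (freqs < band.hi)
        if mask.any():
            out[..., bi] = bin_gradients[..., mask].mean(axis=-1)
    return out


def recording_saliency(model: TCNRegressor, signal: np.ndarray, sfreq: float,
                       bands=DEFAULT_BANDS, max_crops: int = 32) -> np.ndarray:
    """Channel x band saliency of one standardized recording.

    Uses receptive-field-length crops; to keep the cost bounded, crops are
    taken at a regular stride chosen so at most ``max_crops`` contribute
    (they are averaged, so subsampling the maximally overlapping set changes
    only the sampling density, not the estimand).
    """
    rf = model.receptive_field
    n_pos = signal.shape[-1] - rf + 1
    stride = max(1, n_pos // max_crops)
    crops = make_crops(signal, rf)[::stride].astype(np.float32)
    g = model.input_gradient(crops)
    amp = amplitude_gradients_from_time(g.astype(float),
                                        np.asarray(crops, float))
    per_crop = band_aggregate(amp, rf, sfreq, bands)
    return per_crop.mean(axis=0)


def group_saliency(models: list[TCNRegressor], records: list[dict],
                   sfreq: float, bands=DEFAULT_BANDS,
                   max_crops: int = 32) -> dict[str, np.ndarray]:
    """Saliency maps per pathology group plus their difference (NP - P).

    ``records`` carry ``signal`` (standardized), ``subject_id`` and
    ``pathology``. Aggregation: crops within recording, recordings within
    subject, subjects within group, then runs (models).
    """
    group_maps = {False: [], True: []}
    for model in models:
        per_subject: dict[tuple[str, bool], list[np.ndarray]] = {}
        for rec in records:
            m = recording_saliency(model, rec["signal"], sfreq, bands, max_crops)
            per_subject.setdefault(
                (rec["subject_id"], bool(rec["pathology"])), []).append(m)
        by_group: dict[bool, list[np.ndarray]] = {False: [], True: []}
        for (_, status), maps in per_subject.items():
            by_group[status].append(np.mean(maps, axis=0))
        for status, subj_maps in by_group.items():
            if subj_maps:
                group_maps[status].append(np.mean(subj_maps, axis=0))
    out = {}
    out["non_pathological"] = (np.mean(group_maps[False], axis=0)
                               if group_maps[False] else None)
    out["pathological"] = (np.mean(group_maps[True], axis=0)
                           if group_maps[True] else None)
    if out["non_pathological"] is not None and out["pathological"] is not None:
        out["difference"] = out["non_pathological"] - out["pathological"]
    else:
        out["difference"] = None
    return out
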