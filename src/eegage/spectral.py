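"""Spectral summaries and a transparent alpha-peak age estimator.

The alpha-peak estimator is a deliberately simple, fully inspectable
decoder: it measures the occipital alpha peak frequency with a Welch
spectrum and maps it to age by linear regression. It serves as a solvability
check for the synthetic decoding task and as an independent reference
against which the convolutional decoder can be compared.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import welch

__all__ = ["band_power", "alpha_peak_frequency", "AlphaPeakAgeModel"]


def band_power(signal: np.ndarray, sfreq: float, lo: float, hi: float,
               nperseg: int = 256) -> np.ndarray:
    """Mean Welch power per channel in [lo, hi) Hz."""
    freqs, psd = welch(signal, fs=sfreq, nperseg=min(nperseg, signal.shape[-1]))
    mask = (freqs >= lo) & (freqs < hi)
    return psd[..., mask].mean(axis=-1)


def alpha_peak_frequency(signal: np.ndarray, sfreq: float,
                         channel_idx=None, fmin: float = 6.0,
                         fmax: float = 13.0, nperseg: int = 512) -> float:
    """Peak frequency of the averaged spectrum in the extended alpha range.

    Quadratic interpolation around the maximum bin gives sub-bin resolution.
    """
    sig = signal if channel_idx is None else signal[list(channel_idx)]
    freqs, psd = welch(sig, fs=sfreq, nperseg=min(nperseg, sig.shape[-1]))
    mean_psd = psd.mean(axis=0) if psd.ndim > 1 else psd
    mask = (freqs >= fmin) & (freqs <= fmax)
    f_band, p_band = freqs[mask], mean_psd[mask]
    i = int(np.argmax(p_band))
    if 0 < i < len(p_band) - 1:
        y0, y1, y2 = p_band[i - 1], p_band[i], p_band[i + 1]
        denom = y0 - 2 * y1 + y2
        delta = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
        return float(f_band[i] + delta * (f_band[1] - f_band[0]))
    return float(f_band[i])


class AlphaPeakAgeModel:
    """Linear age-from-alpha-peak regressor (no neural network)."""

    def __init__(self):
        self.slope = None
        self.intercept = None

    def fit(self, signals: list[np.ndarray], ages, sfreq: float,
            channel_idx=None) -> "AlphaPeakAgeModel":
        peaks = np.array([alpha_peak_frequency(s, sfreq, channel_idx)
                          for s in signals])
        self.slope, self.intercept = np.polyfit(peaks, np.asarray(ages, float), 1)
        return self

    def predict(self, signals: list[np.ndarray], sfreq: float,
                channel_idx=None) -> np.ndarray:
        peaks = np.array([alpha_peak_frequency(s, sfreq, channel_idx)
                          for s in signals])
        return self.slope * peaks + self.intercept
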