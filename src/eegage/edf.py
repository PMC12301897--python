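"""EDF reading and writing for clinical EEG.

Reading goes through ``mne.io.read_raw_edf``; writing uses a minimal
EDF writer (16-bit samples, one-second data records, physical dimension uV)
sufficient for round-tripping synthetic cohorts to disk.

Channel labels are normalized to canonical 10-20 names, accepting the common
clinical dialects ``"EEG FP1-REF"``, ``"EEG FP1-LE"`` and bare names,
case-insensitively.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .errors import FormatError, MontageError
from .synthetic import FULL_1020_CHANNELS

__all__ = ["read_edf", "write_edf", "normalize_channel_label"]

_CANONICAL = {name.lower(): name for name in FULL_1020_CHANNELS}
# T3/T4/T5/T6 are also published as T7/T8/P7/P8 in the modified combinatorial
# nomenclature; map those back onto the classic names used here.
_CANONICAL.update({"t7": "T3", "t8": "T4", "p7": "T5", "p8": "T6"})


def normalize_channel_label(label: str, strict: bool = False) -> str:
    """Map an EDF channel label onto its canonical 10-20 name.

    Handles ``"EEG <name>-REF"`` / ``"-LE"`` prefixes/suffixes and any
    capitalization. Unknown labels are returned unchanged (``strict=False``)
    or raise :class:`MontageError` (``strict=True``).
    """
    name = label.strip()
    low = name.lower()
    if low.startswith("eeg "):
        low = low[4:]
    for suffix in ("-ref", "-le"):
        if low.endswith(suffix):
            low = low[: -len(suffix)]
    low = low.strip()
    if low in _CANONICAL:
        return _CANONICAL[low]
    if strict:
        raise MontageError(f"cannot map channel label {label!r} to a 10-20 name")
    return name


def write_edf(
    path: str | Path,
    signal: np.ndarray,
    sfreq: float,
    channel_names: list[str] | tuple[str, ...],
    physical_max: float = 800.0,
) -> None:
    """Write ``signal`` (channels x samples, microvolts) as 16-bit EDF.

    Samples are quantized onto ``[-physical_max, +physical_max]`` uV; the
    recording is split into one-second data records (the tail is zero-padded
    in the last record if the duration is not an integer number of seconds).
    """
    signal = np.asarray(signal, dtype=float)
    n_ch, n_samp = signal.shape
    if len(channel_names) != n_ch:
        raise ValueError("channel_names length must match signal rows")
    spr = int(round(sfreq))               # samples per record (1 s records)
    n_rec = int(np.ceil(n_samp / spr))
    padded = np.zeros((n_ch, n_rec * spr))
    padded[:, :n_samp] = signal

    pmax = float(physical_max)
    dmin, dmax = -32768, 32767
    scale = (dmax - dmin) / (2 * pmax)
    digital = np.clip(np.round((padded + pmax) * scale) + dmin, dmin, dmax).astype("<i2")

    def f(text: str, width: int) -> bytes:
        return text[:width].ljust(width).encode("ascii")

    header = b"".join([
        f("0", 8), f("X X X X", 80), f("Startdate X X X X", 80),
        f("01.01.00", 8), f("00.00.00", 8),
        f(str(256 * (n_ch + 1)), 8), f("", 44),
        f(str(n_rec), 8), f("1", 8), f(str(n_ch), 4),
    ])
    sig_headers = b"".join([
        b"".join(f(ch, 16) for ch in channel_names),
        b"".join(f("AgAgCl electrode", 80) for _ in range(n_ch)),
        b"".join(f("uV", 8) for _ in range(n_ch)),
        b"".join(f(f"{-pmax:g}", 8) for _ in range(n_ch)),
        b"".join(f(f"{pmax:g}", 8) for _ in range(n_ch)),
        b"".join(f(str(dmin), 8) for _ in range(n_ch)),
        b"".join(f(str(dmax), 8) for _ in range(n_ch)),
        b"".join(f("", 80) for _ in range(n_ch)),
        b"".join(f(str(spr), 8) for _ in range(n_ch)),
        b"".join(f("", 32) for _ in range(n_ch)),
    ])
    with open(path, "wb") as fh:
        fh.write(header + sig_headers)
        for r in range(n_rec):
            block = digital[:, r * spr:(r + 1) * spr]
            fh.write(block.tobytes())


def read_edf(path: str | Path, strict_labels: bool = False):
    """Read an EDF file; return ``(signal_uv, sfreq, channel_names)``.

    The signal is returned in microvolts with labels normalized to canonical
    10-20 names where recognizable.
    """
    import mne

    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # mne raises various concrete types
        raise FormatError(f"cannot read EDF file {path}: {exc}") from exc
    signal = raw.get_data() * 1e6   # volts -> microvolts
    names = tuple(normalize_channel_label(ch, strict=strict_labels)
                  for ch in raw.ch_names)
    return signal, float(raw.info["sfreq"]), names
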