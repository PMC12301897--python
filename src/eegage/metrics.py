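"""Regression/classification metrics, brain-age gap, and bias correction.

The brain-age gap is BA - CA (positive = overestimation). Because the
decoding error interacts with the target, the expected gap is modeled as a
quadratic function of chronological age, fit on cross-validation predictions
of non-pathological recordings, and subtracted from every gap before any
further analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateDataError

__all__ = [
    "ConfusionCounts", "BiasModel",
    "mae", "ape", "r2", "explained_variance_ratio", "bacc",
    "compute_gaps", "fit_bias", "apply_bias", "subject_average_gap",
]


@dataclass
class ConfusionCounts:
    """Binary confusion counts; positive class = pathological."""

    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")


def mae(targets, predictions) -> float:
    """Mean absolute error, in the units of the targets (years)."""
    t = np.asarray(targets, dtype=float)
    p = np.asarray(predictions, dtype=float)
    if t.shape != p.shape or t.size == 0:
        raise ValueError("targets and predictions must be equal-length, non-empty")
    return float(np.abs(p - t).mean())


def ape(target: float, prediction: float) -> float:
    """Absolute percentage error, in percent of the target."""
    if target == 0:
        raise ZeroDivisionError("APE undefined for target 0")
    return abs(prediction - target) / abs(target) * 100.0


def r2(targets, predictions) -> float:
    """Coefficient of determination, 1 - SS_res / SS_tot."""
    t = np.asarray(targets, dtype=float)
    p = np.asarray(predictions, dtype=float)
    if t.size < 2:
        raise ValueError("r2 needs at least 2 observations")
    ss_tot = ((t - t.mean()) ** 2).sum()
    if ss_tot == 0:
        raise DegenerateDataError("targets have zero variance")
    return float(1.0 - ((t - p) ** 2).sum() / ss_tot)


def explained_variance_ratio(targets, predictions) -> float:
    """Variance-ratio variant sum (p_i - t_bar)^2 / sum (t_i - t_bar)^2.

    Coincides with :func:`r2` for least-squares-calibrated predictors; kept
    as an optional alternative reporting convention.
    """
    t = np.asarray(targets, dtype=float)
    p = np.asarray(predictions, dtype=float)
    ss_tot = ((t - t.mean()) ** 2).sum()
    if ss_tot == 0:
        raise DegenerateDataError("targets have zero variance")
    return float(((p - t.mean()) ** 2).sum() / ss_tot)


def bacc(counts: ConfusionCounts) -> float:
    """Balanced accuracy: mean of sensitivity and specificity."""
    pos = counts.TP + counts.FN
    neg = counts.TN + counts.FP
    if pos == 0 or neg == 0:
        raise ValueError("BACC undefined: one class has no examples")
    return 0.5 * (counts.TP / pos + counts.TN / neg)


def compute_gaps(predictions: pd.DataFrame) -> pd.DataFrame:
    """Add ``gap_raw = brain_age_raw - chronological_age`` to a prediction table."""
    out = predictions.copy()
    out["gap_raw"] = out["brain_age_raw"] - out["chronological_age"]
    return out


@dataclass
class BiasModel:
    """Quadratic expected-gap model: gap ~ a*CA^2 + b*CA + c."""

    a: float
    b: float
    c: float
    age_lo: float
    age_hi: float
    source: str = "cv"

    def expected_gap(self, ca) -> np.ndarray:
        ca = np.asarray(ca, dtype=float)
        return self.a * ca ** 2 + self.b * ca + self.c


def fit_bias(ca, gap_raw, source: str = "cv") -> BiasModel:
    """Least-squares quadratic regression of the raw gap on chronological age."""
    ca = np.asarray(ca, dtype=float)
    gap = np.asarray(gap_raw, dtype=float)
    if np.unique(ca).size < 3:
        raise DegenerateDataError("bias fit needs >= 3 distinct age values")
    coeffs = np.polyfit(ca, gap, deg=2)
    return BiasModel(float(coeffs[0]), float(coeffs[1]), float(coeffs[2]),
                     float(ca.min()), float(ca.max()), source=source)


def apply_bias(model: BiasModel, records: pd.DataFrame) -> pd.DataFrame:
    """Subtract the expected gap: adds ``gap_corrected`` (and brain age)."""
    out = records.copy()
    out["gap_corrected"] = out["gap_raw"] - model.expected_gap(
        out["chronological_age"].to_numpy())
    out["brain_age"] = out["chronological_age"] + out["gap_corrected"]
    return out


def subject_average_gap(records: pd.DataFrame,
                        gap_col: str = "gap_corrected") -> pd.DataFrame:
    """Mean gap per (subject, pathology status) group.

    Accounts for subjects with multiple recordings: each subject contributes
    one value per pathology status.
    """
    if records.empty:
        raise ValueError("records must be non-empty")
    grp = (records.groupby(["subject_id", "pathology"])[gap_col]
           .mean().reset_index())
    return grp.rename(columns={gap_col: "mean_gap"})
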