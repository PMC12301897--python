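"""Gap-threshold pathology biomarker and longitudinal change-rate statistics.

The biomarker is a two-threshold rule on the corrected brain-age gap: gaps
inside [lo, hi] are called non-pathological, gaps outside pathological. The
thresholds are chosen to maximize balanced accuracy on the data they are fit
to (cross-validation), then frozen and applied to held-out data.

The longitudinal statistics quantify how fast the gap changes: per-subject
slopes within a constant pathology status, and the slope across the single
"moment of transition" for subjects whose label flips once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ClassError, PatternError

__all__ = [
    "ThresholdPair", "optimize_thresholds", "classify_gaps",
    "age_threshold_proxy", "change_rates", "transition_rate",
    "transition_rates_all",
]

DAYS_PER_YEAR = 365.25


@dataclass
class ThresholdPair:
    """Decision rule: gap in [lo, hi] -> non-pathological, else pathological."""

    lo: float
    hi: float

    def __post_init__(self):
        if not self.lo <= self.hi:
            raise ValueError("thresholds must satisfy lo <= hi")


def _candidates(values: np.ndarray) -> np.ndarray:
    """Midpoints between consecutive sorted unique values, plus +/-inf."""
    uniq = np.unique(values)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    return np.concatenate([[-np.inf], mids, [np.inf]])


def optimize_thresholds(gaps, labels) -> tuple[ThresholdPair, float]:
    """Exhaustively search threshold pairs maximizing balanced accuracy.

    Candidates are midpoints between consecutive sorted unique gaps plus
    +/-inf, which covers every achievable interval rule. Ties are broken by
    the widest non-pathological interval, then the smallest lower threshold.
    """
    gaps = np.asarray(gaps, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ClassError("threshold optimization needs both classes")
    cand = _candidates(gaps)
    # cumulative class counts below each candidate (candidates never equal data)
    pos_cum = np.searchsorted(np.sort(gaps[labels]), cand)
    neg_cum = np.searchsorted(np.sort(gaps[~labels]), cand)
    # pair (i, j), i <= j: inside counts are cum[j] - cum[i]
    fn = pos_cum[None, :] - pos_cum[:, None]      # pathological inside
    tn = neg_cum[None, :] - neg_cum[:, None]      # non-pathological inside
    tp = n_pos - fn
    b = 0.5 * (tp / n_pos + tn / n_neg)
    iu = np.triu_indices(len(cand))
    scores = b[iu]
    best = scores.max()
    at_best = np.flatnonzero(np.isclose(scores, best))
    lo_idx, hi_idx = iu[0][at_best], iu[1][at_best]
    widths = cand[hi_idx] - cand[lo_idx]
    widest = widths == widths.max()
    lo_pick = cand[lo_idx][widest]
    hi_pick = cand[hi_idx][widest]
    k = int(np.argmin(lo_pick))
    return ThresholdPair(float(lo_pick[k]), float(hi_pick[k])), float(best)


def classify_gaps(pair: ThresholdPair, gaps) -> np.ndarray:
    """Apply the rule; boundary values count as inside (non-pathological).

    Returns booleans, True = pathological.
    """
    gaps = np.asarray(gaps, dtype=float)
    return ~((gaps >= pair.lo) & (gaps <= pair.hi))


def bacc_of_rule(pair: ThresholdPair, gaps, labels) -> float:
    gaps = np.asarray(gaps, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pred = classify_gaps(pair, gaps)
    n_pos = labels.sum()
    n_neg = (~labels).sum()
    if n_pos == 0 or n_neg == 0:
        raise ClassError("balanced accuracy needs both classes")
    sens = (pred & labels).sum() / n_pos
    spec = (~pred & ~labels).sum() / n_neg
    return float(0.5 * (sens + spec))


def age_threshold_proxy(ages, labels) -> tuple[float, float]:
    """Single age cut maximizing BACC (older -> pathological): baseline proxy."""
    ages = np.asarray(ages, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ClassError("proxy needs both classes")
    cand = _candidates(ages)
    pos_cum = np.searchsorted(np.sort(ages[labels]), cand)
    neg_cum = np.searchsorted(np.sort(ages[~labels]), cand)
    # age > t -> pathological: TP = pos above t, TN = neg at/below t
    b = 0.5 * ((n_pos - pos_cum) / n_pos + neg_cum / n_neg)
    best = b.max()
    at_best = np.flatnonzero(np.isclose(b, best))
    return float(cand[at_best[0]]), float(best)


def _same_day_average(group: pd.DataFrame, gap_col: str) -> pd.DataFrame:
    out = (group.groupby("date_days", as_index=False)[gap_col].mean()
           .sort_values("date_days"))
    return out


def change_rates(records: pd.DataFrame,
                 gap_col: str = "gap_corrected") -> pd.DataFrame:
    """Per-subject gap change rate within constant pathology status.

    Same-day recordings are averaged; consecutive-date slopes (gap-years per
    elapsed year) are averaged per (subject, status) group. Groups with
    fewer than two distinct dates are skipped.
    """
    rows = []
    for (sid, status), grp in records.groupby(["subject_id", "pathology"]):
        daily = _same_day_average(grp, gap_col)
        if len(daily) < 2:
            continue
        d_gap = np.diff(daily[gap_col].to_numpy())
        d_t = np.diff(daily["date_days"].to_numpy()) / DAYS_PER_YEAR
        rows.append({"subject_id": sid, "pathology": bool(status),
                     "rate": float(np.mean(d_gap / d_t))})
    return pd.DataFrame(rows, columns=["subject_id", "pathology", "rate"])


def transition_rate(subject_records: pd.DataFrame,
                    gap_col: str = "gap_corrected") -> float:
    """Gap change rate across a subject's single pathology-label flip.

    Recordings are date-sorted; same-day recordings are averaged within each
    side of the flip. Exactly one flip is required; a flip pair sharing the
    same day (zero elapsed time) is a pattern error.
    """
    df = subject_records.sort_values(["date_days", "pathology"])
    labels = df["pathology"].astype(bool).to_numpy()
    flips = np.flatnonzero(labels[:-1] != labels[1:])
    if len(flips) != 1:
        raise PatternError(f"expected exactly one label flip, found {len(flips)}")
    cut = flips[0] + 1
    pre = _same_day_average(df.iloc[:cut], gap_col).iloc[-1]
    post = _same_day_average(df.iloc[cut:], gap_col).iloc[0]
    d_t = (post["date_days"] - pre["date_days"]) / DAYS_PER_YEAR
    if d_t <= 0:
        raise PatternError("flip pair shares a date: elapsed time is zero")
    return float((post[gap_col] - pre[gap_col]) / d_t)


def transition_rates_all(records: pd.DataFrame,
                         gap_col: str = "gap_corrected") -> pd.DataFrame:
    """Transition rates for every subject with exactly one label flip."""
    rows = []
    for sid, grp in records.groupby("subject_id"):
        try:
            rate = transition_rate(grp, gap_col)
        except PatternError:
            continue
        first_path = bool(grp.sort_values("date_days")["pathology"].iloc[0])
        rows.append({"subject_id": sid,
                     "direction": "TPNP" if first_path else "TNPP",
                     "rate": rate})
    return pd.DataFrame(rows, columns=["subject_id", "direction", "rate"])
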