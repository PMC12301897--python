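"""Longitudinal dataset derivatives and the inclusion/exclusion cascade.

Builds the four repeated-recording cohorts used in the state-vs-trait
analysis:

* RNP  — repeated, all recordings non-pathological
* RP   — repeated, all recordings pathological
* TNPP — one transition, non-pathological recordings strictly first
* TPNP — one transition, pathological recordings strictly first

Recording-level exclusions (too short, inconsistent age sources, excluded
sub-corpus) can cascade: a subject that drops below the minimum number of
recordings loses the remaining ones too, so the filter iterates to a fixed
point.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import ConfigError

__all__ = [
    "DerivativeRules", "check_age_consistency", "apply_inclusion",
    "assign_derivative", "assign_all", "keyword_subgroups", "DEFAULT_KEYWORDS",
]

DEFAULT_KEYWORDS = {
    "schizophrenia": "schizo",
    "depression": "depress",
    "stroke": "stroke",
}


@dataclass
class DerivativeRules:
    min_duration_s: float = 900.0          # 15-minute alignment rule
    min_recordings_per_subject: int = 2
    max_age_source_deviation: float = 1.0  # years

    def validate(self) -> None:
        if (self.min_duration_s <= 0 or self.min_recordings_per_subject <= 0
                or self.max_age_source_deviation <= 0):
            raise ConfigError("all derivative rules must be positive")


def check_age_consistency(age_header: float, age_report: float,
                          rules: DerivativeRules) -> bool:
    """Pass iff the two age sources agree to within the allowed deviation.

    The rule is strict: a deviation of exactly the threshold still passes,
    anything *more than* the threshold fails.
    """
    return abs(age_header - age_report) <= rules.max_age_source_deviation


def apply_inclusion(
    manifest: pd.DataFrame,
    rules: DerivativeRules,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Filter a manifest to a fixed point; return (kept, exclusion_log).

    Recording-level checks: minimum duration, age-source consistency, and an
    optional boolean ``excluded_corpus`` column. Subject-level check: at
    least ``min_recordings_per_subject`` surviving recordings. Dropping a
    recording can push a subject below the minimum, which drops the
    subject's remaining recordings (logged as a cascade), hence iteration.
    """
    rules.validate()
    df = manifest.copy()
    log_rows = []

    too_short = df["duration_s"] < rules.min_duration_s
    age_bad = (df["age_header"] - df["age_report"]).abs() > rules.max_age_source_deviation
    corpus_bad = (df["excluded_corpus"].astype(bool)
                  if "excluded_corpus" in df.columns
                  else pd.Series(False, index=df.index))
    for idx in df.index[too_short]:
        log_rows.append((df.at[idx, "recording_id"], df.at[idx, "subject_id"],
                         "duration below minimum"))
    for idx in df.index[age_bad & ~too_short]:
        log_rows.append((df.at[idx, "recording_id"], df.at[idx, "subject_id"],
                         "age sources deviate by more than allowed"))
    for idx in df.index[corpus_bad & ~too_short & ~age_bad]:
        log_rows.append((df.at[idx, "recording_id"], df.at[idx, "subject_id"],
                         "recording from excluded sub-corpus"))
    df = df[~(too_short | age_bad | corpus_bad)]

    while True:
        counts = df.groupby("subject_id")["recording_id"].transform("size")
        dropped = counts < rules.min_recordings_per_subject
        if not dropped.any():
            break
        for idx in df.index[dropped]:
            log_rows.append((df.at[idx, "recording_id"], df.at[idx, "subject_id"],
                             "subject below minimum recording count (cascade)"))
        df = df[~dropped]

    log = pd.DataFrame(log_rows, columns=["recording_id", "subject_id", "reason"])
    return df.reset_index(drop=True), log


def assign_derivative(labels: list[bool] | tuple[bool, ...]) -> str:
    """Categorize one subject's date-sorted pathology labels.

    Returns one of ``RNP``, ``RP``, ``TNPP``, ``TPNP`` or ``excluded``
    (more than one label flip matches no definition).
    """
    if len(labels) < 2:
        raise ValueError("derivative assignment needs >= 2 recordings")
    labels = [bool(x) for x in labels]
    flips = sum(a != b for a, b in zip(labels, labels[1:]))
    if flips == 0:
        return "RP" if labels[0] else "RNP"
    if flips == 1:
        return "TNPP" if not labels[0] else "TPNP"
    return "excluded"


def assign_all(manifest: pd.DataFrame) -> pd.DataFrame:
    """Per-subject derivative assignment for a (filtered) manifest.

    Same-day ties are ordered non-pathological first (conservative) and the
    subject is flagged in the ``tie_flag`` column for auditing.
    """
    rows = []
    for sid, grp in manifest.groupby("subject_id"):
        grp = grp.sort_values(["date_days", "pathology"])
        tie = grp.duplicated("date_days", keep=False).any()
        rows.append({
            "subject_id": sid,
            "category": assign_derivative(list(grp["pathology"])),
            "tie_flag": bool(tie),
        })
    return pd.DataFrame(rows)


def keyword_subgroups(
    manifest: pd.DataFrame,
    keywords: dict[str, str] = DEFAULT_KEYWORDS,
) -> dict[str, set[str]]:
    """Subjects whose reports mention each condition keyword.

    Case-insensitive substring search over all of a subject's reports; a
    subject may belong to several conditions.
    """
    out: dict[str, set[str]] = {name: set() for name in keywords}
    reports = manifest["report"].fillna("").astype(str).str.lower()
    for name, kw in keywords.items():
        hit = reports.str.contains(kw.lower(), regex=False)
        out[name] = set(manifest.loc[hit, "subject_id"])
    return out
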