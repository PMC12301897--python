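"""Statistical testing battery for the brain-age-gap analyses.

Permutation tests (the constructed nulls) are implemented here; classical
tests (paired t, Kolmogorov-Smirnov, Wilcoxon-Mann-Whitney, Brunner-Munzel)
are delegated to scipy. Permutation p-values use the +1 smoothing
convention, so the smallest attainable p with n permutations is 1/(n+1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .biomarker import ThresholdPair, bacc_of_rule, classify_gaps
from .errors import ClassError, ConfigError, DegenerateDataError

__all__ = [
    "PermutationResult", "perm_test_mean_diff", "perm_test_bacc",
    "paired_t", "ks_test", "wmw_test", "brunner_munzel",
]

_CHUNK = 2000


@dataclass
class PermutationResult:
    observed_stat: float
    n_permutations: int
    p_value: float
    null_quantiles: tuple[float, float, float]   # 2.5%, 50%, 97.5%
    seed: int
    sided: str


def _perm_indices(rng: np.random.Generator, n_perm: int, n_pool: int,
                  n_a: int):
    """Yield chunks of row-wise random subsets of size n_a out of n_pool."""
    done = 0
    while done < n_perm:
        m = min(_CHUNK, n_perm - done)
        keys = rng.random((m, n_pool))
        idx = np.argpartition(keys, n_a - 1, axis=1)[:, :n_a]
        yield idx
        done += m


def perm_test_mean_diff(group_a, group_b, n_permutations: int = 100_000,
                        seed: int = 0) -> PermutationResult:
    """Two-sided permutation test for a difference in group means.

    Statistic: mean(A) - mean(B). The null shuffles pooled group membership
    preserving group sizes.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ClassError("both groups must be non-empty")
    if n_permutations < 1:
        raise ConfigError("n_permutations must be >= 1")
    observed = a.mean() - b.mean()
    pool = np.concatenate([a, b])
    total = pool.sum()
    n_a, n_b = a.size, b.size
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    pos = 0
    for idx in _perm_indices(rng, n_permutations, pool.size, n_a):
        sum_a = pool[idx].sum(axis=1)
        null[pos:pos + len(idx)] = sum_a / n_a - (total - sum_a) / n_b
        pos += len(idx)
    p = (1 + np.sum(np.abs(null) >= abs(observed))) / (n_permutations + 1)
    q = np.percentile(null, [2.5, 50, 97.5])
    return PermutationResult(float(observed), n_permutations, float(p),
                             tuple(map(float, q)), seed, "two-sided")


def perm_test_bacc(gaps, labels, pair: ThresholdPair,
                   n_permutations: int = 100_000,
                   seed: int = 0) -> PermutationResult:
    """One-sided (greater) permutation test of biomarker balanced accuracy.

    The threshold pair stays fixed; the null permutes the pathology labels
    and recomputes the balanced accuracy of the same decision rule.
    """
    gaps = np.asarray(gaps, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ClassError("both classes must be present")
    if n_permutations < 1:
        raise ConfigError("n_permutations must be >= 1")
    observed = bacc_of_rule(pair, gaps, labels)
    pred_path = classify_gaps(pair, gaps)          # fixed rule output
    n = gaps.size
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    pos = 0
    for idx in _perm_indices(rng, n_permutations, n, n_pos):
        # idx: which observations are labeled pathological in this permutation
        tp = pred_path[idx].sum(axis=1)
        fp = pred_path.sum() - tp
        tn = n_neg - fp
        null[pos:pos + len(idx)] = 0.5 * (tp / n_pos + tn / n_neg)
        pos += len(idx)
    p = (1 + np.sum(null >= observed)) / (n_permutations + 1)
    q = np.percentile(null, [2.5, 50, 97.5])
    return PermutationResult(float(observed), n_permutations, float(p),
                             tuple(map(float, q)), seed, "greater")


def paired_t(x, y) -> tuple[float, float]:
    """Two-sided paired t-test on the differences x - y."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("paired t-test needs equal-length samples of size >= 2")
    d = x - y
    if np.allclose(d.std(ddof=1), 0):
        raise DegenerateDataError("zero variance of paired differences")
    res = sps.ttest_rel(x, y)
    return float(res.statistic), float(res.pvalue)


def _check_two_groups(a, b, min_size: int = 2):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < min_size or b.size < min_size:
        raise ValueError(f"both groups need >= {min_size} observations")
    return a, b


def ks_test(a, b) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test (distribution equality)."""
    a, b = _check_two_groups(a, b)
    res = sps.ks_2samp(a, b)
    return float(res.statistic), float(res.pvalue)


def wmw_test(a, b) -> tuple[float, float]:
    """Two-sided Wilcoxon-Mann-Whitney test (stochastic dominance)."""
    a, b = _check_two_groups(a, b)
    res = sps.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def brunner_munzel(a, b) -> tuple[float, float]:
    """Two-sided Brunner-Munzel test; warns for small groups (< 10)."""
    a, b = _check_two_groups(a, b)
    if min(a.size, b.size) < 10:
        warnings.warn("Brunner-Munzel is recommended for group sizes >= 10",
                      stacklevel=2)
    res = sps.brunnermunzel(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
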