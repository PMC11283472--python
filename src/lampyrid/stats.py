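"""Shared statistical helpers used across the analysis modules."""

from __future__ import annotations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = ["rank_sum_test", "bonferroni", "bh_adjust", "star_label"]


def rank_sum_test(x, y, exact_max: int = 20) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) p-value.

    Uses the exact null distribution when both groups have at most
    ``exact_max`` observations and there are no ties; otherwise the
    normal approximation with continuity correction and midrank tie
    handling. Degenerate input where every value is identical returns
    p = 1 (the statistic carries no information).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("rank_sum_test requires non-empty groups")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (not has_ties and max(x.size, y.size) <= exact_max) else "asymptotic"
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(min(res.pvalue, 1.0))


def bonferroni(p, m: int) -> np.ndarray:
    """Bonferroni family-wise adjustment: min(1, p * m)."""
    return np.minimum(1.0, np.asarray(p, dtype=float) * m)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def star_label(
    p: float,
    thresholds: tuple[float, ...] = (1e-4, 1e-3, 1e-2),
    labels: tuple[str, ...] = ("***", "**", "*"),
    ns: str = "",
) -> str:
    """Map a p-value to a significance star label (strict inequality)."""
    for t, lab in zip(thresholds, labels):
        if p < t:
            return lab
    return ns
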