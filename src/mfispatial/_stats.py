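"""Shared statistical helpers: rank-sum tests, BH adjustment, AUROC."""

from __future__ import annotations

import numpy as np
from scipy import stats


def rank_sum_p(x, y, alternative: str = "two-sided") -> float:
    """Two-sample Wilcoxon rank-sum (Mann-Whitney U) p-value.

    Uses the exact null distribution when both samples have at most 10
    observations and the pooled data carry no ties; otherwise the normal
    approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("rank-sum test requires two nonempty samples")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (x.size <= 10 and y.size <= 10 and no_ties) else "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative=alternative, method=method).pvalue)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return stats.false_discovery_control(p, method="bh")


def auroc(values, labels) -> float:
    """Area under the ROC curve for a scalar marker.

    Rank-based (Mann-Whitney) estimator with midrank handling of ties:
    AUROC = (R1 - n1*(n1+1)/2) / (n1*n0), where R1 is the rank sum of the
    positive class.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUROC needs both classes present")
    ranks = stats.rankdata(values)
    r1 = ranks[labels].sum()
    return float((r1 - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def spearman(x, y):
    """Spearman rho and two-sided p-value."""
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)
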