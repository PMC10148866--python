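"""Small shared statistical helpers."""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

__all__ = ["rank_sum_p"]

#: largest group size for which the exact rank-sum null is enumerated
EXACT_LIMIT = 25


def rank_sum_p(x, y, alternative: str) -> tuple[float, float]:
    """One- or two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    Uses the exact null distribution when both groups have at most
    ``EXACT_LIMIT`` observations and no ties are present, otherwise the
    tie-corrected normal approximation with continuity correction.

    Returns ``(U statistic of x, p-value)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    if no_ties and max(x.size, y.size) <= EXACT_LIMIT:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)
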