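"""Shared hypothesis-testing helpers.

Thin wrappers around scipy/statsmodels that fix the conventions used
throughout the pipeline: the Wilcoxon rank-sum test switches from exact
enumeration to the tie-corrected normal approximation at a recorded sample
size, and Holm's step-down controls the family-wise error rate.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

#: below this per-group size (and without ties) the exact null is enumerated
EXACT_LIMIT = 10


def rank_sum_test(
    x: np.ndarray, y: np.ndarray, alternative: str = "two-sided"
) -> tuple[float, float, bool]:
    """Wilcoxon rank-sum (Mann-Whitney U) test of x vs y.

    Returns (U statistic of x, p-value, exact_flag).  The exact distribution
    is enumerated when both samples are smaller than ``EXACT_LIMIT`` and
    carry no cross-sample ties; otherwise the tie-corrected normal
    approximation (no continuity correction) is used.  Degenerate input with
    zero rank variance yields p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("rank-sum test requires two non-empty samples")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    exact = not has_ties and min(x.size, y.size) < EXACT_LIMIT
    if np.ptp(pooled) == 0:
        return float(x.size * y.size / 2), 1.0, False
    res = stats.mannwhitneyu(
        x,
        y,
        alternative=alternative,
        method="exact" if exact else "asymptotic",
        use_continuity=False,
    )
    return float(res.statistic), float(res.pvalue), exact


def holm_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, capped at 1)."""
    pvalues = np.asarray(pvalues, dtype=float)
    if pvalues.size == 0:
        return pvalues.copy()
    return multipletests(pvalues, method="holm")[1]
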