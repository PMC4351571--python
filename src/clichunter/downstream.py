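"""Downstream characterization of CLIC loci: mutual exclusion, gene-set
enrichment, TFBS carriers and insertion-expression association.

Mutual exclusion between two loci is scored by the mean-Manhattan distance
of their binary sample-occupancy vectors — the fraction of samples in which
exactly one of the two loci carries an insertion; mutually exclusive pairs
score high.  Expression effects are quantified per gene by Welch
t-statistics T_A (samples split by insertions in the gene's own locus A)
and T_AB (split by insertions in locus A or its CLIC partner B); a positive
sign(T_A) * (T_AB - T_A) means distal insertions amplify the local effect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import rank_sum_test
from .clusters import InsertionCluster, InsertionDataset
from .simulate import ExpressionMatrix


@dataclass(frozen=True)
class EnrichmentResult:
    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p_value: float
    label_a: str
    label_b: str
    degenerate: bool


@dataclass(frozen=True)
class ExclusionComparison:
    statistic: float
    p_value: float
    median_clic: float
    median_control: float


def sample_locus_matrix(
    data: InsertionDataset, loci: list[InsertionCluster], bin_size: int
) -> pd.DataFrame:
    """Binary samples x loci matrix: 1 iff the sample has at least one
    insertion within the locus extent (half-open bp interval)."""
    mat = np.zeros((data.n_samples, len(loci)), dtype=int)
    sample_index = {s: i for i, s in enumerate(data.samples)}
    rec = data.records
    for li, locus in enumerate(loci):
        lo, hi = locus.span_bp(bin_size)
        sel = (rec["chrom"] == locus.chrom) & (rec["pos"] >= lo) & (rec["pos"] < hi)
        for s in rec.loc[sel, "sample"]:
            mat[sample_index[s], li] = 1
    return pd.DataFrame(mat, index=list(data.samples), columns=range(len(loci)))


def mean_manhattan(m: pd.DataFrame, locus_a, locus_b) -> float:
    """Fraction of samples whose two locus indicators disagree (exactly one
    of the two loci inserted); symmetric and bounded in [0, 1]."""
    if len(m) == 0:
        raise ValueError("mean-Manhattan distance undefined for zero samples")
    a = m[locus_a].to_numpy()
    b = m[locus_b].to_numpy()
    return float(np.mean(a != b))


def mutual_exclusion_comparison(
    m: pd.DataFrame,
    clic_pairs: list[tuple],
    control_pairs: list[tuple],
) -> ExclusionComparison:
    """Two-sided rank-sum comparison of mean-Manhattan distances: CLIC locus
    pairs vs control pairs (non-significant high-IC combinations)."""
    if not clic_pairs or not control_pairs:
        raise ValueError("both pair lists must be non-empty")
    d_clic = np.array([mean_manhattan(m, a, b) for a, b in clic_pairs])
    d_ctrl = np.array([mean_manhattan(m, a, b) for a, b in control_pairs])
    stat, p, _ = rank_sum_test(d_clic, d_ctrl, alternative="two-sided")
    return ExclusionComparison(
        stat, p, float(np.median(d_clic)), float(np.median(d_ctrl))
    )


def enrichment_test(
    members_a: set, members_b: set, universe: set,
    label_a: str = "A", label_b: str = "B",
) -> EnrichmentResult:
    """Fisher's exact test (two-sided) on the 2x2 cross-classification of
    two memberships within a universe; used uniformly for CIS-gene,
    cancer-gene and TFBS-carrier overlaps."""
    if not universe:
        raise ValueError("enrichment universe must be non-empty")
    if not members_a <= universe or not members_b <= universe:
        raise ValueError("membership sets must be subsets of the universe")
    both = len(members_a & members_b)
    a_only = len(members_a - members_b)
    b_only = len(members_b - members_a)
    neither = len(universe) - both - a_only - b_only
    table = np.array([[both, a_only], [b_only, neither]])
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    degenerate = bool(np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0))
    return EnrichmentResult(
        ((both, a_only), (b_only, neither)), float(odds), float(p),
        label_a, label_b, degenerate,
    )


def tfbs_carrier(
    ics: list[InsertionCluster],
    peaks: list[tuple[str, int, int]],
    bin_size: int,
) -> list[bool]:
    """Flag each IC as a TFBS carrier if its length-normalized peak count —
    peaks whose midpoint falls inside the IC extent, divided by the extent
    length in bp — strictly exceeds the median density over all ICs."""
    if not ics:
        raise ValueError("tfbs_carrier needs at least one IC")
    densities = []
    for ic in ics:
        lo, hi = ic.span_bp(bin_size)
        count = sum(
            1
            for chrom, p0, p1 in peaks
            if chrom == ic.chrom and lo <= (p0 + p1) // 2 < hi
        )
        densities.append(count / (hi - lo))
    med = float(np.median(densities))
    return [d > med for d in densities]


def expression_t_scores(
    expr: ExpressionMatrix,
    gene: str,
    m: pd.DataFrame,
    locus_a,
    locus_b,
) -> tuple[float, float]:
    """Welch two-sample t-statistics quantifying the expression effect of
    insertions on ``gene`` (residing in locus A).

    T_A splits samples by insertions in locus A alone; T_AB by insertions in
    locus A or its CLIC partner locus B.  Positive values mean the inserted
    group expresses higher.  When locus B is never inserted the two
    groupings coincide and T_AB == T_A exactly.
    """
    y = expr.values.loc[gene, m.index].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ValueError(f"expression of {gene} is constant: t-score undefined")
    out = []
    for grouping in (m[locus_a].to_numpy(), (m[locus_a] | m[locus_b]).to_numpy()):
        g1, g0 = y[grouping == 1], y[grouping == 0]
        if g1.size < 2 or g0.size < 2:
            raise ValueError("each insertion group needs at least 2 samples")
        t, _ = stats.ttest_ind(g1, g0, equal_var=False)
        out.append(float(t))
    return out[0], out[1]


def spatial_association_delta(t_a: float, t_ab: float) -> tuple[float, bool]:
    """sign(T_A) * (T_AB - T_A): positive when distal insertions amplify the
    local expression effect.  Returns (delta, zero_sign_flag); when T_A is
    exactly 0 the delta is defined as |T_AB| and flagged."""
    if t_a == 0:
        return abs(t_ab), True
    return float(np.sign(t_a) * (t_ab - t_a)), False
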