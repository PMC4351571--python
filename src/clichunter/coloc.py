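"""Spatial co-localization statistics.

Three complementary analyses on the rank-normalized intra-chromosomal
contact maps:

* category-pair comparisons — the normalized contact scores between bins of
  the NI/I/RI categories, compared across the 15 unordered pairs of the 6
  bin-pair categories with a rank-sum test;
* nearest-spatial-neighbour scores — for every inserted bin, the insertion
  count of the bin with which it has maximal normalized contact;
* CLIC detection — for every intra-chromosomal pair of high-scoring ICs,
  the n x m normalized scores bridging the two clusters (positive
  distribution) are compared one-tailed against all scores at a matching
  genomic-distance range (negative distribution, widened until it holds at
  least L values); Holm's step-down controls the FWER over all tested
  pairs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np

from ._stats import holm_adjust, rank_sum_test
from .clusters import NI, I, RI, BinnedInsertionProfile, InsertionCluster
from .hic import NormalizedContactMap

CATEGORIES = (NI, I, RI)


@dataclass(frozen=True)
class CategoryPairTest:
    pair_a: tuple[str, str]
    pair_b: tuple[str, str]
    statistic: float
    p_value: float
    effect_size: float  # median(A) - median(B)


@dataclass(frozen=True)
class CLIC:
    """A pair of insertion clusters with co-localization evidence."""

    ic_a: InsertionCluster
    ic_b: InsertionCluster
    chrom: str
    n_pos: int
    d_min: int
    d_max: int
    p_raw: float
    exact: bool
    p_holm: float | None = None
    significant: bool | None = None


def enumerate_category_pairs() -> tuple[
    list[tuple[str, str]], list[tuple[tuple[str, str], tuple[str, str]]]
]:
    """The 6 unordered bin-pair categories over {NI, I, RI} and their 15
    unordered pairwise comparisons."""
    pairs = list(itertools.combinations_with_replacement(CATEGORIES, 2))
    comparisons = list(itertools.combinations(pairs, 2))
    return pairs, comparisons


def category_pair_scores(
    norm: NormalizedContactMap,
    profile: BinnedInsertionProfile,
    pair: tuple[str, str],
    bin_subset: np.ndarray | None = None,
) -> np.ndarray:
    """All normalized scores h_hat_ij (i < j) whose bin categories match the
    unordered ``pair``, optionally with both bins restricted to
    ``bin_subset`` (e.g. TSS-containing bins or one compartment)."""
    if profile.categories is None:
        raise ValueError("profile must be categorized first")
    if norm.n_bins != profile.n_bins:
        raise ValueError("normalized map and insertion profile binning differ")
    cats = profile.categories
    allowed = np.ones(norm.n_bins, dtype=bool)
    if bin_subset is not None:
        allowed[:] = False
        allowed[np.asarray(bin_subset, dtype=int)] = True
    a, b = pair
    idx_a = np.flatnonzero((cats == a) & allowed)
    idx_b = np.flatnonzero((cats == b) & allowed)
    if a == b:
        ii, jj = np.triu_indices(idx_a.size, k=1)
        rows, cols = idx_a[ii], idx_a[jj]
    else:
        rows = np.repeat(idx_a, idx_b.size)
        cols = np.tile(idx_b, idx_a.size)
        keep = rows != cols
        rows, cols = rows[keep], cols[keep]
    scores = norm.ranks[rows, cols]
    scores = scores[~np.isnan(scores)]
    if scores.size == 0:
        raise ValueError(f"no bin pairs with categories {pair}")
    return scores


def compare_category_pairs(
    scores_a: np.ndarray, scores_b: np.ndarray,
    pair_a: tuple[str, str] = ("", ""), pair_b: tuple[str, str] = ("", ""),
) -> CategoryPairTest:
    """Two-sided rank-sum comparison of two category-pair score vectors."""
    if len(scores_a) == 0 or len(scores_b) == 0:
        raise ValueError("both score vectors must be non-empty")
    stat, p, _ = rank_sum_test(scores_a, scores_b, alternative="two-sided")
    effect = float(np.median(scores_a) - np.median(scores_b))
    return CategoryPairTest(pair_a, pair_b, stat, p, effect)


def nearest_spatial_neighbor_scores(
    norm: NormalizedContactMap,
    profile: BinnedInsertionProfile,
    exclude_adjacent: int = 1,
) -> list[dict]:
    """For each inserted bin, the insertion count of its nearest spatial
    neighbour — the bin with maximal normalized contact, excluding the bin
    itself and bins within ``exclude_adjacent`` of it.  Ties resolve to the
    smaller index and are flagged."""
    if norm.n_bins != profile.n_bins:
        raise ValueError("normalized map and insertion profile binning differ")
    n = norm.n_bins
    out = []
    for i in np.flatnonzero(profile.counts > 0):
        row = norm.ranks[i].copy()
        lo = max(0, i - exclude_adjacent)
        hi = min(n, i + exclude_adjacent + 1)
        row[lo:hi] = np.nan
        if np.all(np.isnan(row)):
            continue
        best = float(np.nanmax(row))
        candidates = np.flatnonzero(row == best)
        out.append(
            {
                "bin": int(i),
                "neighbor_bin": int(candidates[0]),
                "neighbor_count": int(profile.counts[candidates[0]]),
                "tie": len(candidates) > 1,
            }
        )
    return out


def _positive_mask_for_distance(
    n: int, d: int, bins_a: np.ndarray, bins_b: np.ndarray
) -> np.ndarray:
    """Boolean mask over the d-th superdiagonal marking entries that belong
    to the positive (A x B) set."""
    i = np.arange(n - d)
    in_a = np.zeros(n, dtype=bool)
    in_a[bins_a] = True
    in_b = np.zeros(n, dtype=bool)
    in_b[bins_b] = True
    return (in_a[i] & in_b[i + d]) | (in_b[i] & in_a[i + d])


def clic_test(
    norm: NormalizedContactMap,
    ic_a: InsertionCluster,
    ic_b: InsertionCluster,
    L: int,
) -> CLIC:
    """One-tailed rank-sum test of the n x m normalized scores between two
    disjoint ICs (positive distribution) against the distance-matched
    background (negative distribution).

    The negative distribution pools all superdiagonal scores at bin
    distances in [d_min, d_max] (the distance range spanned by the positive
    pairs), excluding the positive entries themselves, and is widened one
    distance at a time — alternately below d_min and above d_max — until it
    holds at least ``L`` values.
    """
    if ic_a.chrom != ic_b.chrom:
        raise ValueError("CLIC test requires ICs on the same chromosome")
    if ic_a.start_bin < ic_b.end_bin and ic_b.start_bin < ic_a.end_bin:
        raise ValueError("CLIC test requires disjoint IC extents")
    n = norm.n_bins
    if ic_a.end_bin > n or ic_b.end_bin > n:
        raise ValueError("IC extent outside the contact map")
    bins_a = np.arange(ic_a.start_bin, ic_a.end_bin)
    bins_b = np.arange(ic_b.start_bin, ic_b.end_bin)
    positive = norm.ranks[np.ix_(bins_a, bins_b)].ravel()
    dists = np.abs(np.subtract.outer(bins_a, bins_b)).ravel()
    d_min, d_max = int(dists.min()), int(dists.max())
    lo, hi = d_min, d_max
    take_lo = True

    def negative_values(lo: int, hi: int) -> np.ndarray:
        chunks = []
        for d in range(lo, hi + 1):
            diag = np.diagonal(norm.ranks, d)
            mask = _positive_mask_for_distance(n, d, bins_a, bins_b)
            chunks.append(diag[~mask])
        return np.concatenate(chunks) if chunks else np.array([])

    while True:
        neg = negative_values(lo, hi)
        if neg.size >= L:
            break
        if lo <= 1 and hi >= n - 1:
            raise ValueError(
                "chromosome too short to build a distance-matched null of size L"
            )
        use_lo = (take_lo and lo > 1) or hi >= n - 1
        if use_lo:
            lo -= 1
        else:
            hi += 1
        take_lo = not take_lo
    _, p, exact = rank_sum_test(positive, neg, alternative="greater")
    return CLIC(
        ic_a, ic_b, ic_a.chrom, int(positive.size), d_min, d_max, p, exact
    )


def detect_clics(
    norm_maps: dict[str, NormalizedContactMap],
    high_ics: list[InsertionCluster],
    alpha: float = 1e-5,
    L: int | str = "auto",
) -> list[CLIC]:
    """Test every intra-chromosomal unordered pair of high-scoring ICs with
    disjoint extents, then Holm-adjust over the whole family of tests at
    family-wise level ``alpha``.

    ``L="auto"`` sets the minimum null size to twice the bin count of the
    largest supplied map.
    """
    if L == "auto":
        L_val = 2 * max(m.n_bins for m in norm_maps.values())
    else:
        L_val = int(L)
    results: list[CLIC] = []
    by_chrom: dict[str, list[InsertionCluster]] = {}
    for ic in high_ics:
        by_chrom.setdefault(ic.chrom, []).append(ic)
    for chrom, ics in sorted(by_chrom.items()):
        if chrom not in norm_maps:
            raise ValueError(f"no normalized map supplied for chromosome {chrom}")
        ics = sorted(ics, key=lambda c: (c.start_bin, c.end_bin))
        for a, b in itertools.combinations(ics, 2):
            if a.start_bin < b.end_bin and b.start_bin < a.end_bin:
                continue  # overlapping extents cannot be tested
            results.append(clic_test(norm_maps[chrom], a, b, L_val))
    if not results:
        return []
    adjusted = holm_adjust(np.array([c.p_raw for c in results]))
    return [
        replace(c, p_holm=float(p), significant=bool(p <= alpha))
        for c, p in zip(results, adjusted)
    ]
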