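"""Intra-chromosomal Hi-C contact maps: coarsening, rank-based distance
normalization and chromatin-compartment eigenvector analysis.

Contact frequency between two loci decays steeply (roughly as a power law)
with their genomic distance, and the score distributions at different
distances are neither Gaussian nor homoscedastic.  Rather than modelling an
expected-by-distance curve, every score is replaced by its relative rank
among scores at a similar genomic distance: for each superdiagonal ``k`` of
the symmetric contact matrix a pool of scores is assembled from that
superdiagonal plus, when it is too short, whole neighbouring superdiagonals,
and each entry becomes its average-tie rank divided by the pool size.  The
result lies in ``(0, 1]``, is invariant under any strictly monotone
transform of the raw scores, and is flat in distance by construction.

Open/closed chromatin compartments are recovered as the sign of the first
principal component of the bin-by-bin correlation matrix of the normalized
contacts (the classical plaid-pattern analysis).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


class DegenerateInputError(ValueError):
    """Raised when an input has no usable variation (e.g. a constant map)."""


@dataclass
class ContactMap:
    """Symmetric non-negative contact scores ``h_ij`` for one chromosome."""

    chrom: str
    bin_size: int
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[0] != self.scores.shape[1]:
            raise ValueError("contact map must be a square matrix")
        if self.scores.shape[0] < 2:
            raise ValueError("contact map needs at least 2 bins")
        if not np.allclose(self.scores, self.scores.T, rtol=0.0, atol=1e-8):
            raise ValueError("contact map must be symmetric")
        if np.any(self.scores < 0):
            raise ValueError("contact scores must be non-negative")
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")

    @property
    def n_bins(self) -> int:
        return self.scores.shape[0]


@dataclass
class NormalizedContactMap:
    """Rank-normalized contacts ``h_hat_ij`` in ``(0, 1]``.

    ``pool_length`` is the minimum superdiagonal pool size ``L`` used during
    normalization; the diagonal carries a NaN sentinel and is excluded from
    every downstream test.
    """

    chrom: str
    bin_size: int
    ranks: np.ndarray
    pool_length: int

    @property
    def n_bins(self) -> int:
        return self.ranks.shape[0]


@dataclass
class CompartmentTrack:
    """Per-bin first principal component of the contact correlation matrix.

    Orientation is fixed so that positive values mark bins with higher total
    contact, a proxy for the open (A) compartment; bins masked out of the
    computation carry NaN.  The non-NaN entries have unit Euclidean norm.
    """

    chrom: str
    bin_size: int
    pc1: np.ndarray
    open_is_positive: bool = True


def coarsen_contact_map(cmap: ContactMap, factor: int) -> ContactMap:
    """Sum ``factor`` x ``factor`` blocks into one bin (e.g. 40 kb -> 200 kb).

    A trailing partial block is summed as-is, so the total contact sum is
    conserved exactly.
    """
    if factor < 1:
        raise ValueError("coarsening factor must be >= 1")
    if factor == 1:
        return ContactMap(cmap.chrom, cmap.bin_size, cmap.scores.copy())
    n = cmap.n_bins
    idx = np.arange(0, n, factor)
    out = np.add.reduceat(np.add.reduceat(cmap.scores, idx, axis=0), idx, axis=1)
    out = (out + out.T) / 2  # remove float summation-order asymmetry
    return ContactMap(cmap.chrom, cmap.bin_size * factor, out)


def _pool_offsets(n: int, k: int, L: int) -> list[int]:
    """Superdiagonal offsets pooled for distance ``k``: the k-th first, then
    whole neighbours in the order k-1, k+1, k-2, k+2, ... until the pooled
    length reaches ``L`` or the matrix is exhausted."""
    offsets = [k]
    total = n - k
    lo, hi = k - 1, k + 1
    take_lo = True
    while total < L and (lo >= 1 or hi <= n - 1):
        use_lo = (take_lo and lo >= 1) or hi > n - 1
        if use_lo:
            offsets.append(lo)
            total += n - lo
            lo -= 1
        else:
            offsets.append(hi)
            total += n - hi
            hi += 1
        take_lo = not take_lo
    return offsets


def build_superdiagonal_pool(cmap: ContactMap, k: int, L: int) -> np.ndarray:
    """Scores at genomic distance ``k`` bins, extended with whole
    neighbouring superdiagonals until the pool holds at least ``L`` values.

    The k-th superdiagonal itself always occupies the head of the returned
    vector, in matrix order.
    """
    n = cmap.n_bins
    if not 1 <= k <= n - 1:
        raise ValueError(f"superdiagonal index k={k} outside [1, {n - 1}]")
    if L < 1:
        raise ValueError("pool length L must be >= 1")
    offsets = _pool_offsets(n, k, L)
    return np.concatenate([np.diagonal(cmap.scores, off) for off in offsets])


def rank_normalize(cmap: ContactMap, L: int | str = "auto") -> NormalizedContactMap:
    """Replace each contact score by its average-tie rank within its
    distance-matched pool, scaled by the pool size into ``(0, 1]``.

    ``L="auto"`` sets the minimum pool length to twice the number of bins of
    the map (in a multi-chromosome run, pass ``2 * n_bins`` of the longest
    chromosome explicitly so all maps share one pool policy).  The main
    diagonal is set to NaN and excluded from all downstream tests.
    """
    n = cmap.n_bins
    if n < 3:
        raise ValueError("rank normalization needs at least 3 bins")
    L_val = 2 * n if L == "auto" else int(L)
    if L_val < 1:
        raise ValueError("pool length L must be >= 1")
    ranks = np.full((n, n), np.nan)
    for k in range(1, n):
        offsets = _pool_offsets(n, k, L_val)
        pool = np.concatenate([np.diagonal(cmap.scores, off) for off in offsets])
        head = stats.rankdata(pool)[: n - k] / pool.size
        idx = np.arange(n - k)
        ranks[idx, idx + k] = head
        ranks[idx + k, idx] = head
    return NormalizedContactMap(cmap.chrom, cmap.bin_size, ranks, L_val)


def compartment_pc1(norm: NormalizedContactMap) -> CompartmentTrack:
    """First principal component of the bin-by-bin correlation matrix of the
    normalized contacts; its sign separates the two chromatin compartments.

    Bins whose contact profile has no variance (e.g. from all-zero rows of
    the raw map) are masked out and reported as NaN.  The returned vector is
    oriented so that positive PC1 correlates with higher per-bin total
    normalized contact, the usual open-compartment proxy.
    """
    n = norm.n_bins
    if n < 3:
        raise ValueError("compartment analysis needs at least 3 bins")
    if all(np.ptp(np.diagonal(norm.ranks, k)) == 0 for k in range(1, n)):
        raise DegenerateInputError(
            "no contact variation at any genomic distance (constant map?)"
        )
    corr = pd.DataFrame(norm.ranks).corr().to_numpy()
    valid = ~np.all(np.isnan(corr - np.eye(n)), axis=0)
    if valid.sum() < 3:
        raise DegenerateInputError("too few bins with contact variance for PC1")
    sub = corr[np.ix_(valid, valid)]
    if np.any(np.isnan(sub)):
        # isolated undefined correlations: treat as zero association
        sub = np.where(np.isnan(sub), 0.0, sub)
    if np.allclose(sub - np.diag(np.diag(sub)), 0.0):
        raise DegenerateInputError("correlation matrix has no off-diagonal structure")
    w, v = np.linalg.eigh(sub)
    pc = v[:, -1]
    pc1 = np.full(n, np.nan)
    pc1[valid] = pc / np.linalg.norm(pc)
    totals = np.nansum(norm.ranks, axis=0)[valid]
    if totals.std() > 0 and pc.std() > 0:
        if np.corrcoef(pc, totals)[0, 1] < 0:
            pc1 = -pc1
    return CompartmentTrack(norm.chrom, norm.bin_size, pc1, open_is_positive=True)


def correlate_insertions_compartment(
    track: CompartmentTrack, counts: np.ndarray
) -> tuple[float, float]:
    """Pearson correlation (with two-sided p-value) between per-bin insertion
    counts and the compartment PC1, over bins where PC1 is defined."""
    counts = np.asarray(counts, dtype=float)
    if counts.shape[0] != track.pc1.shape[0]:
        raise ValueError("insertion profile and compartment track bin counts differ")
    mask = ~np.isnan(track.pc1)
    x, y = track.pc1[mask], counts[mask]
    if x.std() == 0 or y.std() == 0:
        raise DegenerateInputError("correlation undefined: zero variance input")
    r, p = stats.pearsonr(y, x)
    return float(r), float(p)
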