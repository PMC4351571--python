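"""Insertion binning, bin categories and insertion-cluster (IC) detection.

Insertions from an insertional-mutagenesis screen are (chromosome,
position, sample) records.  Two views are used downstream:

* per-bin counts at coarse (200 kb) resolution, with each bin labelled
  non-inserted (NI), inserted (I) or recurrently inserted (RI) by count
  thresholds, for genome-wide co-localization statistics;
* a Gaussian-kernel-smoothed density f(x) along the unbinned coordinate,
  whose local maxima define ICs — candidate selected loci — at the fine
  (40 kb) Hi-C resolution.

The kernel is unnormalized, so an isolated insertion contributes a peak of
height exactly 1 and peak heights read as "effective overlapping
insertions"; the median peak height separates high- from low-scoring ICs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: bin category labels
NI, I, RI, UNASSIGNED = "NI", "I", "RI", "UNASSIGNED"


@dataclass
class InsertionDataset:
    """Cohort of insertion records across tumour samples.

    ``records`` has columns ``chrom`` (str), ``pos`` (int, 0-based bp) and
    ``sample`` (str, drawn from the fixed roster ``samples``); ``genome``
    maps chromosome name to length in bp.
    """

    records: pd.DataFrame
    samples: list[str]
    genome: dict[str, int]

    def __post_init__(self) -> None:
        required = {"chrom", "pos", "sample"}
        if not required.issubset(self.records.columns):
            raise ValueError(f"records must have columns {sorted(required)}")
        for idx, row in enumerate(self.records.itertuples(index=False)):
            if row.chrom not in self.genome:
                raise ValueError(f"record {idx}: unknown chromosome {row.chrom!r}")
            if not 0 <= row.pos < self.genome[row.chrom]:
                raise ValueError(
                    f"record {idx}: position {row.pos} outside {row.chrom} "
                    f"[0, {self.genome[row.chrom]})"
                )
        roster = set(self.samples)
        bad = set(self.records["sample"]) - roster
        if bad:
            raise ValueError(f"samples outside the cohort roster: {sorted(bad)[:5]}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class BinnedInsertionProfile:
    """Per-bin insertion counts ``S_i`` for one chromosome, with optional
    NI/I/RI category labels."""

    chrom: str
    bin_size: int
    counts: np.ndarray
    categories: np.ndarray | None = None

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]


@dataclass
class DensityTrack:
    """Kernel-smoothed insertion count f(x) on a regular bp grid."""

    chrom: str
    grid: np.ndarray
    values: np.ndarray
    sigma: float


@dataclass(frozen=True)
class InsertionCluster:
    """A peak of the smoothed insertion density with a bin-aligned extent
    ``[start_bin, end_bin)`` (after the minimum-size expansion) and the set
    of samples carrying at least one insertion inside the extent."""

    chrom: str
    peak_position: float
    peak_height: float
    start_bin: int
    end_bin: int
    sample_hits: frozenset = frozenset()

    @property
    def n_bins(self) -> int:
        return self.end_bin - self.start_bin

    def span_bp(self, bin_size: int) -> tuple[int, int]:
        return self.start_bin * bin_size, self.end_bin * bin_size


def bin_insertions(
    data: InsertionDataset, bin_size: int
) -> dict[str, BinnedInsertionProfile]:
    """Tally insertions into half-open genomic bins of ``bin_size`` bp:
    an insertion at position p lands in bin ``p // bin_size``."""
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    out: dict[str, BinnedInsertionProfile] = {}
    for chrom, length in data.genome.items():
        n_bins = -(-length // bin_size)
        pos = data.records.loc[data.records["chrom"] == chrom, "pos"].to_numpy(
            dtype=np.int64
        )
        counts = np.bincount(pos // bin_size, minlength=n_bins).astype(int)
        out[chrom] = BinnedInsertionProfile(chrom, bin_size, counts)
    return out


def categorize_bins(
    profile: BinnedInsertionProfile, n_m: int = 2, n_r: int = 5
) -> BinnedInsertionProfile:
    """Label bins non-inserted (S=0), inserted (0<S<=n_m) or recurrently
    inserted (S>n_r); counts in the gap (n_m, n_r] stay UNASSIGNED and are
    excluded from category tests."""
    if not 0 < n_m <= n_r:
        raise ValueError("thresholds must satisfy 0 < n_m <= n_r")
    s = profile.counts
    cats = np.select(
        [s == 0, s <= n_m, s > n_r], [NI, I, RI], default=UNASSIGNED
    ).astype(object)
    return BinnedInsertionProfile(profile.chrom, profile.bin_size, s.copy(), cats)


def smooth_insertion_density(
    data: InsertionDataset,
    sigma: float = 40_000.0,
    grid_step: float = 10_000.0,
) -> dict[str, DensityTrack]:
    """Gaussian-kernel convolution of the insertion positions.

    f(x) = sum_i exp(-(x - p_i)^2 / (2 sigma^2)), evaluated on a regular grid
    (default step sigma/4).  The kernel is not area-normalized, so one
    isolated insertion yields a peak of height 1.
    """
    if sigma <= 0 or grid_step <= 0:
        raise ValueError("sigma and grid_step must be positive")
    out: dict[str, DensityTrack] = {}
    # +-8 sigma window: truncation error per insertion < 2e-14
    halfwin = int(np.ceil(8 * sigma / grid_step))
    for chrom, length in data.genome.items():
        grid = np.arange(0.0, length, grid_step)
        vals = np.zeros_like(grid)
        pos = data.records.loc[data.records["chrom"] == chrom, "pos"].to_numpy()
        for p in pos:
            c = int(round(p / grid_step))
            lo, hi = max(0, c - halfwin), min(grid.size, c + halfwin + 1)
            vals[lo:hi] += np.exp(-((grid[lo:hi] - p) ** 2) / (2 * sigma**2))
        out[chrom] = DensityTrack(chrom, grid, vals, sigma)
    return out


def detect_clusters(
    density: DensityTrack,
    bin_size: int,
    data: InsertionDataset | None = None,
    min_density: float = 0.5,
) -> list[InsertionCluster]:
    """Call ICs as strict local maxima of f(x).

    Each peak's extent runs between the flanking local minima of f, trimmed
    inward to where f stays above ``min_density`` (on the unnormalized
    kernel scale 0.5 means half of a single insertion's contribution, so
    extents never bleed into insertion-free background), then aligned
    outward to the nearest ``bin_size`` boundaries; extents under three bins
    are expanded by one bin on both sides (clipped at the chromosome ends).
    Overlapping extents are kept separate.  A flat density yields no peaks.
    """
    f, grid = density.values, density.grid
    step = grid[1] - grid[0] if grid.size > 1 else float(bin_size)
    chrom_bins = -(-int(grid[-1] + step) // bin_size)
    interior = np.arange(1, f.size - 1)
    peaks = interior[(f[interior] > f[interior - 1]) & (f[interior] > f[interior + 1])]
    clusters: list[InsertionCluster] = []
    for pk in peaks:
        left = pk
        while left > 0 and f[left - 1] < f[left]:
            left -= 1
        right = pk
        while right < f.size - 1 and f[right + 1] < f[right]:
            right += 1
        floor = min(min_density, f[pk] / 2)
        while left < pk and f[left] < floor:
            left += 1
        while right > pk and f[right] < floor:
            right -= 1
        start_bin = int(grid[left] // bin_size)
        end_bin = max(int(-(-grid[right] // bin_size)), start_bin + 1)
        if end_bin - start_bin < 3:
            start_bin -= 1
            end_bin += 1
        start_bin = max(0, start_bin)
        end_bin = min(chrom_bins, end_bin)
        hits: frozenset = frozenset()
        if data is not None:
            lo, hi = start_bin * bin_size, end_bin * bin_size
            rec = data.records
            sel = (
                (rec["chrom"] == density.chrom)
                & (rec["pos"] >= lo)
                & (rec["pos"] < hi)
            )
            hits = frozenset(rec.loc[sel, "sample"])
        clusters.append(
            InsertionCluster(
                density.chrom, float(grid[pk]), float(f[pk]), start_bin, end_bin, hits
            )
        )
    return clusters


def split_by_peak_height(
    clusters: list[InsertionCluster],
) -> tuple[list[InsertionCluster], list[InsertionCluster]]:
    """Split ICs at the genome-wide median peak height: *high* ICs strictly
    exceed the median (evidence of selection), the rest are *low*."""
    if not clusters:
        raise ValueError("no clusters to split")
    heights = np.array([c.peak_height for c in clusters])
    threshold = float(np.median(heights))
    high = [c for c in clusters if c.peak_height > threshold]
    low = [c for c in clusters if c.peak_height <= threshold]
    return high, low


def randomize_insertions(
    data: InsertionDataset,
    mode: str = "uniform",
    tss_bins: dict[str, np.ndarray] | None = None,
    bin_size: int | None = None,
    seed: int = 0,
) -> InsertionDataset:
    """Permutation control: redraw every insertion position, keeping the
    per-sample insertion counts.

    ``"uniform"`` redraws positions uniformly over the whole genome;
    ``"tss_bins"`` redraws uniformly within the supplied per-chromosome bin
    sets (requires ``bin_size``), emulating restriction to bins containing a
    transcription start site.
    """
    rng = np.random.default_rng(seed)
    n = len(data.records)
    chroms = list(data.genome)
    if mode == "uniform":
        lengths = np.array([data.genome[c] for c in chroms], dtype=float)
        offsets = np.concatenate([[0.0], np.cumsum(lengths)])
        u = rng.uniform(0.0, offsets[-1], size=n)
        ci = np.searchsorted(offsets, u, side="right") - 1
        new_chrom = [chroms[i] for i in ci]
        new_pos = (u - offsets[ci]).astype(int)
    elif mode == "tss_bins":
        if not tss_bins or all(len(v) == 0 for v in tss_bins.values()):
            raise ValueError("tss_bins mode requires a non-empty bin set")
        if bin_size is None:
            raise ValueError("tss_bins mode requires bin_size")
        flat = [(c, int(b)) for c, bins in tss_bins.items() for b in bins]
        picks = rng.integers(0, len(flat), size=n)
        new_chrom, new_pos = [], []
        for k in picks:
            c, b = flat[k]
            hi = min((b + 1) * bin_size, data.genome[c])
            new_chrom.append(c)
            new_pos.append(int(rng.integers(b * bin_size, hi)))
        new_pos = np.asarray(new_pos)
    else:
        raise ValueError(f"unknown randomization mode {mode!r}")
    out = data.records.copy()
    out["chrom"] = new_chrom
    out["pos"] = new_pos
    return InsertionDataset(out, list(data.samples), dict(data.genome))
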