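"""Synthetic Hi-C maps, insertion cohorts and expression matrices.

The generator reproduces the statistical structure the analysis assumes,
so every downstream stage can be exercised with known ground truth:

* a symmetric non-negative contact matrix with power-law distance decay,
  a plaid two-compartment pattern (alternating blocks, multiplicative
  same-compartment boost) and multiplicative log-normal noise;
* insertion cohorts made of a uniform background plus selected clusters,
  optionally with pairs of clusters whose per-sample occupancy is made
  mutually exclusive to a chosen degree;
* elevated contact planted between chosen locus pairs (the positive signal
  CLIC detection must recover);
* an expression matrix in which the gene at a planted locus shifts in the
  samples carrying an insertion in that locus or in its planted partner.

One call simulates one chromosome; multi-chromosome cohorts are built by
repeated calls with derived seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clusters import InsertionDataset
from .hic import ContactMap


class ConfigurationError(ValueError):
    """A SimulationConfig field is out of range (the message names it)."""


@dataclass(frozen=True)
class ClusterSpec:
    """A selected insertion cluster: Gaussian kernel of ``width_bp`` around
    ``center_bin``, hitting ``expected_hits`` distinct samples."""

    center_bin: int
    width_bp: float
    expected_hits: int
    selected: bool = True


@dataclass(frozen=True)
class ClicPairSpec:
    """A planted co-localized pair: contact between the two cluster loci is
    boosted by ``boost`` and a fraction ``exclusivity`` of samples hitting
    both clusters is reassigned so they hit exactly one."""

    cluster_a: int
    cluster_b: int
    boost: float = 5.0
    exclusivity: float = 0.0


@dataclass
class SimulationConfig:
    n_bins: int = 500
    bin_size: int = 40_000
    decay_exponent: float = 1.0
    compartment_block_len: int = 25
    compartment_contrast: float = 2.0
    noise_dispersion: float = 0.3
    n_samples: int = 100
    background_rate: float = 5.0
    cluster_specs: tuple[ClusterSpec, ...] = ()
    planted_clic_pairs: tuple[ClicPairSpec, ...] = ()
    effect_size: float = 3.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bins < 10:
            raise ConfigurationError("n_bins must be >= 10")
        if self.bin_size <= 0:
            raise ConfigurationError("bin_size must be positive")
        if self.compartment_contrast < 1:
            raise ConfigurationError("compartment_contrast must be >= 1")
        if self.compartment_block_len < 1:
            raise ConfigurationError("compartment_block_len must be >= 1")
        if self.noise_dispersion < 0:
            raise ConfigurationError("noise_dispersion must be >= 0")
        if self.n_samples < 1:
            raise ConfigurationError("n_samples must be >= 1")
        if self.background_rate < 0:
            raise ConfigurationError("background_rate must be >= 0")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        self.cluster_specs = tuple(
            s if isinstance(s, ClusterSpec) else ClusterSpec(*s)
            for s in self.cluster_specs
        )
        self.planted_clic_pairs = tuple(
            p if isinstance(p, ClicPairSpec) else ClicPairSpec(*p)
            for p in self.planted_clic_pairs
        )
        for s in self.cluster_specs:
            if s.width_bp <= 0:
                raise ConfigurationError("cluster_specs: width_bp must be > 0")
            if not 0 <= s.center_bin < self.n_bins:
                raise ConfigurationError("cluster_specs: center_bin outside chromosome")
        for p in self.planted_clic_pairs:
            if not 0 <= p.exclusivity <= 1:
                raise ConfigurationError("planted_clic_pairs: exclusivity must be in [0, 1]")
            k = len(self.cluster_specs)
            if not (0 <= p.cluster_a < k and 0 <= p.cluster_b < k) or p.cluster_a == p.cluster_b:
                raise ConfigurationError("planted_clic_pairs: invalid cluster indices")

    @property
    def chrom_length(self) -> int:
        return self.n_bins * self.bin_size

    @property
    def chrom(self) -> str:
        return "chr1"


def compartment_labels(config: SimulationConfig) -> np.ndarray:
    """Deterministic alternating compartment blocks (0/1)."""
    return (np.arange(config.n_bins) // config.compartment_block_len) % 2


def cluster_interval(config: SimulationConfig, index: int) -> tuple[int, int]:
    """Half-open bin interval covered by a cluster spec.

    Spans +-3 placement-kernel standard deviations (the kernel sd is
    width/4, so this covers essentially all of the cluster's insertions)."""
    spec = config.cluster_specs[index]
    half = max(1, int(np.ceil(3 * (spec.width_bp / 4) / config.bin_size)))
    return (
        max(0, spec.center_bin - half),
        min(config.n_bins, spec.center_bin + half + 1),
    )


def simulate_contact_map(config: SimulationConfig) -> ContactMap:
    """Power-law decay x plaid compartment boost x log-normal noise.

    Expected contact between bins i, j is (|i-j|+1)^(-decay_exponent),
    multiplied by ``compartment_contrast`` when the bins share a compartment
    block.  The noise is mean-one log-normal with log-sd
    ``noise_dispersion``, so expectations are preserved and the matrix stays
    strictly positive; it is drawn on the upper triangle and mirrored.
    """
    n = config.n_bins
    d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    base = (d + 1.0) ** (-config.decay_exponent)
    comp = compartment_labels(config)
    same = np.equal.outer(comp, comp)
    base = np.where(same, base * config.compartment_contrast, base)
    rng = np.random.default_rng([config.seed, 0])
    if config.noise_dispersion > 0:
        s = config.noise_dispersion
        ln = rng.normal(-0.5 * s * s, s, size=(n, n))
        iu = np.triu_indices(n)
        noise = np.empty((n, n))
        noise[iu] = np.exp(ln[iu])
        noise.T[iu] = noise[iu]
        base = base * noise
    return ContactMap(config.chrom, config.bin_size, base)


def plant_clic_contacts(
    cmap: ContactMap,
    pairs: list[tuple[tuple[int, int], tuple[int, int], float]],
) -> ContactMap:
    """Multiply the A x B (and B x A) submatrix by ``boost`` for each
    (interval A, interval B, boost) triple; intervals are half-open bin
    ranges and must be disjoint."""
    scores = cmap.scores.copy()
    n = cmap.n_bins
    for (a0, a1), (b0, b1), boost in pairs:
        if not (0 <= a0 < a1 <= n and 0 <= b0 < b1 <= n):
            raise ValueError("planted interval outside contact-map bounds")
        if a0 < b1 and b0 < a1:
            raise ValueError("a planted locus pair must be disjoint")
        if boost < 1:
            raise ValueError("contact boost must be >= 1")
        ra, rb = np.arange(a0, a1), np.arange(b0, b1)
        scores[np.ix_(ra, rb)] *= boost
        scores[np.ix_(rb, ra)] *= boost
    return ContactMap(cmap.chrom, cmap.bin_size, scores)


def simulate_insertions(config: SimulationConfig) -> InsertionDataset:
    """Uniform background plus selected clusters, with optional planted
    mutual exclusivity between paired clusters.

    Background: per sample a Poisson(``background_rate``) number of
    insertions, uniform over the chromosome.  Each cluster hits
    ``expected_hits`` distinct samples (drawn without replacement); each hit
    sample receives one insertion at N(center, (width/4)^2), clipped to the
    chromosome.  For each planted pair with exclusivity e, a fraction e of
    the samples hitting both clusters is moved out of one of them
    (alternately), with a replacement sample drawn outside the pair when
    available so the hit counts are preserved.
    """
    rng = np.random.default_rng([config.seed, 1])
    samples = [f"S{i:04d}" for i in range(config.n_samples)]
    hits: list[set[int]] = []
    for spec in config.cluster_specs:
        k = int(round(spec.expected_hits))
        if k > config.n_samples:
            raise ConfigurationError(
                "cluster_specs: expected_hits exceeds n_samples"
            )
        hits.append(set(rng.choice(config.n_samples, size=k, replace=False).tolist()))
    for pair in config.planted_clic_pairs:
        a, b = hits[pair.cluster_a], hits[pair.cluster_b]
        overlap = sorted(a & b)
        n_move = int(round(pair.exclusivity * len(overlap)))
        if n_move:
            movers = rng.choice(len(overlap), size=n_move, replace=False)
            for t, idx in enumerate(sorted(movers.tolist())):
                victim = a if t % 2 else b
                victim.discard(overlap[idx])
                free = sorted(set(range(config.n_samples)) - a - b)
                if free:
                    victim.add(int(rng.choice(free)))
    rows: list[tuple[str, int, str]] = []
    length = config.chrom_length
    for si in range(config.n_samples):
        for _ in range(rng.poisson(config.background_rate)):
            rows.append((config.chrom, int(rng.integers(0, length)), samples[si]))
    for spec, hit in zip(config.cluster_specs, hits):
        center = spec.center_bin * config.bin_size + config.bin_size // 2
        for si in sorted(hit):
            pos = int(round(rng.normal(center, spec.width_bp / 4)))
            rows.append((config.chrom, int(np.clip(pos, 0, length - 1)), samples[si]))
    records = pd.DataFrame(rows, columns=["chrom", "pos", "sample"])
    return InsertionDataset(records, samples, {config.chrom: length})


def simulate_dataset(config: SimulationConfig) -> tuple[ContactMap, InsertionDataset]:
    """Contact map with planted pair contacts boosted, plus the matching
    insertion cohort."""
    cmap = simulate_contact_map(config)
    planted = [
        (
            cluster_interval(config, p.cluster_a),
            cluster_interval(config, p.cluster_b),
            p.boost,
        )
        for p in config.planted_clic_pairs
    ]
    if planted:
        cmap = plant_clic_contacts(cmap, planted)
    return cmap, simulate_insertions(config)


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with gene -> locus membership
    (``None`` for filler genes)."""

    values: pd.DataFrame
    gene_locus: dict[str, int | None]


def simulate_expression(
    insertions: InsertionDataset,
    loci: list[tuple[str, int, int]],
    config: SimulationConfig,
    n_filler: int = 50,
) -> ExpressionMatrix:
    """One gene per locus plus filler genes.

    expression = effect_size * 1[sample has an insertion in the gene's locus
    or in a locus planted as its pair partner] + N(0, noise_sd).  ``loci``
    are (chrom, start_bp, end_bp) intervals indexed like
    ``config.cluster_specs`` so partners resolve through
    ``config.planted_clic_pairs``.
    """
    for chrom, start, end in loci:
        if chrom not in insertions.genome or not 0 <= start < end <= insertions.genome[chrom]:
            raise ConfigurationError("loci: interval outside genome bounds")
    rng = np.random.default_rng([config.seed, 2])
    partners: dict[int, set[int]] = {i: set() for i in range(len(loci))}
    for p in config.planted_clic_pairs:
        if p.cluster_a < len(loci) and p.cluster_b < len(loci):
            partners[p.cluster_a].add(p.cluster_b)
            partners[p.cluster_b].add(p.cluster_a)
    rec = insertions.records
    inserted: list[set[str]] = []
    for chrom, start, end in loci:
        sel = (rec["chrom"] == chrom) & (rec["pos"] >= start) & (rec["pos"] < end)
        inserted.append(set(rec.loc[sel, "sample"]))
    names, rows, gene_locus = [], [], {}
    for gi in range(len(loci)):
        carriers = set(inserted[gi])
        for pj in partners[gi]:
            carriers |= inserted[pj]
        ind = np.array([s in carriers for s in insertions.samples], dtype=float)
        rows.append(config.effect_size * ind + rng.normal(0, config.noise_sd, insertions.n_samples))
        name = f"gene_locus{gi}"
        names.append(name)
        gene_locus[name] = gi
    for fi in range(n_filler):
        rows.append(rng.normal(0, config.noise_sd, insertions.n_samples))
        name = f"filler{fi}"
        names.append(name)
        gene_locus[name] = None
    values = pd.DataFrame(np.vstack(rows), index=names, columns=insertions.samples)
    return ExpressionMatrix(values, gene_locus)
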