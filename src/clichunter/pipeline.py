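"""End-to-end pipeline driver.

Chains the analysis stages — rank normalization, compartment track,
insertion binning and categories, IC detection, CLIC detection and the
downstream statistics — over either simulated or file-based inputs, writes
every result table and records a machine-readable run manifest so any run
is reproducible from its parameters and seed.
"""

from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import asdict, dataclass, field


from . import io as cio
from .clusters import (
    bin_insertions,
    categorize_bins,
    detect_clusters,
    smooth_insertion_density,
    split_by_peak_height,
)
from .coloc import detect_clics
from .downstream import mean_manhattan, sample_locus_matrix
from .hic import (
    compartment_pc1,
    coarsen_contact_map,
    correlate_insertions_compartment,
    rank_normalize,
)
from .simulate import SimulationConfig, simulate_dataset

log = logging.getLogger("clichunter")


@dataclass
class RunConfig:
    """Pipeline parameters; the defaults are the study settings (40 kb maps,
    200 kb insertion bins, 2*sigma = 80 kb kernel, N_m=2, N_r=5,
    alpha=1e-5, L = twice the longest chromosome's bin count)."""

    insertions_path: str | None = None
    contact_map_paths: dict[str, str] = field(default_factory=dict)
    contact_map_dialect: str = "dense"
    genome: dict[str, int] = field(default_factory=dict)
    simulation: SimulationConfig | None = None
    bin_size: int = 40_000
    coarse_factor: int = 5
    sigma: float = 40_000.0
    grid_step: float = 10_000.0
    n_m: int = 2
    n_r: int = 5
    alpha: float = 1e-5
    L: int | str = "auto"
    seed: int = 0
    outdir: str | None = None


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and return a result bundle.

    The bundle maps stage names to in-memory results; when ``outdir`` is set
    every table is also written out along with ``manifest.json``.
    """
    t0 = time.time()
    stage = "inputs"
    try:
        if config.simulation is not None:
            cmap, data = simulate_dataset(config.simulation)
            maps = {cmap.chrom: cmap}
        else:
            if not config.contact_map_paths or config.insertions_path is None:
                raise ValueError("need contact_map_paths and insertions_path (or a simulation)")
            maps = {}
            for chrom, path in config.contact_map_paths.items():
                if not os.path.exists(path):
                    raise FileNotFoundError(path)
                maps[chrom] = cio.read_contact_map(
                    path, config.contact_map_dialect, chrom, config.bin_size
                )
            genome = config.genome or {
                c: m.n_bins * m.bin_size for c, m in maps.items()
            }
            if not os.path.exists(config.insertions_path):
                raise FileNotFoundError(config.insertions_path)
            data = cio.read_insertions(config.insertions_path, genome)
        log.info("inputs: %d chromosomes, %d insertions, %d samples",
                 len(maps), len(data), data.n_samples)

        stage = "normalize"
        L = config.L
        if L == "auto":
            L = 2 * max(m.n_bins for m in maps.values())
        norm = {c: rank_normalize(m, L) for c, m in maps.items()}
        coarse = {
            c: rank_normalize(coarsen_contact_map(m, config.coarse_factor), L)
            for c, m in maps.items()
        }

        stage = "compartments"
        tracks = {c: compartment_pc1(nm) for c, nm in coarse.items()}

        stage = "insertion-binning"
        coarse_bin = config.bin_size * config.coarse_factor
        profiles = {
            c: categorize_bins(p, config.n_m, config.n_r)
            for c, p in bin_insertions(data, coarse_bin).items()
        }
        compartment_corr = {}
        for c, track in tracks.items():
            try:
                compartment_corr[c] = correlate_insertions_compartment(
                    track, profiles[c].counts
                )
            except ValueError:
                compartment_corr[c] = (float("nan"), float("nan"))

        stage = "clusters"
        density = smooth_insertion_density(data, config.sigma, config.grid_step)
        clusters = []
        for c in maps:
            clusters.extend(detect_clusters(density[c], config.bin_size, data))
        high, low = split_by_peak_height(clusters) if clusters else ([], [])
        log.info("clusters: %d ICs (%d high-scoring)", len(clusters), len(high))

        stage = "clics"
        clics = detect_clics(norm, high, config.alpha, L)
        significant = [c for c in clics if c.significant]
        log.info("clics: %d pairs tested, %d significant", len(clics), len(significant))

        stage = "downstream"
        exclusion = None
        if significant and high:
            loci = sorted(
                {ic for c in significant for ic in (c.ic_a, c.ic_b)},
                key=lambda ic: (ic.chrom, ic.start_bin),
            )
            slm = sample_locus_matrix(data, loci, config.bin_size)
            index = {ic: k for k, ic in enumerate(loci)}
            distances = [
                mean_manhattan(slm, index[c.ic_a], index[c.ic_b]) for c in significant
            ]
            exclusion = {"clic_mean_manhattan": distances}

        stage = "outputs"
        bundle = {
            "maps": maps,
            "normalized": norm,
            "compartments": tracks,
            "compartment_correlation": compartment_corr,
            "profiles": profiles,
            "density": density,
            "clusters": clusters,
            "high_clusters": high,
            "low_clusters": low,
            "clics": clics,
            "significant_clics": significant,
            "exclusion": exclusion,
            "insertions": data,
        }
        if config.outdir:
            os.makedirs(config.outdir, exist_ok=True)
            out = config.outdir
            cio.write_insertions(data, os.path.join(out, "insertions.bed"))
            for c, track in tracks.items():
                cio.write_compartment_track(
                    track, os.path.join(out, f"compartments_{c}.bedgraph")
                )
            cio.write_clusters(clusters, config.bin_size, os.path.join(out, "ics.bed"))
            cio.write_clics(clics, config.bin_size, os.path.join(out, "clics.tsv"))
            cio.write_clics_bedpe(
                significant, config.bin_size, os.path.join(out, "clics.bedpe")
            )
            manifest = {
                "parameters": {
                    "bin_size": config.bin_size,
                    "coarse_factor": config.coarse_factor,
                    "sigma": config.sigma,
                    "grid_step": config.grid_step,
                    "n_m": config.n_m,
                    "n_r": config.n_r,
                    "alpha": config.alpha,
                    "L": L,
                    "seed": config.seed,
                },
                "simulation": asdict(config.simulation) if config.simulation else None,
                "counts": {
                    "insertions": len(data),
                    "samples": data.n_samples,
                    "clusters": len(clusters),
                    "high_clusters": len(high),
                    "clic_tests": len(clics),
                    "significant_clics": len(significant),
                },
                "elapsed_s": round(time.time() - t0, 3),
            }
            with open(os.path.join(out, "manifest.json"), "w") as fh:
                json.dump(manifest, fh, indent=2, default=str)
        return bundle
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
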