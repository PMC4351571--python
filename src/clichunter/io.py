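"""Text-format readers and writers.

All genomic coordinates are 0-based half-open.  Supported dialects:
insertions as 4-column BED-like TSV (chrom, start, end=start+1, sample_id);
contact maps as whitespace-separated dense matrices or 3-column COO
(bin_i, bin_j, score; symmetrized by mirroring); tracks as bedGraph; ICs as
BED6 with the peak height in the score column; CLICs as TSV and BEDPE.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .clusters import DensityTrack, InsertionCluster, InsertionDataset
from .coloc import CLIC
from .hic import CompartmentTrack, ContactMap


class ParseError(ValueError):
    pass


def read_insertions(
    path: str,
    genome: dict[str, int],
    samples: list[str] | None = None,
) -> InsertionDataset:
    """Parse a BED-like insertion TSV (chrom, start, end, sample_id).

    Malformed lines are rejected with their line number; coordinates must be
    non-negative and chromosomes must be present in ``genome``.  If
    ``samples`` is omitted the roster is the sorted set of observed ids.
    """
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{ln}: expected >= 3 tab-separated columns")
            chrom, start = parts[0], parts[1]
            sample = parts[3] if len(parts) >= 4 else parts[2]
            try:
                pos = int(start)
            except ValueError:
                raise ParseError(f"{path}:{ln}: non-integer start {start!r}") from None
            if pos < 0:
                raise ParseError(f"{path}:{ln}: negative coordinate {pos}")
            if chrom not in genome:
                raise ParseError(f"{path}:{ln}: unknown chromosome {chrom!r}")
            rows.append((chrom, pos, sample))
    records = pd.DataFrame(rows, columns=["chrom", "pos", "sample"])
    if samples is None:
        samples = sorted(set(records["sample"]))
    return InsertionDataset(records, samples, dict(genome))


def write_insertions(data: InsertionDataset, path: str) -> None:
    with open(path, "w") as fh:
        for row in data.records.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.pos}\t{row.pos + 1}\t{row.sample}\n")


def read_contact_map(
    path: str,
    dialect: str = "dense",
    chrom: str = "chr1",
    bin_size: int = 40_000,
    n_bins: int | None = None,
) -> ContactMap:
    """Load a contact matrix.  Dense input must be square and symmetric to
    1e-8; COO input (bin_i, bin_j, score) is symmetrized by mirroring."""
    if dialect == "dense":
        mat = np.loadtxt(path, ndmin=2)
        if mat.shape[0] != mat.shape[1]:
            raise ParseError(f"{path}: dense contact map is not square {mat.shape}")
        if not np.allclose(mat, mat.T, rtol=0.0, atol=1e-8):
            raise ParseError(f"{path}: dense contact map is asymmetric")
        mat = (mat + mat.T) / 2
    elif dialect == "coo":
        raw = np.loadtxt(path, ndmin=2)
        if raw.shape[1] != 3:
            raise ParseError(f"{path}: COO contact map needs 3 columns")
        i = raw[:, 0].astype(int)
        j = raw[:, 1].astype(int)
        n = n_bins if n_bins is not None else int(max(i.max(), j.max())) + 1
        mat = np.zeros((n, n))
        mat[i, j] = raw[:, 2]
        upper = np.triu(mat, 1)
        lower = np.tril(mat, -1)
        sym = np.where(upper != 0, upper, lower.T)
        mat = sym + sym.T + np.diag(np.diag(mat))
    else:
        raise ValueError(f"unknown contact-map dialect {dialect!r}")
    return ContactMap(chrom, bin_size, mat)


def write_contact_map(cmap: ContactMap, path: str, dialect: str = "dense") -> None:
    if dialect == "dense":
        np.savetxt(path, cmap.scores, fmt="%.10g")
    elif dialect == "coo":
        iu = np.triu_indices(cmap.n_bins)
        with open(path, "w") as fh:
            for i, j in zip(*iu):
                v = cmap.scores[i, j]
                if v != 0:
                    fh.write(f"{i}\t{j}\t{v:.10g}\n")
    else:
        raise ValueError(f"unknown contact-map dialect {dialect!r}")


def write_bedgraph(
    chrom: str, starts: np.ndarray, ends: np.ndarray, values: np.ndarray, path: str
) -> None:
    with open(path, "w") as fh:
        for s, e, v in zip(starts, ends, values):
            if np.isnan(v):
                continue
            fh.write(f"{chrom}\t{int(s)}\t{int(e)}\t{v:.6g}\n")


def write_compartment_track(track: CompartmentTrack, path: str) -> None:
    n = track.pc1.shape[0]
    starts = np.arange(n) * track.bin_size
    write_bedgraph(track.chrom, starts, starts + track.bin_size, track.pc1, path)


def write_density_track(track: DensityTrack, path: str) -> None:
    step = track.grid[1] - track.grid[0] if track.grid.size > 1 else 1
    write_bedgraph(track.chrom, track.grid, track.grid + step, track.values, path)


def write_clusters(
    clusters: list[InsertionCluster], bin_size: int, path: str
) -> None:
    """BED6: name = IC index, score column = peak height."""
    with open(path, "w") as fh:
        for k, ic in enumerate(clusters):
            lo, hi = ic.span_bp(bin_size)
            fh.write(f"{ic.chrom}\t{lo}\t{hi}\tIC{k}\t{ic.peak_height:.4f}\t.\n")


def write_clics(clics: list[CLIC], bin_size: int, path: str) -> None:
    cols = (
        "chrom\tic_a_start\tic_a_end\tic_b_start\tic_b_end\t"
        "n_pos\td_min\td_max\tp_raw\tp_holm\tsignificant\n"
    )
    with open(path, "w") as fh:
        fh.write(cols)
        for c in clics:
            a0, a1 = c.ic_a.span_bp(bin_size)
            b0, b1 = c.ic_b.span_bp(bin_size)
            fh.write(
                f"{c.chrom}\t{a0}\t{a1}\t{b0}\t{b1}\t{c.n_pos}\t{c.d_min}\t"
                f"{c.d_max}\t{c.p_raw:.6g}\t{c.p_holm:.6g}\t{int(bool(c.significant))}\n"
            )


def write_clics_bedpe(clics: list[CLIC], bin_size: int, path: str) -> None:
    with open(path, "w") as fh:
        for k, c in enumerate(clics):
            a0, a1 = c.ic_a.span_bp(bin_size)
            b0, b1 = c.ic_b.span_bp(bin_size)
            fh.write(
                f"{c.chrom}\t{a0}\t{a1}\t{c.chrom}\t{b0}\t{b1}\tCLIC{k}\t"
                f"{c.p_holm:.6g}\t.\t.\n"
            )


def read_flat_config(path: str) -> dict[str, str]:
    """Flat ``key = value`` configuration file; '#' starts a comment."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ParseError(f"{path}:{ln}: expected 'key = value'")
            key, val = line.split("=", 1)
            out[key.strip()] = val.strip()
    return out
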