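"""5'SS-anchored coverage matrices, cpm normalization, ordering, metaplots.

Offset 0 is the first intronic base of a donor; exonic (upstream) positions
are negative.  Minus-strand sites are mirrored into transcript orientation,
so a signal "30 nt upstream" of a donor sits at offset -30 on both strands.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .annotation import DonorSite
from .errors import ConfigError
from .samio import ReadAln


@dataclass
class CoverageMatrix:
    """Sites x offsets signal matrix with its provenance."""

    values: np.ndarray  # (n_sites, 2 * flank)
    flank: int
    sites: Sequence[DonorSite]
    replicates: tuple[str, ...] = ()

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(-self.flank, self.flank)


def coverage_around_sites(
    reads: Iterable[ReadAln],
    sites: Sequence[DonorSite],
    flank: int = 200,
    unique_only: bool = True,
    min_mapq: int = 255,
    orientation: str = "sense",
    footprint: str = "full",
) -> np.ndarray:
    """Raw per-base read coverage in +/-``flank`` around each site.

    ``orientation``: "sense" counts reads on the site's transcript strand
    (mirrored for minus-strand sites), "forward" counts literal genomic
    plus-strand reads, "any" counts all.  ``footprint``: "full" adds the
    whole aligned footprint, "start" adds only the read's 5' base
    (cross-link proxy).
    """
    if flank <= 0:
        raise ConfigError("flank must be positive")
    if orientation not in ("sense", "forward", "any"):
        raise ConfigError(f"unknown orientation {orientation!r}")
    if footprint not in ("full", "start"):
        raise ConfigError(f"unknown footprint {footprint!r}")
    matrix = np.zeros((len(sites), 2 * flank), dtype=np.float64)
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for row, site in enumerate(sites):
        by_chrom.setdefault(site.chrom, []).append((site.pos, row, site.strand))
    arrays = {
        chrom: (
            np.array([p for p, _, _ in sorted(vals)]),
            [(r, st) for _, r, st in sorted(vals)],
        )
        for chrom, vals in by_chrom.items()
    }
    for read in reads:
        if unique_only and read.mapq < min_mapq:
            continue
        entry = arrays.get(read.chrom)
        if entry is None:
            continue
        positions, meta = entry
        lo = np.searchsorted(positions, read.start - flank, side="left")
        hi = np.searchsorted(positions, read.end + flank, side="right")
        if hi <= lo:
            continue
        if footprint == "start":
            blocks: tuple[tuple[int, int], ...] = (
                ((read.start, read.start + 1),)
                if read.strand == "+"
                else ((read.end - 1, read.end),)
            )
        else:
            blocks = read.blocks
        for j in range(lo, hi):
            p = positions[j]
            row, strand = meta[j]
            if orientation == "sense" and read.strand != strand:
                continue
            if orientation == "forward" and read.strand != "+":
                continue
            for bs, be in blocks:
                if strand == "+":
                    o1 = max(bs - p, -flank)
                    o2 = min(be - p, flank)
                else:
                    o1 = max(p - be + 1, -flank)
                    o2 = min(p - bs + 1, flank)
                if o2 > o1:
                    matrix[row, o1 + flank : o2 + flank] += 1.0
    return matrix


def normalize_cpm(
    raw_matrices: Sequence[np.ndarray] | np.ndarray,
    library_sizes: Sequence[int] | int,
    flank: int,
    sites: Sequence[DonorSite],
    replicates: tuple[str, ...] = (),
) -> CoverageMatrix:
    """Scale each replicate to counts-per-million and average elementwise."""
    if isinstance(raw_matrices, np.ndarray):
        raw_matrices = [raw_matrices]
    if isinstance(library_sizes, (int, np.integer)):
        library_sizes = [int(library_sizes)]
    if len(raw_matrices) != len(library_sizes):
        raise ConfigError("one library size per replicate matrix is required")
    scaled = []
    for mat, size in zip(raw_matrices, library_sizes):
        if size <= 0:
            raise ConfigError("library size must be positive")
        scaled.append(mat * (1e6 / size))
    return CoverageMatrix(
        values=np.mean(scaled, axis=0),
        flank=flank,
        sites=sites,
        replicates=replicates,
    )


def order_rows(matrix: np.ndarray, key: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rows sorted by decreasing ``key`` (stable; ties keep original order).

    The returned permutation can be applied to other matrices for
    cross-sample comparisons ordered by a reference sample.
    """
    key = np.asarray(key)
    if key.shape[0] != matrix.shape[0]:
        raise ConfigError(
            f"key length {key.shape[0]} != number of rows {matrix.shape[0]}"
        )
    order = np.argsort(-key, kind="stable")
    return matrix[order], order


@dataclass
class Metaplot:
    offsets: np.ndarray
    profile: np.ndarray  # column means over sites
    peak_offset: int
    degenerate: bool  # flat profile; peak is the tie-break value


def metaplot(matrix: CoverageMatrix | np.ndarray, flank: int | None = None) -> Metaplot:
    """Average profile over sites; peak = argmax offset (ties -> smallest)."""
    if isinstance(matrix, CoverageMatrix):
        values, flank = matrix.values, matrix.flank
    else:
        if flank is None:
            raise ConfigError("flank required when passing a bare array")
        values = matrix
    if values.size == 0:
        raise ConfigError("empty matrix")
    profile = values.mean(axis=0)
    peak_idx = int(np.argmax(profile))
    degenerate = bool(np.all(profile == profile[0]))
    return Metaplot(
        offsets=np.arange(-flank, flank),
        profile=profile,
        peak_offset=peak_idx - flank,
        degenerate=degenerate,
    )


def library_size(reads: Iterable[ReadAln], unique_only: bool = True, min_mapq: int = 255) -> int:
    """Uniquely mapped read count used as the cpm denominator."""
    return sum(1 for r in reads if not unique_only or r.mapq >= min_mapq)


def write_matrix_tsv(matrix: CoverageMatrix, path: str | Path) -> None:
    header = "site\t" + "\t".join(str(o) for o in matrix.offsets)
    with open(path, "w") as fh:
        fh.write(header + "\n")
        for site, row in zip(matrix.sites, matrix.values):
            name = f"{site.chrom}:{site.pos}:{site.strand}"
            fh.write(name + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")


def write_metaplot_tsv(plot: Metaplot, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("offset\tmean_signal\n")
        for o, v in zip(plot.offsets, plot.profile):
            fh.write(f"{o}\t{v:.6g}\n")
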