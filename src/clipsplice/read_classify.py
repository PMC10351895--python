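"""Read preprocessing, hierarchical read categorization and snRNA profiling.

The categorization follows a cascade: each read is assigned to the first
reference tier (rRNA, then protein-coding transcripts, then genome) in which
it has an alignment; the remainder is "unmapped".  The snRNA profile counts
only alignments at least 20 nt long with edit distance NM <= 1 and reports
per-base coverage, the fraction of all reads on major-spliceosome snRNAs,
and each snRNA's share of those reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ConfigError, ConsistencyError
from .samio import ReadAln

MS_SNRNAS = ("U1", "U2", "U4", "U5", "U6")


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------


@dataclass
class PreprocessResult:
    samples: dict[str, list[tuple[str, str]]]  # sample -> [(name, seq)]
    undetermined: list[tuple[str, str]]
    n_input: int
    n_duplicates: int

    def counts(self) -> dict[str, int]:
        out = {s: len(reads) for s, reads in self.samples.items()}
        out["undetermined"] = len(self.undetermined)
        return out


def trim_homopolymer_tail(seq: str, min_run: int = 6) -> str:
    """Remove a 3' run of a single nucleotide when it is at least ``min_run``."""
    if not seq:
        return seq
    last = seq[-1]
    i = len(seq)
    while i > 0 and seq[i - 1] == last:
        i -= 1
    run = len(seq) - i
    return seq[:i] if run >= min_run else seq


def preprocess_reads(
    reads: Iterable[tuple[str, str]],
    barcodes: Mapping[str, str],
    homopolymer_min_run: int = 6,
) -> PreprocessResult:
    """Collapse duplicates, demultiplex by exact barcode, trim 3' homopolymers.

    ``reads`` are (name, sequence) pairs whose sequence begins with an
    in-line barcode.  Exact-sequence duplicates are collapsed first (keeping
    the first name), reads are then routed by exact barcode prefix match
    (ties impossible: barcode collisions raise), the matched barcode is
    stripped, and 3' single-nucleotide runs of length >= ``min_run`` are
    removed.  Unmatched reads land in the "undetermined" bin untrimmed.
    """
    inverse: dict[str, str] = {}
    for sample, bc in barcodes.items():
        if bc in inverse:
            raise ConfigError(
                f"barcode {bc!r} assigned to both {inverse[bc]!r} and {sample!r}"
            )
        inverse[bc] = sample
    seen: set[str] = set()
    samples: dict[str, list[tuple[str, str]]] = {s: [] for s in barcodes}
    undetermined: list[tuple[str, str]] = []
    n_input = 0
    n_dup = 0
    lengths = sorted({len(bc) for bc in inverse}, reverse=True)
    for name, seq in reads:
        n_input += 1
        if seq in seen:
            n_dup += 1
            continue
        seen.add(seq)
        assigned = None
        for blen in lengths:
            sample = inverse.get(seq[:blen])
            if sample is not None:
                assigned = (sample, seq[blen:])
                break
        if assigned is None:
            undetermined.append((name, seq))
        else:
            sample, rest = assigned
            samples[sample].append((name, trim_homopolymer_tail(rest, homopolymer_min_run)))
    return PreprocessResult(
        samples=samples, undetermined=undetermined, n_input=n_input, n_duplicates=n_dup
    )


# ---------------------------------------------------------------------------
# Hierarchical categorization
# ---------------------------------------------------------------------------


@dataclass
class ReadCategoryTally:
    """Per-library counts over the cascade tiers plus "unmapped"."""

    counts: dict[str, int]
    total: int

    def fractions(self) -> dict[str, float]:
        return {k: v / self.total for k, v in self.counts.items()} if self.total else {}


def categorize_hierarchical(
    read_ids: Iterable[str], tier_hits: Mapping[str, set[str]]
) -> ReadCategoryTally:
    """Assign each read to the first tier of the cascade where it mapped.

    ``tier_hits`` is an ordered mapping tier name -> set of read ids mapped
    against that reference (each tier queried with the full read pool, as in
    a sequential alignment cascade).  Reads absent from every tier are
    counted as "unmapped".  A tier containing an id outside the read pool is
    a consistency error.
    """
    pool = set(read_ids)
    counts: dict[str, int] = {}
    remaining = set(pool)
    for tier, hits in tier_hits.items():
        stray = hits - pool
        if stray:
            raise ConsistencyError(
                f"tier {tier!r} contains {len(stray)} read ids missing from the "
                f"input pool (e.g. {sorted(stray)[:3]})"
            )
        assigned = remaining & hits
        counts[tier] = len(assigned)
        remaining -= assigned
    counts["unmapped"] = len(remaining)
    return ReadCategoryTally(counts=counts, total=len(pool))


# ---------------------------------------------------------------------------
# snRNA coverage
# ---------------------------------------------------------------------------


@dataclass
class SnrnaCoverage:
    coverage: dict[str, np.ndarray]  # per-snRNA per-base coverage
    counts: dict[str, int]  # reads passing the filters, per snRNA
    ms_fraction: float  # passing ms-snRNA reads / total library reads
    shares: dict[str, float] = field(default_factory=dict)  # within ms-snRNA reads


def snrna_profile(
    alignments: Iterable[ReadAln],
    snrna_lengths: Mapping[str, int],
    total_reads: int,
    min_length: int = 20,
    max_edit_distance: int = 1,
    ms_snrnas: Sequence[str] = MS_SNRNAS,
) -> SnrnaCoverage:
    """Coverage and read-share profile across snRNA references.

    Only alignments with aligned length >= ``min_length`` and edit distance
    <= ``max_edit_distance`` contribute.  ``total_reads`` is the library size
    used for the ms-snRNA fraction.
    """
    coverage = {
        name: np.zeros(int(snrna_lengths[name]), dtype=np.int64) for name in ms_snrnas
    }
    counts = {name: 0 for name in ms_snrnas}
    for aln in alignments:
        if aln.chrom not in coverage:
            continue
        if aln.nm is None:
            raise ConsistencyError(
                f"alignment {aln.name!r} lacks an edit-distance (NM) annotation"
            )
        if aln.aligned_length < min_length or aln.nm > max_edit_distance:
            continue
        counts[aln.chrom] += 1
        cov = coverage[aln.chrom]
        for s, e in aln.blocks:
            cov[max(s, 0) : min(e, len(cov))] += 1
    ms_total = sum(counts.values())
    shares = (
        {name: counts[name] / ms_total for name in ms_snrnas} if ms_total else
        {name: 0.0 for name in ms_snrnas}
    )
    ms_fraction = ms_total / total_reads if total_reads else 0.0
    return SnrnaCoverage(
        coverage=coverage, counts=counts, ms_fraction=ms_fraction, shares=shares
    )


def write_tally_tsv(tallies: Mapping[str, ReadCategoryTally], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("library\tcategory\tcount\tfraction\n")
        for lib in sorted(tallies):
            tally = tallies[lib]
            for cat, n in tally.counts.items():
                frac = n / tally.total if tally.total else 0.0
                fh.write(f"{lib}\t{cat}\t{n}\t{frac:.6g}\n")


def write_snrna_bedgraph(profile: SnrnaCoverage, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(profile.coverage):
            cov = profile.coverage[name]
            start = 0
            for i in range(1, len(cov) + 1):
                if i == len(cov) or cov[i] != cov[start]:
                    if cov[start] > 0:
                        fh.write(f"{name}\t{start}\t{i}\t{int(cov[start])}\n")
                    start = i
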