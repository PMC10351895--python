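"""Lightweight alignment I/O on top of pysam.

Analysis modules operate on in-memory :class:`ReadAln` records rather than on
open file handles, so the same code paths serve simulated SAM, real BAM, and
reads constructed directly in tests.  Coordinates are 0-based half-open
throughout; ``blocks`` are the gapless aligned segments of a read, so a
spliced alignment has one block per exon side of each junction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pysam


@dataclass(frozen=True, slots=True)
class ReadAln:
    """One aligned read."""

    name: str
    chrom: str
    strand: str  # '+' or '-'
    blocks: tuple[tuple[int, int], ...]  # sorted, non-overlapping, half-open
    mapq: int = 255
    nm: int | None = None
    tags: Mapping[str, str] = field(default_factory=dict)

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]

    @property
    def aligned_length(self) -> int:
        return sum(e - s for s, e in self.blocks)

    def gaps(self) -> tuple[tuple[int, int], ...]:
        """Junction gaps (N operations) between consecutive blocks."""
        return tuple(
            (self.blocks[i][1], self.blocks[i + 1][0])
            for i in range(len(self.blocks) - 1)
        )

    @property
    def is_spliced(self) -> bool:
        return len(self.blocks) > 1


def _segment_to_readaln(seg: pysam.AlignedSegment) -> ReadAln:
    blocks: list[tuple[int, int]] = []
    pos = seg.reference_start
    for op, length in seg.cigartuples or []:
        if op in (0, 7, 8):  # M, =, X
            if blocks and blocks[-1][1] == pos:
                blocks[-1] = (blocks[-1][0], pos + length)
            else:
                blocks.append((pos, pos + length))
            pos += length
        elif op in (2, 3):  # D, N consume reference
            pos += length
    nm = None
    if seg.has_tag("NM"):
        nm = int(seg.get_tag("NM"))
    tags = {}
    for key in ("XT", "XC"):
        if seg.has_tag(key):
            tags[key] = str(seg.get_tag(key))
    return ReadAln(
        name=seg.query_name,
        chrom=seg.reference_name,
        strand="-" if seg.is_reverse else "+",
        blocks=tuple(blocks),
        mapq=seg.mapping_quality,
        nm=nm,
        tags=tags,
    )


def read_alignments(path: str | Path, references: Sequence[str] | None = None) -> list[ReadAln]:
    """Load all mapped alignments from a SAM/BAM file.

    ``references`` restricts loading to reads on the named references.
    """
    wanted = set(references) if references is not None else None
    out: list[ReadAln] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for seg in fh.fetch(until_eof=True):
            if seg.is_unmapped or not seg.cigartuples:
                continue
            if wanted is not None and seg.reference_name not in wanted:
                continue
            out.append(_segment_to_readaln(seg))
    return out


def mapped_ids(path: str | Path) -> set[str]:
    """Names of all mapped reads in a SAM/BAM file."""
    out: set[str] = set()
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for seg in fh.fetch(until_eof=True):
            if not seg.is_unmapped:
                out.add(seg.query_name)
    return out


def write_sam(
    path: str | Path,
    reference_lengths: Mapping[str, int],
    reads: Iterable[tuple[ReadAln, str]],
) -> int:
    """Write ``(ReadAln, sequence)`` pairs to a SAM file.

    The sequence must be given in reference-forward orientation and match the
    total block length.  Returns the number of records written.
    """
    names = list(reference_lengths)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": n, "LN": int(reference_lengths[n])} for n in names],
    }
    ref_index = {n: i for i, n in enumerate(names)}
    n_written = 0
    with pysam.AlignmentFile(str(path), "wh", header=header) as fh:
        for aln, seq in reads:
            seg = pysam.AlignedSegment(fh.header)
            seg.query_name = aln.name
            seg.flag = 16 if aln.strand == "-" else 0
            seg.reference_id = ref_index[aln.chrom]
            seg.reference_start = aln.start
            seg.mapping_quality = aln.mapq
            cigar: list[tuple[int, int]] = []
            prev_end = None
            for bs, be in aln.blocks:
                if prev_end is not None:
                    cigar.append((3, bs - prev_end))  # N
                cigar.append((0, be - bs))  # M
                prev_end = be
            seg.cigartuples = cigar
            seg.query_sequence = seq
            tags: list[tuple[str, object]] = []
            if aln.nm is not None:
                tags.append(("NM", int(aln.nm)))
            for k, v in aln.tags.items():
                tags.append((k, v))
            if tags:
                seg.set_tags(tags)
            fh.write(seg)
            n_written += 1
    return n_written


def iter_sam_names(path: str | Path) -> Iterator[str]:
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for seg in fh.fetch(until_eof=True):
            yield seg.query_name
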