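"""Transcript annotation model: genes, transcripts, exons, introns, donors.

Internal coordinates are 0-based half-open; GTF I/O converts to the 1-based
closed convention of the format.  The donor position of an intron is its
first intronic base in transcript orientation (``start`` on '+', ``end - 1``
on '-'); the acceptor is the last intronic base.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import gffutils

from .errors import AnnotationError, GtfParseError

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    if not seq:
        return float("nan")
    s = seq.upper()
    return (s.count("G") + s.count("C")) / len(s)


@dataclass(frozen=True, slots=True)
class Intron:
    """A unique intron, aggregated over the transcripts that share it."""

    chrom: str
    start: int
    end: int
    strand: str
    gene_id: str
    transcript_ids: tuple[str, ...]
    gc: float = float("nan")

    def __post_init__(self):
        if self.end - self.start < 4:
            raise AnnotationError(
                f"intron {self.chrom}:{self.start}-{self.end} shorter than 4 nt"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def donor(self) -> int:
        """Genomic position of the first intronic base (transcript sense)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def acceptor(self) -> int:
        """Genomic position of the last intronic base (transcript sense)."""
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def key(self) -> tuple[str, int, int, str]:
        return (self.chrom, self.start, self.end, self.strand)


@dataclass
class Transcript:
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]  # sorted by genomic start

    def __post_init__(self):
        self.exons = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise AnnotationError(
                    f"transcript {self.transcript_id}: exons "
                    f"[{s1},{e1}) and [{s2},{e2}) overlap"
                )

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def intron_intervals(self) -> list[tuple[int, int]]:
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]


@dataclass
class Gene:
    gene_id: str
    chrom: str
    strand: str
    transcripts: dict[str, Transcript] = field(default_factory=dict)

    @property
    def start(self) -> int:
        return min(t.start for t in self.transcripts.values())

    @property
    def end(self) -> int:
        return max(t.end for t in self.transcripts.values())


class AnnotationModel:
    """Hierarchy of genes → transcripts → exons with derived introns."""

    def __init__(self, genes: Mapping[str, Gene]):
        self.genes: dict[str, Gene] = dict(genes)

    def transcripts(self) -> Iterator[Transcript]:
        for gene in self.genes.values():
            yield from gene.transcripts.values()

    def transcript(self, transcript_id: str) -> Transcript:
        for gene in self.genes.values():
            if transcript_id in gene.transcripts:
                return gene.transcripts[transcript_id]
        raise KeyError(transcript_id)

    def n_transcripts(self) -> int:
        return sum(len(g.transcripts) for g in self.genes.values())


@dataclass(frozen=True, slots=True)
class DonorSite:
    """A deduplicated 5' splice site.

    ``intron`` keeps the shortest intron using this donor, which carries the
    per-site feature metadata (length, GC) for downstream analyses.
    """

    chrom: str
    pos: int
    strand: str
    gene_id: str
    intron: Intron

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chrom, self.pos, self.strand)


@dataclass
class ExpressedSet:
    genes: set[str]
    transcripts: set[str]
    donors: list[DonorSite]


# ---------------------------------------------------------------------------
# GTF I/O
# ---------------------------------------------------------------------------

_STRANDS = {"+", "-"}


def _validate_gtf_lines(path: Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise GtfParseError(lineno, f"expected 9 tab-separated fields, got {len(fields)}")
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError:
                raise GtfParseError(lineno, "start/end are not integers") from None
            if start < 1 or end < start:
                raise GtfParseError(lineno, f"invalid coordinates {start}-{end}")
            if fields[6] not in _STRANDS:
                raise GtfParseError(lineno, f"invalid strand {fields[6]!r}")
            if fields[2] in ("gene", "transcript", "exon") and "gene_id" not in fields[8]:
                raise GtfParseError(lineno, "missing gene_id attribute")


def parse_gtf(path: str | Path) -> AnnotationModel:
    """Parse a GTF with explicit gene/transcript/exon records.

    Raises :class:`GtfParseError` with the offending line number for a
    malformed record and :class:`AnnotationError` for overlapping exons
    within one transcript.
    """
    path = Path(path)
    _validate_gtf_lines(path)
    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genes: dict[str, Gene] = {}
    for g in db.features_of_type("gene"):
        gid = g.attributes["gene_id"][0]
        genes[gid] = Gene(gene_id=gid, chrom=g.seqid, strand=g.strand)
    for t in db.features_of_type("transcript"):
        gid = t.attributes["gene_id"][0]
        tid = t.attributes["transcript_id"][0]
        if gid not in genes:
            genes[gid] = Gene(gene_id=gid, chrom=t.seqid, strand=t.strand)
        exons = [
            (e.start - 1, e.end)
            for e in db.children(t, featuretype="exon", order_by="start")
        ]
        if not exons:
            continue
        genes[gid].transcripts[tid] = Transcript(
            transcript_id=tid, gene_id=gid, chrom=t.seqid, strand=t.strand, exons=exons
        )
    return AnnotationModel(genes)


def write_gtf(model: AnnotationModel, path: str | Path, source: str = "clipsplice") -> None:
    lines: list[str] = []
    for gid in sorted(model.genes):
        gene = model.genes[gid]
        attrs = f'gene_id "{gid}";'
        lines.append(
            "\t".join(
                [gene.chrom, source, "gene", str(gene.start + 1), str(gene.end),
                 ".", gene.strand, ".", attrs]
            )
        )
        for tid in sorted(gene.transcripts):
            t = gene.transcripts[tid]
            tattrs = f'gene_id "{gid}"; transcript_id "{tid}";'
            lines.append(
                "\t".join(
                    [t.chrom, source, "transcript", str(t.start + 1), str(t.end),
                     ".", t.strand, ".", tattrs]
                )
            )
            numbered = t.exons if t.strand == "+" else t.exons[::-1]
            for i, (s, e) in enumerate(numbered, start=1):
                eattrs = tattrs + f' exon_number "{i}";'
                lines.append(
                    "\t".join(
                        [t.chrom, source, "exon", str(s + 1), str(e),
                         ".", t.strand, ".", eattrs]
                    )
                )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Intron extraction and expressed-set selection
# ---------------------------------------------------------------------------


def extract_introns(
    model: AnnotationModel, genome: Mapping[str, str] | None = None
) -> list[Intron]:
    """Unique introns over all transcripts, keyed by (chrom, start, end, strand).

    Transcript ids sharing an intron are aggregated; GC content is computed
    on the intronic sequence when a genome mapping is supplied.
    """
    grouped: dict[tuple[str, int, int, str], dict] = {}
    for t in model.transcripts():
        for s, e in t.intron_intervals():
            key = (t.chrom, s, e, t.strand)
            entry = grouped.setdefault(key, {"gene_id": t.gene_id, "tids": []})
            entry["tids"].append(t.transcript_id)
    out: list[Intron] = []
    for (chrom, s, e, strand), entry in sorted(grouped.items()):
        gc = float("nan")
        if genome is not None:
            gc = gc_fraction(str(genome[chrom][s:e]))
        out.append(
            Intron(
                chrom=chrom,
                start=s,
                end=e,
                strand=strand,
                gene_id=entry["gene_id"],
                transcript_ids=tuple(sorted(entry["tids"])),
                gc=gc,
            )
        )
    return out


def select_expressed(
    model: AnnotationModel,
    gene_counts: Mapping[str, float],
    transcript_abundance: Mapping[str, float],
    genome: Mapping[str, str] | None = None,
) -> ExpressedSet:
    """Apply the expression filters and collect deduplicated expressed donors.

    Genes with abundance > 0 and transcripts with abundance > 0 are kept;
    a donor is expressed when it belongs to at least one kept transcript of a
    kept gene.  Any positive-scaling unit (counts, FPKM, TPM) gives the same
    selection, since only the > 0 threshold is applied.
    """
    known_genes = set(model.genes)
    known_tids = {t.transcript_id for t in model.transcripts()}
    unknown = sorted(set(gene_counts) - known_genes) + sorted(
        set(transcript_abundance) - known_tids
    )
    if unknown:
        raise KeyError(f"ids not present in the annotation: {unknown}")

    genes = {g for g, c in gene_counts.items() if c > 0}
    transcripts = {
        t.transcript_id
        for t in model.transcripts()
        if t.gene_id in genes and transcript_abundance.get(t.transcript_id, 0) > 0
    }

    introns = extract_introns(model, genome)
    by_key = {i.key: i for i in introns}
    per_donor: dict[tuple[str, int, str], Intron] = {}
    for t in model.transcripts():
        if t.transcript_id not in transcripts:
            continue
        for s, e in t.intron_intervals():
            intron = by_key[(t.chrom, s, e, t.strand)]
            dkey = (intron.chrom, intron.donor, intron.strand)
            prev = per_donor.get(dkey)
            if prev is None or intron.length < prev.length:
                per_donor[dkey] = intron
    donors = [
        DonorSite(chrom=c, pos=p, strand=st, gene_id=per_donor[(c, p, st)].gene_id,
                  intron=per_donor[(c, p, st)])
        for (c, p, st) in sorted(per_donor)
    ]
    return ExpressedSet(genes=genes, transcripts=transcripts, donors=donors)


def write_donor_bed(donors: Iterable[DonorSite], path: str | Path) -> None:
    """BED6 of donor sites (single-base intervals, 0-based half-open)."""
    with open(path, "w") as fh:
        for d in donors:
            fh.write(f"{d.chrom}\t{d.pos}\t{d.pos + 1}\t{d.gene_id}\t0\t{d.strand}\n")


def write_expressed_tsv(expressed: ExpressedSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("kind\tid\n")
        for g in sorted(expressed.genes):
            fh.write(f"gene\t{g}\n")
        for t in sorted(expressed.transcripts):
            fh.write(f"transcript\t{t}\n")
        for d in expressed.donors:
            fh.write(f"donor\t{d.chrom}:{d.pos}:{d.strand}\n")
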