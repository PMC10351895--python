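"""Synthetic genome, annotation and pre-aligned CLIP / RNA-seq read simulator.

The generator emulates the data regimes the downstream analysis assumes:
multi-exon genes with introns on both sides of 1 kb, donor sites of graded
strength realized as controlled mismatches to the donor consensus,
per-intron spliced fractions, CLIP cross-link positions at a configurable
offset upstream of donors, rRNA/snRNA contaminant reads, and a knockout
condition with intron up-regulation planted only in weak-donor introns.

Reads are emitted pre-aligned (SAM records with gapped CIGARs for spliced
molecules), so no external aligner is involved.  The cross-link nucleotide
is placed uniformly within each CLIP read, which makes the per-base coverage
kernel around a cross-link triangular and therefore puts the averaged
coverage maximum exactly at the cross-link mode — the geometry the
metaprofile analysis is meant to recover.

Every source of randomness derives from ``config.seed``; a fixed config
yields byte-identical FASTA/GTF/SAM/TSV outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import AnnotationModel, Gene, Transcript, revcomp, write_gtf
from .errors import ConfigError, SizingError
from .samio import ReadAln, write_sam

DONOR_CONSENSUS = "CAGGTAAGT"  # 3 exonic + GTAAGT
BRANCH_CONSENSUS = "TACTAAC"
ACCEPTOR_INTRONIC_PLANT = "TTTCTTTTCTTTCTTTTCAG"  # 20-mer ending in AG
#: transcript-orientation offset (nt upstream of the intron 3' end) of the
#: planted branch heptamer's last base
BRANCH_PLANT_END_OFFSET = 25

#: disjoint mismatch-position sets used when a strength class is given as a
#: plain mismatch count; disjointness across classes keeps PWM scores
#: monotone in the number of mismatches
MISMATCH_LADDER: dict[int, tuple[int, ...]] = {0: (), 1: (5,), 2: (6, 8), 3: (0, 2, 7)}

#: base substituted at a mismatched position (never the consensus base)
_ALT_BASE = {"A": "C", "C": "A", "G": "C", "T": "G"}

CONTAMINANT_LENGTHS = {"rRNA": 2000, "U1": 164, "U2": 187, "U4": 145, "U5": 116, "U6": 107}


def _default_contaminants() -> dict[str, float]:
    return {"rRNA": 0.08, "U1": 0.02, "U2": 0.012, "U4": 0.004, "U5": 0.008, "U6": 0.004}


def _default_spliced() -> dict[str, float]:
    return {"consensus": 0.95, "medium": 0.85, "weak": 0.75}


def _default_cryptic_usage() -> dict[str, float]:
    return {"WT": 0.0, "KO": 0.5}


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults are the study conditions."""

    seed: int = 1
    n_genes: int = 40
    exons_per_gene: tuple[int, int] = (2, 4)
    exon_length: tuple[int, int] = (150, 300)
    intron_length_short: tuple[int, int] = (300, 900)
    intron_length_long: tuple[int, int] = (1200, 2600)
    long_intron_fraction: float = 0.6
    genes_per_chromosome: int = 50
    gene_spacing: int = 1000
    gc_content: float = 0.45
    chromosome_length: int | None = None
    donor_strength_classes: tuple = (
        ("consensus", ()),
        ("medium", (5,)),
        ("weak", (6, 8)),
    )
    spliced_fraction: dict[str, float] = field(default_factory=_default_spliced)
    planted_intron_log2fc: float = 1.5
    planted_classes: tuple[str, ...] = ("weak",)
    planted_gene_log2fc: float = -0.5
    crosslink_offset: tuple[float, float] = (30.0, 3.0)  # (mean nt upstream, sd)
    read_length: int = 45
    n_reads_per_library: int = 20000
    contaminant_fractions: dict[str, float] = field(default_factory=_default_contaminants)
    background_fraction: float = 0.25
    bound_fraction: float = 1.0
    conditions: tuple[str, ...] = ("WT", "KO")
    ko_conditions: tuple[str, ...] = ("KO",)
    replicates_per_condition: int = 2
    cryptic_fraction: float = 0.0
    cryptic_usage: dict[str, float] = field(default_factory=_default_cryptic_usage)

    def __post_init__(self):
        self.validate()

    # -- derived -----------------------------------------------------------
    def classes(self) -> list[tuple[str, tuple[int, ...]]]:
        out = []
        for label, spec in self.donor_strength_classes:
            if isinstance(spec, int):
                if spec not in MISMATCH_LADDER:
                    raise ConfigError(
                        f"no predefined mismatch set for count {spec}; "
                        "give explicit positions"
                    )
                positions = MISMATCH_LADDER[spec]
            else:
                positions = tuple(spec)
            out.append((label, positions))
        return out

    def donor_ninemer(self, label: str) -> str:
        positions = dict(self.classes())[label]
        site = list(DONOR_CONSENSUS)
        for p in positions:
            site[p] = _ALT_BASE[site[p]]
        return "".join(site)

    def spliced_fraction_for(self, label: str, condition: str) -> float:
        p = self.spliced_fraction[label]
        if condition in self.ko_conditions and label in self.planted_classes:
            retention = min(1.0, (1.0 - p) * 2.0 ** self.planted_intron_log2fc)
            return 1.0 - retention
        return p

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")
        total = sum(self.contaminant_fractions.values())
        if total >= 1.0:
            raise ConfigError(f"contaminant fractions sum to {total} >= 1")
        if any(f < 0 for f in self.contaminant_fractions.values()):
            raise ConfigError("contaminant fractions must be nonnegative")
        for label, p in self.spliced_fraction.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"spliced fraction for {label!r} outside [0, 1]")
        for label, positions in self.classes():
            if label not in self.spliced_fraction:
                raise ConfigError(f"no spliced fraction for class {label!r}")
            if any(p in (3, 4) for p in positions):
                raise ConfigError(
                    "mismatch positions 3 and 4 would break the GT dinucleotide"
                )
            if any(not 0 <= p < len(DONOR_CONSENSUS) for p in positions):
                raise ConfigError("mismatch position outside the donor 9-mer")
        if self.read_length < 20:
            raise ConfigError("read_length must be >= 20")
        if not 0.0 <= self.background_fraction <= 1.0:
            raise ConfigError("background_fraction outside [0, 1]")
        if self.exons_per_gene[0] < 2:
            raise ConfigError("genes need at least 2 exons to contain an intron")
        for lo, hi in (self.intron_length_short, self.intron_length_long):
            if lo < 100 or hi < lo:
                raise ConfigError("intron length ranges must satisfy 100 <= lo <= hi")


# ---------------------------------------------------------------------------
# Layout and genome
# ---------------------------------------------------------------------------


@dataclass
class IntronMeta:
    index: int
    gene_id: str
    chrom: str
    strand: str
    t_start: int  # gene-local transcript-orientation first intronic base
    length: int
    label: str
    bound: bool
    cryptic_offset: int | None  # nt downstream of the annotated donor
    start: int = -1  # genomic, filled once the gene is placed
    end: int = -1
    mature_junction: int = -1  # mature coordinate of the first base after the junction

    @property
    def donor(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def cryptic_donor_genomic(self) -> int | None:
        if self.cryptic_offset is None:
            return None
        if self.strand == "+":
            return self.start + self.cryptic_offset
        return self.end - 1 - self.cryptic_offset

    @property
    def key(self) -> tuple[str, int, int, str]:
        return (self.chrom, self.start, self.end, self.strand)

    @property
    def key_str(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}:{self.strand}"


@dataclass
class GeneLayout:
    gene_id: str
    chrom: str
    strand: str
    gstart: int
    glen: int
    exon_t: list[tuple[int, int]]  # gene-local transcript orientation
    introns: list[IntronMeta]
    mature_len: int

    def local_to_genomic(self, a: int, b: int) -> tuple[int, int]:
        if self.strand == "+":
            return (self.gstart + a, self.gstart + b)
        return (self.gstart + self.glen - b, self.gstart + self.glen - a)

    def exon_genomic(self) -> list[tuple[int, int]]:
        blocks = [self.local_to_genomic(a, b) for a, b in self.exon_t]
        return sorted(blocks)


@dataclass
class Genome:
    chroms: dict[str, str]
    contaminants: dict[str, str]
    layout: list[GeneLayout]
    config: SimulationConfig

    def __getitem__(self, chrom: str) -> str:
        return self.chroms[chrom]

    def all_references(self) -> dict[str, int]:
        refs = {c: len(s) for c, s in self.chroms.items()}
        refs.update({c: len(s) for c, s in self.contaminants.items()})
        return refs


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    codes = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length, p=probs)
    return codes.tobytes().decode("ascii")


def _plant(seq: list[str], start: int, motif: str) -> None:
    for i, base in enumerate(motif):
        seq[start + i] = base


def generate_genome(config: SimulationConfig) -> Genome:
    """Build chromosome and contaminant sequences hosting the gene layout."""
    rng = np.random.default_rng([config.seed, 0])
    classes = config.classes()
    n_classes = len(classes)
    elo, ehi = config.exon_length
    layouts: list[GeneLayout] = []
    gene_seqs: list[str] = []
    intron_counter = 0
    for g in range(config.n_genes):
        gene_id = f"g{g:04d}"
        n_ex = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        exon_lens = rng.integers(elo, ehi + 1, size=n_ex)
        intron_lens = []
        metas: list[IntronMeta] = []
        for j in range(n_ex - 1):
            if rng.random() < config.long_intron_fraction:
                lo, hi = config.intron_length_long
            else:
                lo, hi = config.intron_length_short
            ilen = int(rng.integers(lo, hi + 1))
            label = classes[intron_counter % n_classes][0]
            bound = bool(rng.random() < config.bound_fraction)
            cryptic = None
            if label in config.planted_classes and rng.random() < config.cryptic_fraction:
                co_max = ilen - 50
                if co_max >= 30:
                    cryptic = int(rng.integers(30, co_max + 1))
            intron_lens.append(ilen)
            metas.append(
                IntronMeta(
                    index=intron_counter,
                    gene_id=gene_id,
                    chrom="",
                    strand="",
                    t_start=-1,
                    length=ilen,
                    label=label,
                    bound=bound,
                    cryptic_offset=cryptic,
                )
            )
            intron_counter += 1
        # gene-local transcript-orientation coordinates
        exon_t: list[tuple[int, int]] = []
        cursor = 0
        for j in range(n_ex):
            exon_t.append((cursor, cursor + int(exon_lens[j])))
            cursor += int(exon_lens[j])
            if j < n_ex - 1:
                metas[j].t_start = cursor
                cursor += intron_lens[j]
        glen = cursor
        tseq = list(_random_seq(rng, glen, config.gc_content))
        for meta in metas:
            s = meta.t_start
            _plant(tseq, s - 3, config.donor_ninemer(meta.label))
            # branch/acceptor motifs vary mildly between introns so 3'-side
            # strength features are non-degenerate across the transcriptome
            branch = list(BRANCH_CONSENSUS)
            if rng.random() < 0.5:
                p = int(rng.integers(0, len(branch)))
                branch[p] = _ALT_BASE[branch[p]]
            acceptor = list(ACCEPTOR_INTRONIC_PLANT)
            if rng.random() < 0.5:
                for p in rng.choice(16, size=2, replace=False):
                    acceptor[int(p)] = "G"
            _plant(tseq, s + meta.length - BRANCH_PLANT_END_OFFSET - len(BRANCH_CONSENSUS),
                   "".join(branch))
            _plant(tseq, s + meta.length - len(ACCEPTOR_INTRONIC_PLANT),
                   "".join(acceptor))
            if meta.cryptic_offset is not None:
                _plant(tseq, s + meta.cryptic_offset - 3, DONOR_CONSENSUS)
        strand = "+" if rng.random() < 0.5 else "-"
        tseq_str = "".join(tseq)
        gseq = tseq_str if strand == "+" else revcomp(tseq_str)
        mature = 0
        for j, (a, b) in enumerate(exon_t):
            mature += b - a
            if j < len(metas):
                metas[j].mature_junction = mature
        for meta in metas:
            meta.strand = strand
        layouts.append(
            GeneLayout(
                gene_id=gene_id,
                chrom="",
                strand=strand,
                gstart=-1,
                glen=glen,
                exon_t=exon_t,
                introns=metas,
                mature_len=mature,
            )
        )
        gene_seqs.append(gseq)

    # place genes on chromosomes with >= gene_spacing flanks
    chroms: dict[str, str] = {}
    spacing = config.gene_spacing
    per_chrom = config.genes_per_chromosome
    for c0 in range(0, config.n_genes, per_chrom):
        chrom = f"chr{c0 // per_chrom + 1}"
        parts: list[str] = []
        cursor = 0
        for g in range(c0, min(c0 + per_chrom, config.n_genes)):
            parts.append(_random_seq(rng, spacing, config.gc_content))
            cursor += spacing
            layouts[g].chrom = chrom
            layouts[g].gstart = cursor
            for meta in layouts[g].introns:
                meta.chrom = chrom
                gs, ge = layouts[g].local_to_genomic(
                    meta.t_start, meta.t_start + meta.length
                )
                meta.start, meta.end = gs, ge
            parts.append(gene_seqs[g])
            cursor += layouts[g].glen
        parts.append(_random_seq(rng, spacing, config.gc_content))
        cursor += spacing
        seq = "".join(parts)
        if config.chromosome_length is not None:
            if cursor > config.chromosome_length:
                raise SizingError(
                    f"{chrom}: genes need {cursor} nt but chromosome_length is "
                    f"{config.chromosome_length}"
                )
            seq += _random_seq(rng, config.chromosome_length - cursor, config.gc_content)
        chroms[chrom] = seq

    crng = np.random.default_rng([config.seed, 1])
    contaminants = {
        name: _random_seq(crng, length, 0.5)
        for name, length in CONTAMINANT_LENGTHS.items()
    }
    return Genome(chroms=chroms, contaminants=contaminants, layout=layouts, config=config)


def generate_annotation(config: SimulationConfig, genome: Genome) -> AnnotationModel:
    """Annotation model (one transcript per gene) matching the genome layout."""
    genes: dict[str, Gene] = {}
    for gl in genome.layout:
        tid = gl.gene_id.replace("g", "t", 1)
        gene = Gene(gene_id=gl.gene_id, chrom=gl.chrom, strand=gl.strand)
        gene.transcripts[tid] = Transcript(
            transcript_id=tid,
            gene_id=gl.gene_id,
            chrom=gl.chrom,
            strand=gl.strand,
            exons=gl.exon_genomic(),
        )
        genes[gl.gene_id] = gene
    return AnnotationModel(genes)


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Library:
    kind: str  # "clip" or "rna"
    condition: str
    replicate: int
    path: Path
    n_reads: int

    @property
    def lib_id(self) -> str:
        return f"{self.kind}_{self.condition}_rep{self.replicate}"


@dataclass
class SimulationTruth:
    """Ground truth of a simulated dataset."""

    introns: pd.DataFrame  # one row per intron
    reads: pd.DataFrame  # one row per simulated read

    def write(self, outdir: str | Path, prefix: str = "truth") -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.introns.to_csv(outdir / f"{prefix}_introns.tsv", sep="\t", index=False)
        self.reads.to_csv(outdir / f"{prefix}_reads.tsv", sep="\t", index=False)


def intron_truth_table(config: SimulationConfig, genome: Genome) -> pd.DataFrame:
    rows = []
    for gl in genome.layout:
        for meta in gl.introns:
            row = {
                "intron": meta.key_str,
                "gene_id": meta.gene_id,
                "chrom": meta.chrom,
                "start": meta.start,
                "end": meta.end,
                "strand": meta.strand,
                "length": meta.length,
                "class": meta.label,
                "bound": meta.bound,
                "donor_ninemer": config.donor_ninemer(meta.label),
                "cryptic_donor": (
                    -1 if meta.cryptic_donor_genomic is None else meta.cryptic_donor_genomic
                ),
                "planted_log2fc": (
                    config.planted_intron_log2fc if meta.label in config.planted_classes else 0.0
                ),
            }
            for cond in config.conditions:
                row[f"spliced_{cond}"] = config.spliced_fraction_for(meta.label, cond)
            rows.append(row)
    return pd.DataFrame(rows)


def _blocks_from_molecule(
    gl: GeneLayout, segments: list[tuple[int, int]], start: int, length: int
) -> tuple[tuple[int, int], ...]:
    """Map a molecule-coordinate interval to sorted genomic blocks."""
    local: list[tuple[int, int]] = []
    offset = 0
    remaining_start, remaining_end = start, start + length
    for a, b in segments:
        seg_len = b - a
        lo = max(remaining_start - offset, 0)
        hi = min(remaining_end - offset, seg_len)
        if hi > lo:
            la, lb = a + lo, a + hi
            if local and local[-1][1] == la:
                local[-1] = (local[-1][0], lb)
            else:
                local.append((la, lb))
        offset += seg_len
    blocks = [gl.local_to_genomic(a, b) for a, b in local]
    blocks.sort()
    merged: list[tuple[int, int]] = []
    for bs, be in blocks:
        if merged and merged[-1][1] == bs:
            merged[-1] = (merged[-1][0], be)
        else:
            merged.append((bs, be))
    return tuple(merged)


def _mature_segments(
    gl: GeneLayout, retained: Sequence[bool] | None = None,
    cryptic_used: Sequence[bool] | None = None,
) -> list[tuple[int, int]]:
    """Molecule segment list in gene-local transcript orientation."""
    segments: list[tuple[int, int]] = []
    for j, (a, b) in enumerate(gl.exon_t):
        if segments and segments[-1][1] == a:
            segments[-1] = (segments[-1][0], b)
        else:
            segments.append((a, b))
        if j < len(gl.introns):
            meta = gl.introns[j]
            if retained is not None and retained[j]:
                segments[-1] = (segments[-1][0], b + meta.length)
            elif cryptic_used is not None and cryptic_used[j] and meta.cryptic_offset:
                segments[-1] = (segments[-1][0], b + meta.cryptic_offset)
    return segments


def _seq_for_blocks(chrom_seq: str, blocks: Sequence[tuple[int, int]]) -> str:
    return "".join(chrom_seq[s:e] for s, e in blocks)


def _contaminant_counts(
    rng: np.random.Generator, config: SimulationConfig, n: int
) -> tuple[dict[str, int], int]:
    names = sorted(config.contaminant_fractions)
    probs = [config.contaminant_fractions[n_] for n_ in names]
    probs.append(1.0 - sum(probs))
    counts = rng.multinomial(n, probs)
    return dict(zip(names, counts[:-1].tolist())), int(counts[-1])


def _library_list(config: SimulationConfig) -> list[tuple[str, int]]:
    return [
        (cond, rep)
        for cond in config.conditions
        for rep in range(1, config.replicates_per_condition + 1)
    ]


def simulate_clip_reads(
    config: SimulationConfig,
    genome: Genome,
    annotation: AnnotationModel | None = None,
    outdir: str | Path = ".",
    prefix: str = "clip",
) -> tuple[list[Library], SimulationTruth]:
    """Simulate cross-link-anchored CLIP libraries as pre-aligned SAM files.

    Gene-derived reads either target the donor of a bound intron (cross-link
    drawn from the configured offset distribution, spliced or unspliced
    according to the per-class spliced fraction) or form a uniform gene-body
    background; the rest are contaminant reads on the rRNA/snRNA references.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    refs = genome.all_references()
    L = config.read_length
    mean_up, sd = config.crosslink_offset
    bound = [
        (gl, j)
        for gl in genome.layout
        for j in range(len(gl.introns))
        if gl.introns[j].bound
    ]
    libraries: list[Library] = []
    read_rows: list[dict] = []
    for lib_index, (cond, rep) in enumerate(_library_list(config)):
        rng = np.random.default_rng([config.seed, 100 + lib_index])
        lib_id = f"{prefix}_{cond}_rep{rep}"
        path = outdir / f"{lib_id}.sam"
        records: list[tuple[ReadAln, str]] = []
        contam_counts, n_gene = _contaminant_counts(rng, config, config.n_reads_per_library)
        i = 0
        for name in sorted(contam_counts):
            ref_seq = genome.contaminants[name]
            for _ in range(contam_counts[name]):
                pos = int(rng.integers(0, len(ref_seq) - L + 1))
                aln = ReadAln(
                    name=f"{lib_id}_{i:07d}",
                    chrom=name,
                    strand="+",
                    blocks=((pos, pos + L),),
                    mapq=255,
                    nm=0,
                    tags={"XT": name, "XC": "contaminant"},
                )
                records.append((aln, ref_seq[pos : pos + L]))
                read_rows.append(
                    {"library": lib_id, "name": aln.name, "origin": name,
                     "status": "contaminant", "crosslink_offset": np.nan,
                     "condition": cond, "replicate": rep}
                )
                i += 1
        n_background = int(rng.binomial(n_gene, config.background_fraction)) if bound else n_gene
        n_targeted = n_gene - n_background
        # donor-targeted reads
        for _ in range(n_targeted):
            gl, j = bound[int(rng.integers(0, len(bound)))]
            meta = gl.introns[j]
            p_spliced = config.spliced_fraction_for(meta.label, cond)
            spliced = bool(rng.random() < p_spliced)
            c = -int(np.round(rng.normal(mean_up, sd)))
            u = int(rng.integers(0, L))
            chrom_seq = genome.chroms[gl.chrom]
            if spliced:
                use_cryptic = (
                    meta.cryptic_offset is not None
                    and rng.random() < config.cryptic_usage.get(cond, 0.0)
                )
                cryptic_used = [False] * len(gl.introns)
                cryptic_used[j] = use_cryptic
                segments = _mature_segments(gl, cryptic_used=cryptic_used)
                junction = meta.mature_junction + (
                    meta.cryptic_offset if use_cryptic else 0
                )
                mol_len = sum(b - a for a, b in segments)
                xl = junction + min(c, -1)
                start = min(max(xl - u, 0), mol_len - L)
                blocks = _blocks_from_molecule(gl, segments, start, L)
                status = "spliced_cryptic" if use_cryptic else "spliced"
            else:
                p0 = meta.t_start + c - u
                p0 = min(max(p0, 0), gl.glen - L)
                blocks = _blocks_from_molecule(gl, [(0, gl.glen)], p0, L)
                status = "unspliced"
            aln = ReadAln(
                name=f"{lib_id}_{i:07d}",
                chrom=gl.chrom,
                strand=gl.strand,
                blocks=blocks,
                mapq=255,
                nm=0,
                tags={"XT": meta.key_str, "XC": status},
            )
            records.append((aln, _seq_for_blocks(chrom_seq, blocks)))
            read_rows.append(
                {"library": lib_id, "name": aln.name, "origin": meta.key_str,
                 "status": status, "crosslink_offset": c,
                 "condition": cond, "replicate": rep}
            )
            i += 1
        # uniform gene-body background
        for _ in range(n_background):
            gl = genome.layout[int(rng.integers(0, len(genome.layout)))]
            p0 = int(rng.integers(0, gl.glen - L + 1))
            blocks = _blocks_from_molecule(gl, [(0, gl.glen)], p0, L)
            aln = ReadAln(
                name=f"{lib_id}_{i:07d}",
                chrom=gl.chrom,
                strand=gl.strand,
                blocks=blocks,
                mapq=255,
                nm=0,
                tags={"XT": gl.gene_id, "XC": "background"},
            )
            records.append((aln, _seq_for_blocks(genome.chroms[gl.chrom], blocks)))
            read_rows.append(
                {"library": lib_id, "name": aln.name, "origin": gl.gene_id,
                 "status": "background", "crosslink_offset": np.nan,
                 "condition": cond, "replicate": rep}
            )
            i += 1
        write_sam(path, refs, records)
        libraries.append(
            Library(kind="clip", condition=cond, replicate=rep, path=path, n_reads=i)
        )
    truth = SimulationTruth(
        introns=intron_truth_table(config, genome),
        reads=pd.DataFrame(read_rows),
    )
    return libraries, truth


def simulate_rnaseq_reads(
    config: SimulationConfig,
    genome: Genome,
    annotation: AnnotationModel | None = None,
    outdir: str | Path = ".",
    prefix: str = "rna",
) -> tuple[list[Library], SimulationTruth]:
    """Simulate RNA-seq libraries with uniform coverage along each molecule.

    Each gene read samples a molecule: every intron is independently retained
    with its condition-specific retention probability (the planted log2
    fold-change inflates retention of planted-class introns in knockout
    conditions), spliced introns may use a planted cryptic donor, and the
    read position is uniform along the resulting molecule.  Genes hosting
    planted introns are down-weighted in knockout conditions by
    ``planted_gene_log2fc``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    refs = genome.all_references()
    L = config.read_length
    layouts = genome.layout
    planted_gene = np.array(
        [
            any(m.label in config.planted_classes for m in gl.introns)
            for gl in layouts
        ]
    )
    libraries: list[Library] = []
    read_rows: list[dict] = []
    for lib_index, (cond, rep) in enumerate(_library_list(config)):
        rng = np.random.default_rng([config.seed, 500 + lib_index])
        lib_id = f"{prefix}_{cond}_rep{rep}"
        path = outdir / f"{lib_id}.sam"
        weights = np.ones(len(layouts))
        if cond in config.ko_conditions:
            weights[planted_gene] *= 2.0 ** config.planted_gene_log2fc
        weights /= weights.sum()
        records: list[tuple[ReadAln, str]] = []
        contam_counts, n_gene = _contaminant_counts(rng, config, config.n_reads_per_library)
        i = 0
        for name in sorted(contam_counts):
            ref_seq = genome.contaminants[name]
            for _ in range(contam_counts[name]):
                pos = int(rng.integers(0, len(ref_seq) - L + 1))
                aln = ReadAln(
                    name=f"{lib_id}_{i:07d}",
                    chrom=name,
                    strand="+",
                    blocks=((pos, pos + L),),
                    mapq=255,
                    nm=0,
                    tags={"XT": name, "XC": "contaminant"},
                )
                records.append((aln, ref_seq[pos : pos + L]))
                read_rows.append(
                    {"library": lib_id, "name": aln.name, "origin": name,
                     "status": "contaminant", "condition": cond, "replicate": rep}
                )
                i += 1
        gene_draws = rng.choice(len(layouts), size=n_gene, p=weights)
        for gidx in gene_draws:
            gl = layouts[int(gidx)]
            n_int = len(gl.introns)
            retained = [False] * n_int
            cryptic_used = [False] * n_int
            for j, meta in enumerate(gl.introns):
                p_spliced = config.spliced_fraction_for(meta.label, cond)
                if rng.random() >= p_spliced:
                    retained[j] = True
                elif (
                    meta.cryptic_offset is not None
                    and rng.random() < config.cryptic_usage.get(cond, 0.0)
                ):
                    cryptic_used[j] = True
            segments = _mature_segments(gl, retained=retained, cryptic_used=cryptic_used)
            mol_len = sum(b - a for a, b in segments)
            start = int(rng.integers(0, mol_len - L + 1))
            blocks = _blocks_from_molecule(gl, segments, start, L)
            status = (
                "retained" if any(retained)
                else ("spliced_cryptic" if any(cryptic_used) else "spliced")
            )
            aln = ReadAln(
                name=f"{lib_id}_{i:07d}",
                chrom=gl.chrom,
                strand=gl.strand,
                blocks=blocks,
                mapq=255,
                nm=0,
                tags={"XT": gl.gene_id, "XC": status},
            )
            records.append((aln, _seq_for_blocks(genome.chroms[gl.chrom], blocks)))
            read_rows.append(
                {"library": lib_id, "name": aln.name, "origin": gl.gene_id,
                 "status": status, "condition": cond, "replicate": rep}
            )
            i += 1
        write_sam(path, refs, records)
        libraries.append(
            Library(kind="rna", condition=cond, replicate=rep, path=path, n_reads=i)
        )
    truth = SimulationTruth(
        introns=intron_truth_table(config, genome),
        reads=pd.DataFrame(read_rows),
    )
    return libraries, truth


# ---------------------------------------------------------------------------
# Convenience: full dataset with on-disk artifacts
# ---------------------------------------------------------------------------


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def simulate_dataset(config: SimulationConfig, outdir: str | Path) -> dict:
    """Generate genome, annotation, CLIP + RNA libraries and truth files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = generate_genome(config)
    model = generate_annotation(config, genome)
    write_fasta(genome.chroms, outdir / "genome.fa")
    write_fasta(genome.contaminants, outdir / "contaminants.fa")
    write_gtf(model, outdir / "annotation.gtf")
    clip_libs, clip_truth = simulate_clip_reads(
        config, genome, model, outdir / "clip", prefix="clip"
    )
    rna_libs, rna_truth = simulate_rnaseq_reads(
        config, genome, model, outdir / "rna", prefix="rna"
    )
    clip_truth.write(outdir / "truth", prefix="clip")
    rna_truth.write(outdir / "truth", prefix="rna")
    return {
        "genome": genome,
        "annotation": model,
        "clip_libraries": clip_libs,
        "rna_libraries": rna_libs,
        "clip_truth": clip_truth,
        "rna_truth": rna_truth,
    }
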