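"""Shared helpers for the test suite."""

from __future__ import annotations

from clipsplice.annotation import DonorSite, Intron
from clipsplice.samio import ReadAln


def mk_read(
    chrom: str,
    blocks,
    strand: str = "+",
    name: str = "r",
    mapq: int = 255,
    nm: int | None = 0,
) -> ReadAln:
    return ReadAln(
        name=name,
        chrom=chrom,
        strand=strand,
        blocks=tuple(tuple(b) for b in blocks),
        mapq=mapq,
        nm=nm,
    )


def mk_intron(
    chrom="chr1", start=1000, end=2200, strand="+", gene_id="gX", tids=("tX",), gc=0.5
) -> Intron:
    return Intron(
        chrom=chrom,
        start=start,
        end=end,
        strand=strand,
        gene_id=gene_id,
        transcript_ids=tuple(tids),
        gc=gc,
    )


def donors_from_introns(introns) -> list[DonorSite]:
    per = {}
    for i in introns:
        key = (i.chrom, i.donor, i.strand)
        if key not in per or i.length < per[key].intron.length:
            per[key] = DonorSite(i.chrom, i.donor, i.strand, i.gene_id, i)
    return [per[k] for k in sorted(per)]


def intron_key(i) -> str:
    return f"{i.chrom}:{i.start}-{i.end}:{i.strand}"
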