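"""Spliced/unspliced classification at donors and novel splice-site detection.

A donor-overlapping read is *spliced* when it carries a junction gap whose
edges coincide exactly with an annotated intron, *unspliced* when it is a
contiguous alignment crossing the exon|intron boundary with at least ``k``
aligned nt on each side (k = 5 by default, guarding against alignment-edge
artifacts), and ignored otherwise.  Novel (cryptic) splice sites are gaps
sharing one annotated edge of an intron but not the other; events are tested
per intron with a 2x2 Fisher test across conditions and Benjamini-Hochberg
correction.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotation import Intron
from .errors import ConfigError
from .samio import ReadAln


# ---------------------------------------------------------------------------
# Spliced / unspliced classification
# ---------------------------------------------------------------------------


def classify_donor_reads(
    reads: Iterable[ReadAln],
    intron: Intron,
    min_overhang: int = 5,
    match_strand: bool = True,
) -> tuple[int, int]:
    """Count (spliced, unspliced) reads at one intron's donor.

    See the module docstring for the classification rule; each read falls in
    exactly one of {spliced, unspliced, ignored}.
    """
    spliced = 0
    unspliced = 0
    for read in reads:
        if read.chrom != intron.chrom:
            continue
        if match_strand and read.strand != intron.strand:
            continue
        if read.is_spliced:
            if (intron.start, intron.end) in read.gaps():
                spliced += 1
        else:
            s, e = read.blocks[0]
            if intron.strand == "+":
                # exon side upstream of intron.start
                if s <= intron.start - min_overhang and e >= intron.start + min_overhang:
                    unspliced += 1
            else:
                boundary = intron.end  # first exonic base is intron.end
                if s <= boundary - min_overhang and e >= boundary + min_overhang:
                    unspliced += 1
    return spliced, unspliced


def classify_junction_reads(
    reads_by_library: Mapping[str, Sequence[ReadAln]],
    introns: Sequence[Intron],
    min_overhang: int = 5,
    match_strand: bool = True,
) -> pd.DataFrame:
    """Per-intron, per-library spliced/unspliced counts (long format).

    Equivalent to running :func:`classify_donor_reads` per intron but in one
    pass over the reads.
    """
    by_gap: dict[tuple[str, str, int, int], int] = {}
    donors_by_cs: dict[tuple[str, str], list[tuple[int, int]]] = defaultdict(list)
    for idx, intron in enumerate(introns):
        by_gap[(intron.chrom, intron.strand, intron.start, intron.end)] = idx
        boundary = intron.start if intron.strand == "+" else intron.end
        donors_by_cs[(intron.chrom, intron.strand)].append((boundary, idx))
    donor_arrays = {
        key: (np.array([b for b, _ in sorted(vals)]), [i for _, i in sorted(vals)])
        for key, vals in donors_by_cs.items()
    }
    rows: list[dict] = []
    for lib, reads in reads_by_library.items():
        spliced = np.zeros(len(introns), dtype=np.int64)
        unspliced = np.zeros(len(introns), dtype=np.int64)
        for read in reads:
            for key_strand in ((read.strand,) if match_strand else ("+", "-")):
                if read.is_spliced:
                    for gs, ge in read.gaps():
                        idx = by_gap.get((read.chrom, key_strand, gs, ge))
                        if idx is not None:
                            spliced[idx] += 1
                else:
                    arr = donor_arrays.get((read.chrom, key_strand))
                    if arr is None:
                        continue
                    positions, idxs = arr
                    s, e = read.blocks[0]
                    lo = np.searchsorted(positions, s + min_overhang, side="left")
                    hi = np.searchsorted(positions, e - min_overhang, side="right")
                    for j in range(lo, hi):
                        unspliced[idxs[j]] += 1
        for idx, intron in enumerate(introns):
            rows.append(
                {
                    "intron": f"{intron.chrom}:{intron.start}-{intron.end}:{intron.strand}",
                    "library": lib,
                    "spliced": int(spliced[idx]),
                    "unspliced": int(unspliced[idx]),
                }
            )
    return pd.DataFrame(rows)


def region_read_totals(
    reads_by_library: Mapping[str, Sequence[ReadAln]],
    introns: Sequence[Intron],
    flank: int = 100,
    match_strand: bool = True,
) -> pd.Series:
    """Reads overlapping the +/-``flank`` window around each donor, summed
    over all libraries."""
    donors_by_cs: dict[tuple[str, str], list[tuple[int, int]]] = defaultdict(list)
    for idx, intron in enumerate(introns):
        donors_by_cs[(intron.chrom, intron.strand)].append((intron.donor, idx))
    donor_arrays = {
        key: (np.array([p for p, _ in sorted(vals)]), [i for _, i in sorted(vals)])
        for key, vals in donors_by_cs.items()
    }
    totals = np.zeros(len(introns), dtype=np.int64)
    for reads in reads_by_library.values():
        for read in reads:
            for key_strand in ((read.strand,) if match_strand else ("+", "-")):
                arr = donor_arrays.get((read.chrom, key_strand))
                if arr is None:
                    continue
                positions, idxs = arr
                # read [s,e) overlaps window [p-flank, p+flank+1)
                lo = np.searchsorted(positions, read.start - flank, side="left")
                hi = np.searchsorted(positions, read.end + flank, side="right")
                for j in range(lo, hi):
                    p = positions[j]
                    if read.start < p + flank + 1 and read.end > p - flank:
                        totals[idxs[j]] += 1
    index = [f"{i.chrom}:{i.start}-{i.end}:{i.strand}" for i in introns]
    return pd.Series(totals, index=index, name="region_reads")


def junction_ratio_table(
    counts: pd.DataFrame,
    introns: Sequence[Intron],
    region_totals: pd.Series | None = None,
    min_intron_length: int = 1000,
    min_region_reads: int = 50,
    min_count: int = 10,
    count_rule: str = "both",
) -> pd.DataFrame:
    """Filtered per-donor spliced/unspliced ratio table.

    Counts are summed over libraries.  A donor is excluded when its intron is
    not longer than ``min_intron_length``, when fewer than
    ``min_region_reads`` reads fall in the +/-100 bp window over all samples,
    or when its spliced/unspliced totals fail the ``> min_count`` rule
    (``count_rule="both"`` requires both counts above the threshold,
    ``"either"`` accepts one).  Survivors carry log2(spliced/unspliced).
    """
    if count_rule not in ("both", "either"):
        raise ConfigError(f"unknown count_rule {count_rule!r}")
    lengths = {
        f"{i.chrom}:{i.start}-{i.end}:{i.strand}": i.length for i in introns
    }
    agg = counts.groupby("intron")[["spliced", "unspliced"]].sum()
    agg["length"] = [lengths[k] for k in agg.index]
    agg["region_reads"] = (
        region_totals.reindex(agg.index).fillna(0).astype(int)
        if region_totals is not None
        else agg["spliced"] + agg["unspliced"]
    )
    agg["pass_length"] = agg["length"] > min_intron_length
    agg["pass_region"] = agg["region_reads"] >= min_region_reads
    if count_rule == "both":
        agg["pass_counts"] = (agg["spliced"] > min_count) & (agg["unspliced"] > min_count)
    else:
        agg["pass_counts"] = (agg["spliced"] > min_count) | (agg["unspliced"] > min_count)
    agg["kept"] = agg["pass_length"] & agg["pass_region"] & agg["pass_counts"]
    with np.errstate(divide="ignore", invalid="ignore"):
        agg["log2_ratio"] = np.where(
            (agg["spliced"] > 0) & (agg["unspliced"] > 0),
            np.log2(agg["spliced"] / agg["unspliced"]),
            np.nan,
        )
    return agg


# ---------------------------------------------------------------------------
# Novel splice-site (cryptic donor/acceptor, retained intron) detection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NovelDonorEvent:
    intron: str
    event_class: str  # "novel_5ss" | "novel_3ss" | "retained_intron"
    position: int  # novel junction edge (first/last intronic base); -1 for RI
    counts: tuple[int, int, int, int]  # novel_alt, annot_alt, novel_ref, annot_ref
    inclusion_ref: float
    inclusion_alt: float
    inclusion_difference: float
    pvalue: float
    fdr: float


def collect_junction_evidence(
    reads_by_library: Mapping[str, Sequence[ReadAln]],
    library_condition: Mapping[str, str],
    introns: Sequence[Intron],
) -> pd.DataFrame:
    """Tally junction gaps per condition against the annotated introns.

    Returns one row per (intron, event class, position) carrying alternative
    and annotated junction read counts per condition.  Positions of novel
    edges are the first (5') or last (3') intronic base of the observed gap,
    in transcript orientation.
    """
    conditions = sorted(set(library_condition.values()))
    by_key = {}
    for intron in introns:
        by_key[(intron.chrom, intron.strand, intron.start, intron.end)] = intron
    start_index: dict[tuple[str, str, int], list[Intron]] = defaultdict(list)
    end_index: dict[tuple[str, str, int], list[Intron]] = defaultdict(list)
    for intron in introns:
        start_index[(intron.chrom, intron.strand, intron.start)].append(intron)
        end_index[(intron.chrom, intron.strand, intron.end)].append(intron)

    annotated: dict[tuple[str, str], int] = defaultdict(int)  # (intron, cond)
    novel: dict[tuple[str, str, str, int], int] = defaultdict(int)
    for lib, reads in reads_by_library.items():
        if lib not in library_condition:
            raise ConfigError(f"library {lib!r} has no condition label")
        cond = library_condition[lib]
        for read in reads:
            if not read.is_spliced:
                continue
            for gs, ge in read.gaps():
                intron = by_key.get((read.chrom, read.strand, gs, ge))
                if intron is not None:
                    key = f"{intron.chrom}:{intron.start}-{intron.end}:{intron.strand}"
                    annotated[(key, cond)] += 1
                    continue
                # shared 3' edge, novel 5' edge (and vice versa), strandwise
                for host in end_index.get((read.chrom, read.strand, ge), []):
                    key = f"{host.chrom}:{host.start}-{host.end}:{host.strand}"
                    if host.strand == "+":
                        novel[(key, "novel_5ss", cond, gs)] += 1
                    else:
                        novel[(key, "novel_3ss", cond, gs)] += 1
                for host in start_index.get((read.chrom, read.strand, gs), []):
                    key = f"{host.chrom}:{host.start}-{host.end}:{host.strand}"
                    if host.strand == "+":
                        novel[(key, "novel_3ss", cond, ge - 1)] += 1
                    else:
                        novel[(key, "novel_5ss", cond, ge - 1)] += 1
    rows = []
    events = sorted({(k[0], k[1], k[3]) for k in novel})
    for intron_key, event_class, pos in events:
        row = {"intron": intron_key, "event_class": event_class, "position": pos}
        for cond in conditions:
            row[f"alt_{cond}"] = novel.get((intron_key, event_class, cond, pos), 0)
            row[f"annot_{cond}"] = annotated.get((intron_key, cond), 0)
        rows.append(row)
    columns = ["intron", "event_class", "position"]
    for cond in conditions:
        columns += [f"alt_{cond}", f"annot_{cond}"]
    return pd.DataFrame(rows, columns=columns)


def retained_intron_evidence(
    counts: pd.DataFrame, library_condition: Mapping[str, str]
) -> pd.DataFrame:
    """Retained-intron evidence rows from per-library spliced/unspliced counts.

    The unspliced count plays the role of the alternative junction.
    """
    df = counts.copy()
    df["condition"] = df["library"].map(library_condition)
    agg = df.groupby(["intron", "condition"])[["spliced", "unspliced"]].sum().unstack()
    rows = []
    conditions = sorted(set(library_condition.values()))
    for intron_key, r in agg.iterrows():
        row = {"intron": intron_key, "event_class": "retained_intron", "position": -1}
        for cond in conditions:
            row[f"alt_{cond}"] = int(r.get(("unspliced", cond), 0))
            row[f"annot_{cond}"] = int(r.get(("spliced", cond), 0))
        rows.append(row)
    return pd.DataFrame(rows)


def call_splice_events(
    evidence: pd.DataFrame,
    ref_condition: str,
    alt_condition: str,
    min_total_reads: int = 30,
    min_inclusion_difference: float = 0.1,
    fdr_threshold: float = 0.01,
) -> list[NovelDonorEvent]:
    """Test evidence rows and keep significant events.

    Events need more than ``min_total_reads`` reads across all samples to be
    tested; kept events satisfy BH FDR < ``fdr_threshold`` and an inclusion
    level difference > ``min_inclusion_difference``.
    """
    if evidence.empty:
        return []
    na, aa = f"alt_{alt_condition}", f"annot_{alt_condition}"
    nr, ar = f"alt_{ref_condition}", f"annot_{ref_condition}"
    for col in (na, aa, nr, ar):
        if col not in evidence.columns:
            raise ConfigError(f"evidence lacks column {col!r}; both conditions required")
    ev = evidence.copy()
    ev["total"] = ev[na] + ev[aa] + ev[nr] + ev[ar]
    ev = ev[ev["total"] > min_total_reads]
    if ev.empty:
        return []
    pvals = np.array(
        [
            stats.fisher_exact([[r[na], r[aa]], [r[nr], r[ar]]])[1]
            for _, r in ev.iterrows()
        ]
    )
    _, fdr, _, _ = multipletests(pvals, method="fdr_bh")
    out: list[NovelDonorEvent] = []
    for (idx, r), p, q in zip(ev.iterrows(), pvals, fdr):
        inc_alt = r[na] / (r[na] + r[aa]) if (r[na] + r[aa]) > 0 else np.nan
        inc_ref = r[nr] / (r[nr] + r[ar]) if (r[nr] + r[ar]) > 0 else np.nan
        dincl = inc_alt - inc_ref
        if q < fdr_threshold and abs(dincl) > min_inclusion_difference:
            out.append(
                NovelDonorEvent(
                    intron=r["intron"],
                    event_class=r["event_class"],
                    position=int(r["position"]),
                    counts=(int(r[na]), int(r[aa]), int(r[nr]), int(r[ar])),
                    inclusion_ref=float(inc_ref),
                    inclusion_alt=float(inc_alt),
                    inclusion_difference=float(dincl),
                    pvalue=float(p),
                    fdr=float(q),
                )
            )
    return out


def detect_novel_donors(
    reads_by_library: Mapping[str, Sequence[ReadAln]],
    library_condition: Mapping[str, str],
    introns: Sequence[Intron],
    ref_condition: str,
    alt_condition: str,
    include_retained: bool = True,
    min_overhang: int = 5,
    min_total_reads: int = 30,
    min_inclusion_difference: float = 0.1,
    fdr_threshold: float = 0.01,
) -> list[NovelDonorEvent]:
    """End-to-end cryptic splice-site and retained-intron event detection."""
    conditions = set(library_condition.values())
    if len(conditions) < 2:
        raise ConfigError("novel-event detection requires at least two conditions")
    evidence = collect_junction_evidence(reads_by_library, library_condition, introns)
    frames = [evidence]
    if include_retained:
        counts = classify_junction_reads(reads_by_library, introns, min_overhang)
        frames.append(retained_intron_evidence(counts, library_condition))
    all_ev = pd.concat([f for f in frames if not f.empty], ignore_index=True) \
        if any(not f.empty for f in frames) else pd.DataFrame()
    return call_splice_events(
        all_ev,
        ref_condition,
        alt_condition,
        min_total_reads=min_total_reads,
        min_inclusion_difference=min_inclusion_difference,
        fdr_threshold=fdr_threshold,
    )


def write_events_tsv(events: Sequence[NovelDonorEvent], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "intron\tevent_class\tposition\talt_alt\tannot_alt\talt_ref\tannot_ref"
            "\tinclusion_ref\tinclusion_alt\tinclusion_difference\tpvalue\tfdr\n"
        )
        for e in events:
            fh.write(
                f"{e.intron}\t{e.event_class}\t{e.position}\t"
                + "\t".join(str(c) for c in e.counts)
                + f"\t{e.inclusion_ref:.6g}\t{e.inclusion_alt:.6g}"
                f"\t{e.inclusion_difference:.6g}\t{e.pvalue:.6g}\t{e.fdr:.6g}\n"
            )


def write_novel_donor_bed(events: Sequence[NovelDonorEvent], path: str | Path) -> None:
    with open(path, "w") as fh:
        for e in events:
            if e.event_class != "novel_5ss" or e.position < 0:
                continue
            chrom = e.intron.split(":")[0]
            strand = e.intron.rsplit(":", 1)[1]
            fh.write(
                f"{chrom}\t{e.position}\t{e.position + 1}\t{e.event_class}\t0\t{strand}\n"
            )
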