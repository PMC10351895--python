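"""Candidate peak calling, replicate-reproducibility filtering and targets.

Candidate calling is deliberately simple — maximal runs of per-base coverage
at or above a threshold — because the discriminating layer is the filter:
a candidate is kept only if it overlaps a candidate of the other replicate,
is wider than 35 nt, and has more than 5 reads (both replicates combined)
in the 50-bp window around its center.  Overlapping kept candidates are
reported as union intervals.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .annotation import DonorSite
from .errors import ConfigError
from .samio import ReadAln


@dataclass(frozen=True)
class Peak:
    chrom: str
    strand: str
    start: int
    end: int
    center: int  # position of maximum coverage, ties -> leftmost
    replicate_support: int = 1
    window_reads: int = -1  # combined reads in +/-25 bp of center; -1 = unset

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Peak") -> bool:
        return (
            self.chrom == other.chrom
            and self.strand == other.strand
            and self.start < other.end
            and other.start < self.end
        )


def build_coverage(
    reads: Iterable[ReadAln],
    reference_lengths: Mapping[str, int],
    unique_only: bool = True,
    min_mapq: int = 255,
) -> dict[tuple[str, str], np.ndarray]:
    """Per-base stranded coverage tracks keyed by (chromosome, strand)."""
    tracks: dict[tuple[str, str], np.ndarray] = {}
    for read in reads:
        if unique_only and read.mapq < min_mapq:
            continue
        key = (read.chrom, read.strand)
        if key not in tracks:
            if read.chrom not in reference_lengths:
                continue
            tracks[key] = np.zeros(reference_lengths[read.chrom], dtype=np.int64)
        track = tracks[key]
        for s, e in read.blocks:
            track[max(s, 0) : min(e, len(track))] += 1
    return tracks


def call_candidate_peaks(
    track: np.ndarray,
    chrom: str,
    strand: str,
    min_height: float | None = None,
    min_width: int = 1,
) -> list[Peak]:
    """Maximal runs of coverage >= ``min_height`` as peak candidates.

    The default threshold is the 90th percentile of the track's nonzero
    coverage.  Centers are the position of maximum coverage within the run,
    leftmost on ties.
    """
    track = np.asarray(track)
    nonzero = track[track > 0]
    if nonzero.size == 0:
        return []
    if min_height is None:
        min_height = float(np.quantile(nonzero, 0.9))
    above = track >= min_height
    if not above.any():
        return []
    edges = np.flatnonzero(np.diff(above.astype(np.int8)))
    starts = list(np.flatnonzero(above[1:] & ~above[:-1]) + 1)
    if above[0]:
        starts.insert(0, 0)
    ends = list(np.flatnonzero(~above[1:] & above[:-1]) + 1)
    if above[-1]:
        ends.append(len(track))
    peaks = []
    for s, e in zip(starts, ends):
        if e - s < min_width:
            continue
        center = s + int(np.argmax(track[s:e]))
        peaks.append(Peak(chrom=chrom, strand=strand, start=s, end=e, center=center))
    return peaks


def call_candidates_all(
    tracks: Mapping[tuple[str, str], np.ndarray],
    min_height: float | None = None,
    min_width: int = 1,
) -> list[Peak]:
    out: list[Peak] = []
    for (chrom, strand) in sorted(tracks):
        out.extend(
            call_candidate_peaks(tracks[(chrom, strand)], chrom, strand, min_height, min_width)
        )
    return out


def count_reads_in_window(
    reads: Sequence[ReadAln], chrom: str, strand: str, center: int, half: int = 25
) -> int:
    """Reads overlapping [center - half, center + half) by at least 1 nt."""
    lo, hi = center - half, center + half
    return sum(
        1
        for r in reads
        if r.chrom == chrom and r.strand == strand and r.start < hi and r.end > lo
    )


def filter_reproducible(
    candidates_rep1: Sequence[Peak],
    candidates_rep2: Sequence[Peak],
    reads_rep1: Sequence[ReadAln],
    reads_rep2: Sequence[ReadAln],
    min_width: int = 35,
    min_window_reads: int = 5,
    window_half: int = 25,
) -> list[Peak]:
    """Apply the reproducibility filters and merge surviving candidates.

    A candidate passes when it (a) overlaps >= 1 bp a candidate of the other
    replicate, (b) is strictly wider than ``min_width``, and (c) has strictly
    more than ``min_window_reads`` reads from both replicates combined within
    +/-``window_half`` bp of its own center.  Passing candidates from both
    replicates that overlap are merged into union intervals; the merged
    center is the combined-coverage maximum inside the union.
    """
    combined_reads = list(reads_rep1) + list(reads_rep2)

    def passes(peak: Peak, others: Sequence[Peak]) -> bool:
        if peak.width <= min_width:
            return False
        if not any(peak.overlaps(o) for o in others):
            return False
        n = count_reads_in_window(
            combined_reads, peak.chrom, peak.strand, peak.center, window_half
        )
        return n > min_window_reads

    kept = [p for p in candidates_rep1 if passes(p, candidates_rep2)]
    kept += [p for p in candidates_rep2 if passes(p, candidates_rep1)]
    if not kept:
        return []
    # merge overlapping kept candidates (union intervals)
    merged: list[Peak] = []
    by_group: dict[tuple[str, str], list[Peak]] = defaultdict(list)
    for p in kept:
        by_group[(p.chrom, p.strand)].append(p)
    for (chrom, strand) in sorted(by_group):
        group = sorted(by_group[(chrom, strand)], key=lambda p: (p.start, p.end))
        cur_start, cur_end, support = group[0].start, group[0].end, 1
        members = [group[0]]
        for p in group[1:]:
            if p.start < cur_end:
                cur_end = max(cur_end, p.end)
                members.append(p)
            else:
                merged.append(
                    _merged_peak(chrom, strand, cur_start, cur_end, members, combined_reads,
                                 window_half)
                )
                cur_start, cur_end, members = p.start, p.end, [p]
        merged.append(
            _merged_peak(chrom, strand, cur_start, cur_end, members, combined_reads,
                         window_half)
        )
    return merged


def _merged_peak(
    chrom: str,
    strand: str,
    start: int,
    end: int,
    members: Sequence[Peak],
    combined_reads: Sequence[ReadAln],
    window_half: int,
) -> Peak:
    cov = np.zeros(end - start, dtype=np.int64)
    for r in combined_reads:
        if r.chrom != chrom or r.strand != strand:
            continue
        for bs, be in r.blocks:
            lo, hi = max(bs, start), min(be, end)
            if hi > lo:
                cov[lo - start : hi - start] += 1
    center = start + int(np.argmax(cov))
    n = count_reads_in_window(combined_reads, chrom, strand, center, window_half)
    return Peak(
        chrom=chrom,
        strand=strand,
        start=start,
        end=end,
        center=center,
        replicate_support=len(members),
        window_reads=n,
    )


# ---------------------------------------------------------------------------
# Target assignment and overlap sets
# ---------------------------------------------------------------------------


@dataclass
class TargetIntronSet:
    label: str
    introns: set[str]  # intron key strings


def assign_targets(
    peaks: Sequence[Peak],
    donors: Sequence[DonorSite],
    window: tuple[int, int] = (-100, 50),
    label: str = "targets",
) -> TargetIntronSet:
    """Introns whose donor window intersects a kept peak.

    ``window`` is in transcript orientation around the donor: the default
    [-100, +50) covers the upstream-exonic binding footprint and the
    proximal intron.
    """
    lo, hi = window
    targets: set[str] = set()
    for d in donors:
        if d.strand == "+":
            wstart, wend = d.pos + lo, d.pos + hi
        else:
            wstart, wend = d.pos - hi + 1, d.pos - lo + 1
        for p in peaks:
            if p.chrom == d.chrom and p.strand == d.strand and p.start < wend and wstart < p.end:
                targets.add(
                    f"{d.intron.chrom}:{d.intron.start}-{d.intron.end}:{d.intron.strand}"
                )
                break
    return TargetIntronSet(label=label, introns=targets)


def overlap_sets(
    named_sets: Mapping[str, set[str]], universe: set[str]
) -> dict:
    """Pairwise/three-way overlap counts and Jaccard indices.

    All sets must be subsets of the shared ``universe``.
    """
    if len(named_sets) < 2:
        raise ConfigError("need at least two sets to overlap")
    for name, s in named_sets.items():
        if not s <= universe:
            raise ConfigError(
                f"set {name!r} contains {len(s - universe)} introns outside the universe"
            )
    names = sorted(named_sets)
    result: dict = {"sizes": {n: len(named_sets[n]) for n in names}, "pairs": {}}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            inter = named_sets[a] & named_sets[b]
            union = named_sets[a] | named_sets[b]
            result["pairs"][f"{a}&{b}"] = {
                "intersection": len(inter),
                "jaccard": len(inter) / len(union) if union else 1.0,
            }
    if len(names) >= 3:
        for i, a in enumerate(names):
            for j, b in enumerate(names[i + 1 :], start=i + 1):
                for c in names[j + 1 :]:
                    result.setdefault("triples", {})[f"{a}&{b}&{c}"] = len(
                        named_sets[a] & named_sets[b] & named_sets[c]
                    )
    return result


def write_peaks_bed(peaks: Sequence[Peak], path: str | Path) -> None:
    """BED6 with the combined window read count as the score."""
    with open(path, "w") as fh:
        for p in sorted(peaks, key=lambda q: (q.chrom, q.start)):
            score = p.window_reads if p.window_reads >= 0 else 0
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\tpeak\t{score}\t{p.strand}\n")
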