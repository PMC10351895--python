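import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clipsplice.errors import ConfigError
from clipsplice.peaks import (
    Peak,
    assign_targets,
    build_coverage,
    call_candidate_peaks,
    filter_reproducible,
    overlap_sets,
)
from testutil import donors_from_introns, mk_intron, mk_read


def bruteforce_runs(track, threshold):
    runs, start = [], None
    for i, v in enumerate(track):
        if v >= threshold and start is None:
            start = i
        elif v < threshold and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(track)))
    return runs


class TestCandidates:
    def test_rectangular_bump(self):
        track = np.zeros(200)
        track[50:100] = 10
        peaks = call_candidate_peaks(track, "chr1", "+", min_height=5)
        assert len(peaks) == 1
        assert (peaks[0].start, peaks[0].end, peaks[0].width) == (50, 100, 50)
        assert peaks[0].center == 50  # leftmost maximum

    def test_flat_zero_track_gives_nothing(self):
        assert call_candidate_peaks(np.zeros(100), "chr1", "+") == []

    def test_two_bumps_split_by_gap(self):
        track = np.zeros(300)
        track[50:80] = 4
        track[150:200] = 6
        peaks = call_candidate_peaks(track, "chr1", "+", min_height=3)
        assert [(p.start, p.end) for p in peaks] == [(50, 80), (150, 200)]

    @settings(max_examples=60, deadline=None)
    @given(
        st.lists(st.integers(min_value=0, max_value=8), min_size=1, max_size=80),
        st.integers(min_value=1, max_value=8),
    )
    def test_matches_bruteforce_run_scan(self, values, threshold):
        track = np.array(values, dtype=float)
        peaks = call_candidate_peaks(track, "c", "+", min_height=threshold)
        assert [(p.start, p.end) for p in peaks] == bruteforce_runs(track, threshold)
        for p in peaks:
            assert p.center == p.start + int(np.argmax(track[p.start : p.end]))

    def test_default_threshold_is_q90_of_nonzero(self):
        track = np.zeros(1000)
        track[:100] = np.arange(1, 101)
        peaks = call_candidate_peaks(track, "c", "+")
        q90 = np.quantile(np.arange(1, 101), 0.9)
        assert peaks[0].start == int(np.ceil(q90)) - 1

    def test_raising_threshold_only_shrinks_candidates(self):
        rng = np.random.default_rng(2)
        track = rng.poisson(2, 500).astype(float)
        low = call_candidate_peaks(track, "c", "+", min_height=2)
        high = call_candidate_peaks(track, "c", "+", min_height=4)
        covered = set()
        for p in low:
            covered.update(range(p.start, p.end))
        for p in high:
            assert set(range(p.start, p.end)) <= covered


def _reads_at(center, n, chrom="chr1", strand="+", half=20):
    return [
        mk_read(chrom, [(center - half, center + half)], strand=strand, name=f"{center}_{i}")
        for i in range(n)
    ]


class TestReproducibilityFilter:
    def _peak(self, start, end, center=None):
        return Peak("chr1", "+", start, end, center if center is not None else start)

    def test_width_threshold_is_strict(self):
        reads = _reads_at(120, 10)
        p35 = self._peak(100, 135, 120)
        p36 = self._peak(100, 136, 120)
        kept35 = filter_reproducible([p35], [p35], reads, reads)
        kept36 = filter_reproducible([p36], [p36], reads, reads)
        assert kept35 == []
        assert len(kept36) == 1

    def test_window_read_threshold_is_strict(self):
        peak = self._peak(100, 140, 120)
        kept5 = filter_reproducible([peak], [peak], _reads_at(120, 3), _reads_at(120, 2))
        kept6 = filter_reproducible([peak], [peak], _reads_at(120, 3), _reads_at(120, 3))
        assert kept5 == []
        assert len(kept6) == 1
        assert kept6[0].window_reads == 6

    def test_no_overlap_partner_rejected(self):
        a = self._peak(100, 140, 120)
        b = self._peak(200, 240, 220)
        assert filter_reproducible([a], [b], _reads_at(120, 10), _reads_at(220, 10)) == []

    def test_overlapping_pair_merged_to_union(self):
        a = self._peak(100, 140, 120)
        b = self._peak(110, 160, 130)
        reads = _reads_at(125, 10)
        kept = filter_reproducible([a], [b], reads, reads)
        assert len(kept) == 1
        assert (kept[0].start, kept[0].end) == (100, 160)
        assert kept[0].replicate_support == 2

    def test_filter_order_independence(self):
        """Applying the three conditions in any order keeps the same candidates."""
        rng = np.random.default_rng(8)
        cands1, cands2, reads1, reads2 = [], [], [], []
        for i in range(30):
            s = int(rng.integers(0, 5000))
            w = int(rng.integers(20, 60))
            c = s + int(rng.integers(0, w))
            (cands1 if i % 2 else cands2).append(self._peak(s, s + w, c))
            reads1.extend(_reads_at(c, int(rng.integers(0, 6))))
            reads2.extend(_reads_at(c, int(rng.integers(0, 6))))
        kept = filter_reproducible(cands1, cands2, reads1, reads2)
        combined = reads1 + reads2

        def cond_overlap(p, others):
            return any(p.overlaps(o) for o in others)

        def cond_width(p):
            return p.width > 35

        def cond_reads(p):
            n = sum(
                1 for r in combined
                if r.chrom == p.chrom and r.strand == p.strand
                and r.start < p.center + 25 and r.end > p.center - 25
            )
            return n > 5

        kept_cover = set()
        for p in kept:
            kept_cover.update(range(p.start, p.end))
        for order in ([0, 1, 2], [2, 1, 0], [1, 2, 0]):
            passing = []
            for p, others in [(q, cands2) for q in cands1] + [(q, cands1) for q in cands2]:
                checks = [cond_overlap(p, others), cond_width(p), cond_reads(p)]
                if all(checks[i] for i in order):
                    passing.append(p)
            covered = set()
            for p in passing:
                covered.update(range(p.start, p.end))
            assert covered == kept_cover


class TestTargets:
    INTRONS = [mk_intron(start=1000, end=2200), mk_intron(start=5000, end=6500, strand="-")]

    def test_peak_over_donor_is_target(self):
        donors = donors_from_introns(self.INTRONS)
        peak = Peak("chr1", "+", 990, 1030, 1000)
        t = assign_targets([peak], donors)
        assert t.introns == {"chr1:1000-2200:+"}

    def test_peak_deep_inside_intron_is_not_target(self):
        donors = donors_from_introns(self.INTRONS)
        peak = Peak("chr1", "+", 2000, 2050, 2010)  # 1 kb into the intron
        assert assign_targets([peak], donors).introns == set()

    def test_window_edges_with_bruteforce_oracle(self):
        rng = np.random.default_rng(4)
        donors = donors_from_introns(self.INTRONS)
        peaks = []
        for i in range(300):
            strand = "+" if rng.random() < 0.5 else "-"
            s = int(rng.integers(500, 7000))
            peaks.append(Peak("chr1", strand, s, s + int(rng.integers(5, 80)), s))
        got = assign_targets(peaks, donors, window=(-100, 50)).introns
        expected = set()
        for d in donors:
            if d.strand == "+":
                lo, hi = d.pos - 100, d.pos + 50
            else:
                lo, hi = d.pos - 49, d.pos + 101
            for p in peaks:
                if p.strand == d.strand and p.start < hi and p.end > lo:
                    expected.add(
                        f"{d.intron.chrom}:{d.intron.start}-{d.intron.end}:{d.intron.strand}"
                    )
        assert got == expected

    def test_upstream_peak_within_default_window(self):
        donors = donors_from_introns(self.INTRONS[:1])
        peak = Peak("chr1", "+", 905, 911, 908)  # donor-90ish
        assert assign_targets([peak], donors).introns == {"chr1:1000-2200:+"}


class TestOverlapSets:
    def test_identical_sets_have_jaccard_one(self):
        u = {"a", "b", "c"}
        res = overlap_sets({"x": {"a", "b"}, "y": {"a", "b"}}, u)
        assert res["pairs"]["x&y"]["jaccard"] == 1.0

    def test_disjoint_sets_have_zero_intersections(self):
        res = overlap_sets({"x": {"a"}, "y": {"b"}, "z": {"c"}}, {"a", "b", "c"})
        assert all(p["intersection"] == 0 for p in res["pairs"].values())
        assert res["triples"]["x&y&z"] == 0

    def test_random_sets_match_bruteforce(self):
        rng = np.random.default_rng(9)
        universe = {f"i{k}" for k in range(50)}
        sets = {
            name: {x for x in universe if rng.random() < 0.4} for name in "abc"
        }
        res = overlap_sets(sets, universe)
        assert res["pairs"]["a&b"]["intersection"] == len(sets["a"] & sets["b"])
        assert res["triples"]["a&b&c"] == len(sets["a"] & sets["b"] & sets["c"])

    def test_universe_mismatch_rejected(self):
        with pytest.raises(ConfigError):
            overlap_sets({"x": {"a"}, "y": {"zzz"}}, {"a"})


def test_build_coverage_counts_unique_reads_only():
    reads = [
        mk_read("chr1", [(10, 20)], name="u"),
        mk_read("chr1", [(10, 20)], name="m", mapq=1),
    ]
    tracks = build_coverage(reads, {"chr1": 100})
    assert tracks[("chr1", "+")][10:20].max() == 1
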