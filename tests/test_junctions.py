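import numpy as np
import pandas as pd
import pytest

from clipsplice.errors import ConfigError
from clipsplice.junctions import (
    call_splice_events,
    classify_donor_reads,
    classify_junction_reads,
    collect_junction_evidence,
    detect_novel_donors,
    junction_ratio_table,
    region_read_totals,
)
from testutil import intron_key, mk_intron, mk_read

INTRON = mk_intron(start=1000, end=2200)  # plus strand, donor at 1000


class TestClassifyDonorReads:
    def test_gapped_read_matching_intron_is_spliced(self):
        read = mk_read("chr1", [(960, 1000), (2200, 2240)])
        assert classify_donor_reads([read], INTRON) == (1, 0)

    def test_contiguous_boundary_read_is_unspliced(self):
        read = mk_read("chr1", [(990, 1010)])  # 10 exonic + 10 intronic
        assert classify_donor_reads([read], INTRON) == (0, 1)

    def test_short_overhang_is_ignored(self):
        read = mk_read("chr1", [(960, 1002)])  # only 2 nt into the intron
        assert classify_donor_reads([read], INTRON, min_overhang=5) == (0, 0)

    def test_gap_not_matching_intron_is_ignored(self):
        read = mk_read("chr1", [(960, 1001), (2200, 2240)])
        assert classify_donor_reads([read], INTRON) == (0, 0)

    def test_wrong_strand_read_is_ignored(self):
        read = mk_read("chr1", [(990, 1010)], strand="-")
        assert classify_donor_reads([read], INTRON) == (0, 0)

    def test_minus_strand_boundary(self):
        intron = mk_intron(start=1000, end=2200, strand="-")  # donor at 2199
        read = mk_read("chr1", [(2190, 2210)], strand="-")
        assert classify_donor_reads([read], intron) == (0, 1)

    def test_partition_matches_bruteforce(self):
        """One-pass classification equals per-read brute force on random reads."""
        rng = np.random.default_rng(17)
        introns = [
            mk_intron(start=1000, end=2200),
            mk_intron(start=5000, end=6500, strand="-"),
        ]
        reads = []
        for i in range(400):
            strand = "+" if rng.random() < 0.5 else "-"
            if rng.random() < 0.4:
                intron = introns[int(rng.integers(0, 2))]
                s = int(rng.integers(intron.start - 60, intron.start + 10))
                reads.append(
                    mk_read("chr1", [(s, intron.start), (intron.end, intron.end + 30)],
                            strand=strand, name=f"g{i}")
                )
            else:
                s = int(rng.integers(900, 6600))
                reads.append(mk_read("chr1", [(s, s + 40)], strand=strand, name=f"c{i}"))
        table = classify_junction_reads({"lib": reads}, introns, min_overhang=5)
        for intron in introns:
            row = table[table["intron"] == intron_key(intron)].iloc[0]
            expected = classify_donor_reads(reads, intron, min_overhang=5)
            assert (row["spliced"], row["unspliced"]) == expected
            # spliced/unspliced/ignored partition the donor-overlapping reads
            assert row["spliced"] + row["unspliced"] <= len(reads)


class TestRatioTable:
    def _counts(self, spliced, unspliced, intron):
        return pd.DataFrame(
            [{"intron": intron_key(intron), "library": "l1",
              "spliced": spliced, "unspliced": unspliced}]
        )

    def test_region_total_below_50_excluded(self):
        counts = self._counts(20, 20, INTRON)
        totals = pd.Series({intron_key(INTRON): 49})
        table = junction_ratio_table(counts, [INTRON], totals)
        assert not table["kept"].iloc[0]
        totals50 = pd.Series({intron_key(INTRON): 50})
        assert junction_ratio_table(counts, [INTRON], totals50)["kept"].iloc[0]

    def test_short_intron_excluded(self):
        short = mk_intron(start=1000, end=1900)  # 900 nt
        counts = self._counts(40, 40, short)
        totals = pd.Series({intron_key(short): 500})
        assert not junction_ratio_table(counts, [short], totals)["kept"].iloc[0]

    def test_symmetric_counts_give_zero_log2fc(self):
        counts = self._counts(40, 40, INTRON)
        totals = pd.Series({intron_key(INTRON): 500})
        table = junction_ratio_table(counts, [INTRON], totals)
        assert table["log2_ratio"].iloc[0] == 0.0
        assert table["kept"].iloc[0]

    def test_both_rule_requires_both_counts_above_threshold(self):
        counts = self._counts(11, 10, INTRON)
        totals = pd.Series({intron_key(INTRON): 500})
        both = junction_ratio_table(counts, [INTRON], totals, count_rule="both")
        either = junction_ratio_table(counts, [INTRON], totals, count_rule="either")
        assert not both["kept"].iloc[0]
        assert either["kept"].iloc[0]

    def test_ratio_undefined_when_a_count_is_zero(self):
        counts = self._counts(40, 0, INTRON)
        totals = pd.Series({intron_key(INTRON): 500})
        assert np.isnan(junction_ratio_table(counts, [INTRON], totals)["log2_ratio"].iloc[0])


def test_region_totals_count_window_overlaps():
    reads = [
        mk_read("chr1", [(899, 905)], name="in_window"),  # overlaps 1000-100
        mk_read("chr1", [(880, 900)], name="outside"),  # ends at window edge
        mk_read("chr1", [(1100, 1140)], name="in_right"),
    ]
    totals = region_read_totals({"l": reads}, [INTRON], flank=100)
    assert totals.iloc[0] == 2


class TestNovelDonors:
    def _reads(self, n, gap, name_prefix):
        return [
            mk_read("chr1", [(gap[0] - 30, gap[0]), (gap[1], gap[1] + 30)],
                    name=f"{name_prefix}{i}")
            for i in range(n)
        ]

    def test_ko_only_cryptic_donor_detected_with_full_inclusion_shift(self):
        annotated = (1000, 2200)
        cryptic = (1040, 2200)  # novel 5' edge inside the intron
        reads = {
            "wt": self._reads(100, annotated, "w"),
            "ko": self._reads(60, annotated, "k") + self._reads(100, cryptic, "kc"),
        }
        events = detect_novel_donors(
            reads, {"wt": "WT", "ko": "KO"}, [INTRON], "WT", "KO",
            include_retained=False,
        )
        assert len(events) == 1
        e = events[0]
        assert e.event_class == "novel_5ss"
        assert e.position == 1040
        assert e.inclusion_ref == 0.0
        assert e.inclusion_alt == pytest.approx(100 / 160)

    def test_low_read_events_excluded(self):
        cryptic = (1040, 2200)
        reads = {"wt": self._reads(5, cryptic, "w"), "ko": self._reads(24, cryptic, "k")}
        events = detect_novel_donors(
            reads, {"wt": "WT", "ko": "KO"}, [INTRON], "WT", "KO",
            include_retained=False,
        )
        assert events == []  # 29 reads across samples is not > 30

    def test_identical_usage_not_reported(self):
        annotated, cryptic = (1000, 2200), (1040, 2200)
        reads = {
            "wt": self._reads(50, annotated, "w") + self._reads(50, cryptic, "wc"),
            "ko": self._reads(50, annotated, "k") + self._reads(50, cryptic, "kc"),
        }
        events = detect_novel_donors(
            reads, {"wt": "WT", "ko": "KO"}, [INTRON], "WT", "KO",
            include_retained=False,
        )
        assert events == []

    def test_single_condition_rejected(self):
        with pytest.raises(ConfigError):
            detect_novel_donors(
                {"a": [], "b": []}, {"a": "WT", "b": "WT"}, [INTRON], "WT", "KO"
            )

    def test_novel_3ss_on_minus_strand_is_donor_side_aware(self):
        intron = mk_intron(start=1000, end=2200, strand="-")  # donor at 2199
        novel = (1000, 2100)  # shares the 5' (genomic-left) edge = acceptor on '-'
        reads = {
            "wt": [],
            "ko": [
                mk_read("chr1", [(970, 1000), (2100, 2130)], strand="-", name=f"k{i}")
                for i in range(40)
            ],
        }
        ev = collect_junction_evidence(reads, {"wt": "WT", "ko": "KO"}, [intron])
        assert set(ev["event_class"]) == {"novel_5ss"}
        assert ev["position"].iloc[0] == 2099

    def test_retained_intron_inclusion_uses_unspliced_reads(self):
        spliced = self._reads(60, (1000, 2200), "s")
        unspliced = [
            mk_read("chr1", [(980, 1020)], name=f"u{i}") for i in range(60)
        ]
        reads = {"wt": spliced, "ko": unspliced}
        events = detect_novel_donors(
            reads, {"wt": "WT", "ko": "KO"}, [INTRON], "WT", "KO",
            include_retained=True,
        )
        assert len(events) == 1
        assert events[0].event_class == "retained_intron"
        assert events[0].inclusion_difference == pytest.approx(1.0)


def test_call_splice_events_requires_both_condition_columns():
    ev = pd.DataFrame([{"intron": "x", "event_class": "novel_5ss", "position": 1,
                        "alt_WT": 5, "annot_WT": 5}])
    with pytest.raises(ConfigError):
        call_splice_events(ev, "WT", "KO")
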