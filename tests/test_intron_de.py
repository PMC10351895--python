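import numpy as np
import pandas as pd
import pytest

from clipsplice.annotation import Gene, AnnotationModel, Transcript
from clipsplice.errors import ConfigError
from clipsplice.intron_de import (
    Feature,
    count_features,
    differential,
    features_from_genes,
    flag_regulated,
    select_misspliced,
    size_factors,
    target_fraction,
)
from testutil import mk_read

GENES = [
    Feature("gA", "chr1", "+", 1000, 3000),
    Feature("gB", "chr1", "+", 2500, 5000),  # overlaps gA in 2500-3000
    Feature("gC", "chr1", "-", 6000, 8000),
]
INTRONS = [
    Feature("iA", "chr1", "+", 1400, 2400),
    Feature("iC", "chr1", "-", 6500, 7500),
]


class TestCountFeatures:
    def test_gene_mode_single_overlap_counts(self):
        reads = {"l1": [mk_read("chr1", [(1100, 1140)])]}
        counts = count_features(reads, GENES, mode="gene")
        assert counts.loc["gA", "l1"] == 1

    def test_gene_mode_drops_ambiguous_reads(self):
        reads = {"l1": [mk_read("chr1", [(2600, 2640)])]}  # inside gA and gB
        counts = count_features(reads, GENES, mode="gene")
        assert counts["l1"].sum() == 0

    def test_intron_mode_minimum_overlap_of_ten(self):
        nine = mk_read("chr1", [(1391, 1409)])  # 9 nt inside iA
        ten = mk_read("chr1", [(1390, 1410)])
        counts9 = count_features({"l": [nine]}, INTRONS, mode="intron")
        counts10 = count_features({"l": [ten]}, INTRONS, mode="intron")
        assert counts9.loc["iA", "l"] == 0
        assert counts10.loc["iA", "l"] == 1

    def test_intron_mode_allows_multi_feature_overlap(self):
        overlapping = INTRONS + [Feature("iA2", "chr1", "+", 1400, 2000)]
        read = mk_read("chr1", [(1500, 1560)])
        counts = count_features({"l": [read]}, overlapping, mode="intron")
        assert counts.loc["iA", "l"] == 1 and counts.loc["iA2", "l"] == 1

    def test_multimapper_excluded(self):
        reads = {"l1": [mk_read("chr1", [(1100, 1140)], mapq=3)]}
        assert count_features(reads, GENES, mode="gene")["l1"].sum() == 0

    def test_strand_modes(self):
        read = mk_read("chr1", [(6600, 6640)], strand="+")  # gC is minus strand
        sense = count_features({"l": [read]}, GENES, mode="gene", strandedness="sense")
        rev = count_features({"l": [read]}, GENES, mode="gene", strandedness="reverse")
        assert sense.loc["gC", "l"] == 0
        assert rev.loc["gC", "l"] == 1

    def test_matches_bruteforce_interval_sweep(self):
        rng = np.random.default_rng(11)
        reads = []
        for i in range(200):
            s = int(rng.integers(500, 8200))
            strand = "+" if rng.random() < 0.5 else "-"
            blocks = [(s, s + 30)]
            if rng.random() < 0.3:
                blocks.append((s + 200, s + 230))
            reads.append(mk_read("chr1", blocks, strand=strand, name=f"r{i}"))
        got = count_features({"l": reads}, INTRONS, mode="intron", min_overlap=10)
        for f in INTRONS:
            expected = 0
            for r in reads:
                if r.strand != f.strand:
                    continue
                ov = sum(max(0, min(be, f.end) - max(bs, f.start)) for bs, be in r.blocks)
                if ov >= 10:
                    expected += 1
            assert got.loc[f.feature_id, "l"] == expected


def _counts_table(rng, n=300, libs=("w1", "w2", "k1", "k2"), mu=80.0):
    base = rng.lognormal(np.log(mu), 0.5, n)
    data = {
        lib: rng.poisson(base * s)
        for lib, s in zip(libs, [1.0, 1.1, 0.95, 1.05])
    }
    return pd.DataFrame(data, index=[f"f{i}" for i in range(n)])


COND = {"w1": "WT", "w2": "WT", "k1": "KO", "k2": "KO"}


class TestDifferential:
    def test_prefilter_boundary(self):
        rng = np.random.default_rng(0)
        counts = _counts_table(rng)
        counts.iloc[0] = [28, 27, 27, 27]  # total 109
        counts.iloc[1] = [28, 28, 27, 27]  # total 110
        res = differential(counts, COND, "WT", "KO", prefilter_min_total=110)
        assert res["excluded"].iloc[0]
        assert not res["excluded"].iloc[1]
        assert np.isnan(res["padj"].iloc[0])

    def test_identical_counts_give_zero_lfc_and_p_one(self):
        counts = pd.DataFrame(
            {"w1": [50] * 20, "w2": [50] * 20, "k1": [50] * 20, "k2": [50] * 20},
            index=[f"f{i}" for i in range(20)],
        )
        res = differential(counts, COND, "WT", "KO", prefilter_min_total=0)
        assert np.allclose(res["log2FC"], 0.0)
        assert np.all(res["pvalue"] > 0.99)

    def test_library_scaling_absorbed_by_size_factors(self):
        rng = np.random.default_rng(1)
        counts = _counts_table(rng)
        scaled = counts.copy()
        scaled["k1"] = scaled["k1"] * 3
        sf0 = size_factors(counts)
        sf1 = size_factors(scaled)
        # factors are relative: k1's factor grows by exactly 3 vs the others
        assert (sf1["k1"] / sf1["w1"]) / (sf0["k1"] / sf0["w1"]) == pytest.approx(3.0)
        r0 = differential(counts, COND, "WT", "KO", prefilter_min_total=0)
        r1 = differential(scaled, COND, "WT", "KO", prefilter_min_total=0)
        assert np.allclose(r0["log2FC"], r1["log2FC"])

    def test_planted_effect_detected(self):
        rng = np.random.default_rng(2)
        counts = _counts_table(rng, n=400)
        hot = counts.index[:40]
        counts.loc[hot, ["k1", "k2"]] = (counts.loc[hot, ["k1", "k2"]] * 3).astype(int)
        res = flag_regulated(
            differential(counts, COND, "WT", "KO", prefilter_min_total=0), 0.05, 0.5
        )
        recall = res.loc[hot, "up"].mean()
        fp = res.loc[res.index.difference(hot), "up"].mean()
        assert recall > 0.8
        assert fp < 0.05

    def test_bh_adjustment_properties(self):
        rng = np.random.default_rng(3)
        counts = _counts_table(rng)
        res = differential(counts, COND, "WT", "KO", prefilter_min_total=0)
        p = res["pvalue"].to_numpy()
        q = res["padj"].to_numpy()
        assert np.all(q >= p - 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)  # monotone in rank

    def test_single_replicate_rejected(self):
        counts = pd.DataFrame({"w1": [10], "k1": [12], "k2": [11]})
        with pytest.raises(ConfigError):
            differential(counts, {"w1": "WT", "k1": "KO", "k2": "KO"}, "WT", "KO")


class TestSelection:
    def _results(self):
        intron_res = pd.DataFrame(
            {
                "log2FC": [1.0, 1.0, 1.0, 0.2, -1.0],
                "padj": [0.001, 0.001, 0.2, 0.001, 0.001],
                "excluded": [False] * 5,
            },
            index=[f"i{k}" for k in range(5)],
        )
        gene_res = pd.DataFrame(
            {"log2FC": [-0.3, 0.2, -0.5, -0.5, -0.5]},
            index=[f"g{k}" for k in range(5)],
        )
        intron_gene = {f"i{k}": f"g{k}" for k in range(5)}
        return intron_res, gene_res, intron_gene

    def test_host_gene_up_rejects_intron(self):
        intron_res, gene_res, intron_gene = self._results()
        sel = select_misspliced(intron_res, gene_res, intron_gene)
        assert bool(sel.loc["i0", "misspliced"])  # up intron, gene -0.3
        assert not bool(sel.loc["i1", "misspliced"])  # gene +0.2
        assert not bool(sel.loc["i2", "misspliced"])  # padj too high
        assert not bool(sel.loc["i3", "misspliced"])  # lfc too low
        assert not bool(sel.loc["i4", "misspliced"])  # down, not up

    def test_missing_host_gene_warns_and_excludes(self):
        intron_res, gene_res, intron_gene = self._results()
        del intron_gene["i0"]
        with pytest.warns(UserWarning, match="no host-gene result"):
            sel = select_misspliced(intron_res, gene_res, intron_gene)
        assert not bool(sel.loc["i0", "misspliced"])

    def test_selection_is_set_algebraic(self):
        rng = np.random.default_rng(5)
        n = 200
        intron_res = pd.DataFrame(
            {
                "log2FC": rng.normal(0, 1, n),
                "padj": rng.uniform(0, 0.2, n),
                "excluded": rng.random(n) < 0.1,
            },
            index=[f"i{k}" for k in range(n)],
        )
        gene_res = pd.DataFrame(
            {"log2FC": rng.normal(0, 1, n)}, index=[f"g{k}" for k in range(n)]
        )
        intron_gene = {f"i{k}": f"g{k}" for k in range(n)}
        sel = select_misspliced(intron_res, gene_res, intron_gene)
        up_set = {
            i for i in intron_res.index
            if intron_res.loc[i, "padj"] < 0.05
            and intron_res.loc[i, "log2FC"] > 0.5
            and not intron_res.loc[i, "excluded"]
        }
        down_gene_set = {
            f"i{k}" for k in range(n) if gene_res.loc[f"g{k}", "log2FC"] < 0
        }
        assert set(sel.index[sel["misspliced"]]) == (up_set & down_gene_set)


class TestTargetFraction:
    def test_arithmetic_instance(self):
        targets = {f"i{k}" for k in range(500)}
        hit = {f"i{k}" for k in range(29)}
        assert target_fraction(hit, targets) == pytest.approx(5.8)

    def test_superset_and_disjoint(self):
        targets = {"a", "b"}
        assert target_fraction({"a", "b", "c"}, targets) == 100.0
        assert target_fraction({"x"}, targets) == 0.0

    def test_empty_targets_rejected(self):
        with pytest.raises(ConfigError):
            target_fraction({"a"}, set())


def test_features_from_genes_span_transcripts():
    g = Gene(gene_id="g1", chrom="chr1", strand="+")
    g.transcripts["t1"] = Transcript("t1", "g1", "chr1", "+", [(10, 50), (100, 150)])
    feats = features_from_genes(AnnotationModel({"g1": g}))
    assert feats[0].start == 10 and feats[0].end == 150
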