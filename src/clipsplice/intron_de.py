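"""Gene- and intron-level differential analysis with the selection logic
for mis-spliced introns.

The differential test is a negative-binomial Wald test: libraries are
normalized with median-of-ratios size factors, per-feature dispersions come
from a method-of-moments estimate moderated through a fitted
``alpha(mu) = a0 + a1 / mu`` mean-dispersion trend shared across features
(floored at 1e-8), and the Wald statistic log2FC / SE(log2FC) is referred to
a standard normal, followed by Benjamini-Hochberg adjustment.  The trend
moderation exists because a per-feature moment estimate from 2 replicates
per condition is essentially noise; pooling across hundreds of features
gives a calibrated test while keeping the estimator closed-form.

Selection follows the thresholds of the analysed study design: introns with
adjusted p < 0.05 and |log2FC| > 0.5 are up/down-regulated (genes: p < 0.01,
|log2FC| > 1) after a minimum-total-count prefilter, and "mis-spliced"
introns are up-regulated introns inside genes that are not up-regulated
(gene log2FC < 0, unthresholded).
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError
from .samio import ReadAln

LN2 = np.log(2.0)

#: minimum-total-count prefilters by feature kind and treatment regime
PREFILTERS = {
    ("gene", "untreated"): 200,
    ("gene", "chx"): 80,
    ("intron", "untreated"): 110,
    ("intron", "chx"): 40,
    ("gene", "riboseq"): 10,
}


@dataclass(frozen=True)
class Feature:
    feature_id: str
    chrom: str
    strand: str
    start: int
    end: int


def features_from_genes(model) -> list[Feature]:
    return [
        Feature(g.gene_id, g.chrom, g.strand, g.start, g.end)
        for g in model.genes.values()
    ]


def features_from_introns(introns) -> list[Feature]:
    return [
        Feature(
            f"{i.chrom}:{i.start}-{i.end}:{i.strand}", i.chrom, i.strand, i.start, i.end
        )
        for i in introns
    ]


def count_features(
    reads_by_library: Mapping[str, Sequence[ReadAln]],
    features: Sequence[Feature],
    mode: str,
    min_overlap: int | None = None,
    unique_only: bool = True,
    min_mapq: int = 255,
    strandedness: str = "sense",
) -> pd.DataFrame:
    """Count reads per feature per library.

    ``mode="gene"``: a uniquely mapped, correctly stranded read overlapping
    exactly one feature by >= 1 nt counts for that feature; reads touching
    several features count for none.  ``mode="intron"``: overlap of
    >= ``min_overlap`` nt (default 10) is required and multi-feature overlap
    is allowed.  Overlap is the read's total aligned bases inside the
    feature, summed over blocks.
    """
    if mode not in ("gene", "intron"):
        raise ConfigError(f"unknown counting mode {mode!r}")
    if strandedness not in ("sense", "reverse", "none"):
        raise ConfigError(f"unknown strandedness {strandedness!r}")
    if min_overlap is None:
        min_overlap = 1 if mode == "gene" else 10
    by_cs: dict[tuple[str, str], list[tuple[int, int, int]]] = defaultdict(list)
    for idx, f in enumerate(features):
        by_cs[(f.chrom, f.strand)].append((f.start, f.end, idx))
    indexed = {}
    for key, vals in by_cs.items():
        vals.sort()
        starts = np.array([s for s, _, _ in vals])
        max_len = max(e - s for s, e, _ in vals)
        indexed[key] = (starts, vals, max_len)

    counts = pd.DataFrame(
        0,
        index=[f.feature_id for f in features],
        columns=list(reads_by_library),
        dtype=np.int64,
    )
    values = counts.values
    for col, (lib, reads) in enumerate(reads_by_library.items()):
        for read in reads:
            if unique_only and read.mapq < min_mapq:
                continue
            if strandedness == "sense":
                feat_strand = read.strand
            elif strandedness == "reverse":
                feat_strand = "-" if read.strand == "+" else "+"
            else:
                feat_strand = None
            hits: list[int] = []
            for key in indexed:
                chrom, strand = key
                if chrom != read.chrom:
                    continue
                if feat_strand is not None and strand != feat_strand:
                    continue
                starts, vals, max_len = indexed[key]
                lo = np.searchsorted(starts, read.start - max_len, side="left")
                hi = np.searchsorted(starts, read.end, side="left")
                for s, e, idx in vals[lo:hi]:
                    if e <= read.start:
                        continue
                    overlap = sum(
                        max(0, min(be, e) - max(bs, s)) for bs, be in read.blocks
                    )
                    if overlap >= min_overlap:
                        hits.append(idx)
            if mode == "gene":
                if len(hits) == 1:
                    values[hits[0], col] += 1
            else:
                for idx in hits:
                    values[idx, col] += 1
    return counts


# ---------------------------------------------------------------------------
# NB-Wald differential test
# ---------------------------------------------------------------------------


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalization factors (one per library)."""
    mat = counts.to_numpy(dtype=float)
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise ConfigError("no feature has positive counts in every library")
    log_geo = np.log(mat[positive]).mean(axis=1)
    factors = np.exp(np.median(np.log(mat[positive]) - log_geo[:, None], axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def _trend_dispersion(mu: np.ndarray, alpha_raw: np.ndarray) -> np.ndarray:
    """Fit alpha(mu) = a0 + a1/mu by least squares on the raw estimates.

    Raw (possibly negative) moment estimates enter unfiltered so the fit is
    unbiased; only the fitted values are floored.
    """
    ok = mu > 0
    if ok.sum() < 3:
        return np.full_like(mu, 1e-8)
    X = np.column_stack([np.ones(ok.sum()), 1.0 / mu[ok]])
    coef, *_ = np.linalg.lstsq(X, alpha_raw[ok], rcond=None)
    with np.errstate(divide="ignore"):
        fitted = coef[0] + coef[1] / np.where(mu > 0, mu, np.inf)
    return np.maximum(fitted, 1e-8)


def differential(
    counts: pd.DataFrame,
    condition: Mapping[str, str],
    ref: str,
    alt: str,
    prefilter_min_total: int = 110,
) -> pd.DataFrame:
    """Per-feature log2FC (alt vs ref), Wald p and BH-adjusted p.

    Features whose total raw count across all libraries is below
    ``prefilter_min_total`` are flagged ``excluded`` and get no p-value;
    BH adjustment runs over the tested features only.
    """
    libs_ref = [l for l in counts.columns if condition.get(l) == ref]
    libs_alt = [l for l in counts.columns if condition.get(l) == alt]
    if len(libs_ref) < 2 or len(libs_alt) < 2:
        raise ConfigError(
            "at least two replicates per condition are required to estimate dispersion"
        )
    sf = size_factors(counts[libs_ref + libs_alt])
    norm = counts[libs_ref + libs_alt].to_numpy(dtype=float) / sf.to_numpy()
    n_ref, n_alt = len(libs_ref), len(libs_alt)
    Yr, Ya = norm[:, :n_ref], norm[:, n_ref:]
    mu_r, mu_a = Yr.mean(axis=1), Ya.mean(axis=1)
    mu = norm.mean(axis=1)
    # pooled within-condition variance of normalized counts
    var_within = (
        Yr.var(axis=1, ddof=1) * (n_ref - 1) + Ya.var(axis=1, ddof=1) * (n_alt - 1)
    ) / (n_ref + n_alt - 2)
    inv_sf = 1.0 / sf.to_numpy()
    c_bar = inv_sf.mean()
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_raw = (var_within - mu * c_bar) / np.where(mu > 0, mu**2, np.inf)
    alpha = _trend_dispersion(mu, alpha_raw)

    # moderate zero group means with half a (size-factor-scaled) read
    floor = 0.5 * c_bar
    m_r = np.maximum(mu_r, floor)
    m_a = np.maximum(mu_a, floor)
    lfc = np.log2(m_a / m_r)
    sum_inv_ref = inv_sf[:n_ref].sum()
    sum_inv_alt = inv_sf[n_ref:].sum()
    var_log_ref = sum_inv_ref / (n_ref**2 * m_r) + alpha / n_ref
    var_log_alt = sum_inv_alt / (n_alt**2 * m_a) + alpha / n_alt
    se = np.sqrt(var_log_ref + var_log_alt) / LN2
    with np.errstate(divide="ignore", invalid="ignore"):
        z = lfc / se
    pvalue = 2.0 * stats.norm.sf(np.abs(z))

    total = counts.sum(axis=1).to_numpy()
    excluded = total < prefilter_min_total
    result = pd.DataFrame(
        {
            "baseMean": mu,
            "log2FC": lfc,
            "se": se,
            "stat": z,
            "pvalue": pvalue,
            "total": total,
            "excluded": excluded,
        },
        index=counts.index,
    )
    result.loc[excluded, ["pvalue", "stat"]] = np.nan
    padj = np.full(len(result), np.nan)
    tested = ~excluded
    if tested.any():
        padj[tested] = multipletests(pvalue[tested], method="fdr_bh")[1]
    result["padj"] = padj
    return result


def flag_regulated(
    result: pd.DataFrame, padj_threshold: float, lfc_threshold: float
) -> pd.DataFrame:
    """Add ``up`` / ``down`` flags at the given thresholds."""
    out = result.copy()
    sig = (out["padj"] < padj_threshold) & ~out["excluded"]
    out["up"] = sig & (out["log2FC"] > lfc_threshold)
    out["down"] = sig & (out["log2FC"] < -lfc_threshold)
    return out


def select_misspliced(
    intron_results: pd.DataFrame,
    gene_results: pd.DataFrame,
    intron_gene: Mapping[str, str],
    padj_threshold: float = 0.05,
    lfc_threshold: float = 0.5,
) -> pd.DataFrame:
    """Up-regulated introns inside genes that are not up-regulated.

    An intron is flagged ``misspliced`` iff its adjusted p-value is below
    ``padj_threshold``, its log2FC exceeds ``lfc_threshold`` and the host
    gene's log2FC is negative.  Introns without a host-gene result are
    excluded with a warning.
    """
    out = flag_regulated(intron_results, padj_threshold, lfc_threshold)
    gene_lfc = gene_results["log2FC"]
    host_lfc = []
    missing = []
    for intron_id in out.index:
        gid = intron_gene.get(intron_id)
        if gid is None or gid not in gene_lfc.index:
            missing.append(intron_id)
            host_lfc.append(np.nan)
        else:
            host_lfc.append(float(gene_lfc.loc[gid]))
    if missing:
        warnings.warn(
            f"{len(missing)} introns have no host-gene result and were excluded "
            f"from mis-splicing selection (e.g. {missing[:3]})"
        )
    out["gene_log2FC"] = host_lfc
    out["misspliced"] = out["up"] & (out["gene_log2FC"] < 0)
    return out


def target_fraction(misspliced: Iterable[str], targets: set[str]) -> float:
    """Percentage of target introns that are mis-spliced."""
    if not targets:
        raise ConfigError("target intron set is empty")
    return 100.0 * len(set(misspliced) & targets) / len(targets)
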