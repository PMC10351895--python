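"""Splice-site strength scoring with trained log-odds position weight matrices.

Site definitions (transcript orientation):

* donor: 9-mer, 3 exonic + 6 intronic bases around the exon|intron boundary;
* acceptor: 23-mer, 20 intronic + 3 exonic bases around the intron|exon
  boundary;
* branch point: best-scoring 7-mer whose last base lies 18-44 nt upstream of
  the intron's 3' end.

Scores are log2 odds against a background base composition (uniform by
default), in bits; 0 bits means "looks like background".  A PWM trained on
the annotated sites of the expressed transcriptome preserves the rank
structure needed for stratified comparisons of weak versus strong sites.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .annotation import Intron, revcomp
from .errors import ClipspliceError, ConfigError

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

DONOR_EXONIC = 3
DONOR_INTRONIC = 6
DONOR_LENGTH = DONOR_EXONIC + DONOR_INTRONIC
ACCEPTOR_INTRONIC = 20
ACCEPTOR_EXONIC = 3
ACCEPTOR_LENGTH = ACCEPTOR_INTRONIC + ACCEPTOR_EXONIC
BRANCH_LENGTH = 7
#: heptamer END distance from the intron's last base, inclusive bounds
BRANCH_SEARCH = (18, 44)

SITE_LENGTHS = {
    "donor": DONOR_LENGTH,
    "acceptor": ACCEPTOR_LENGTH,
    "branch": BRANCH_LENGTH,
}


@dataclass
class PwmModel:
    """Column-stochastic per-position base probabilities plus background."""

    kind: str
    probs: np.ndarray  # (length, 4)
    background: np.ndarray  # (4,)

    @property
    def length(self) -> int:
        return self.probs.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=1))

    @property
    def log_odds(self) -> np.ndarray:
        return np.log2(self.probs / self.background)

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    def to_json(self, path: str | Path) -> None:
        obj = {
            "kind": self.kind,
            "probs": self.probs.tolist(),
            "background": self.background.tolist(),
        }
        Path(path).write_text(json.dumps(obj, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "PwmModel":
        obj = json.loads(Path(path).read_text())
        return cls(
            kind=obj["kind"],
            probs=np.asarray(obj["probs"], dtype=float),
            background=np.asarray(obj["background"], dtype=float),
        )


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_BASE_INDEX[b] for b in seq.upper()], dtype=np.int64)
    except KeyError as exc:
        raise ClipspliceError(f"ambiguous or invalid base {exc} in {seq!r}") from None


def train_pwm(
    sequences: Sequence[str],
    kind: str = "donor",
    pseudocount: float = 1.0,
    background: Sequence[float] | None = None,
) -> PwmModel:
    """Train a PWM from aligned site sequences with a per-cell pseudocount."""
    if len(sequences) < 2:
        raise ConfigError("PWM training needs at least 2 sequences")
    length = len(sequences[0])
    expected = SITE_LENGTHS.get(kind)
    if expected is not None and length != expected:
        raise ConfigError(f"{kind} sites must be {expected}-mers, got {length}")
    counts = np.zeros((length, 4), dtype=float)
    for seq in sequences:
        if len(seq) != length:
            raise ConfigError(
                f"training sequences have unequal lengths ({len(seq)} != {length})"
            )
        idx = _encode(seq)
        counts[np.arange(length), idx] += 1
    probs = (counts + pseudocount) / (len(sequences) + 4 * pseudocount)
    bg = (
        np.full(4, 0.25)
        if background is None
        else np.asarray(background, dtype=float)
    )
    if not np.isclose(bg.sum(), 1.0):
        raise ConfigError("background probabilities must sum to 1")
    return PwmModel(kind=kind, probs=probs, background=bg)


def score_site(model: PwmModel, sequence: str, on_ambiguous: str = "error") -> float:
    """Log2-odds score (bits) of a single site against the background."""
    if len(sequence) != model.length:
        raise ConfigError(
            f"sequence length {len(sequence)} != model length {model.length}"
        )
    lo = model.log_odds
    total = 0.0
    for i, base in enumerate(sequence.upper()):
        j = _BASE_INDEX.get(base)
        if j is None:
            if on_ambiguous == "skip":
                continue
            raise ClipspliceError(f"ambiguous base {base!r} at position {i}")
        total += lo[i, j]
    return float(total)


# ---------------------------------------------------------------------------
# Site sequence extraction
# ---------------------------------------------------------------------------


def donor_sequence(genome: Mapping[str, str], intron: Intron) -> str:
    chrom = str(genome[intron.chrom][:])
    if intron.strand == "+":
        return chrom[intron.start - DONOR_EXONIC : intron.start + DONOR_INTRONIC]
    d = intron.end  # one past the first intronic base on '-'
    return revcomp(chrom[d - DONOR_INTRONIC : d + DONOR_EXONIC])


def acceptor_sequence(genome: Mapping[str, str], intron: Intron) -> str:
    chrom = str(genome[intron.chrom][:])
    if intron.strand == "+":
        return chrom[intron.end - ACCEPTOR_INTRONIC : intron.end + ACCEPTOR_EXONIC]
    return revcomp(chrom[intron.start - ACCEPTOR_EXONIC : intron.start + ACCEPTOR_INTRONIC])


def intron_sequence(genome: Mapping[str, str], intron: Intron) -> str:
    seq = str(genome[intron.chrom][intron.start : intron.end])
    return seq if intron.strand == "+" else revcomp(seq)


def branch_windows(intron_seq: str) -> list[str]:
    """Candidate branch heptamers with end 18-44 nt upstream of the 3' end."""
    n = len(intron_seq)
    lo, hi = BRANCH_SEARCH
    out = []
    for d in range(lo, hi + 1):
        end = n - d  # exclusive end of the heptamer
        start = end - BRANCH_LENGTH
        if start >= DONOR_INTRONIC:
            out.append(intron_seq[start:end])
    return out


def canonical_branch_window(intron_seq: str, end_offset: int = 25) -> str | None:
    """The heptamer ending ``end_offset`` nt upstream of the intron 3' end.

    Used as the PWM training window; the modal mammalian branch point sits
    in this range.
    """
    end = len(intron_seq) - end_offset
    if end - BRANCH_LENGTH < DONOR_INTRONIC:
        return None
    return intron_seq[end - BRANCH_LENGTH : end]


def best_branch_score(model: PwmModel, intron_seq: str) -> float:
    windows = branch_windows(intron_seq)
    if not windows:
        return float("nan")
    return max(score_site(model, w) for w in windows)


# ---------------------------------------------------------------------------
# Feature table and stratified comparisons
# ---------------------------------------------------------------------------

FEATURES = ("donor_score", "acceptor_score", "branch_score", "length", "gc")


def train_site_models(
    genome: Mapping[str, str], introns: Sequence[Intron], pseudocount: float = 1.0
) -> dict[str, PwmModel]:
    donors = [donor_sequence(genome, i) for i in introns]
    acceptors = [acceptor_sequence(genome, i) for i in introns]
    branches = [
        w
        for i in introns
        if (w := canonical_branch_window(intron_sequence(genome, i))) is not None
    ]
    return {
        "donor": train_pwm(donors, "donor", pseudocount),
        "acceptor": train_pwm(acceptors, "acceptor", pseudocount),
        "branch": train_pwm(branches, "branch", pseudocount),
    }


def intron_feature_table(
    genome: Mapping[str, str],
    introns: Sequence[Intron],
    models: Mapping[str, PwmModel] | None = None,
):
    """Per-intron feature table: PWM scores in bits, length, GC, percentiles."""
    import pandas as pd

    if models is None:
        models = train_site_models(genome, introns)
    rows = []
    for intron in introns:
        iseq = intron_sequence(genome, intron)
        rows.append(
            {
                "intron": f"{intron.chrom}:{intron.start}-{intron.end}:{intron.strand}",
                "gene_id": intron.gene_id,
                "donor_score": score_site(models["donor"], donor_sequence(genome, intron)),
                "acceptor_score": score_site(
                    models["acceptor"], acceptor_sequence(genome, intron)
                ),
                "branch_score": best_branch_score(models["branch"], iseq),
                "length": intron.length,
                "gc": (iseq.upper().count("G") + iseq.upper().count("C")) / len(iseq),
            }
        )
    table = pd.DataFrame(rows).set_index("intron")
    for feature in FEATURES:
        table[f"{feature}_pct"] = table[feature].rank(pct=True) * 100
    return table


def median_strength_partition(
    table, features: Sequence[str] = ("donor_score", "acceptor_score", "branch_score")
) -> tuple[list[str], list[str]]:
    """Introns with all listed features above vs below their medians."""
    medians = {f: table[f].median() for f in features}
    above = table.index[np.all([table[f] > medians[f] for f in features], axis=0)]
    below = table.index[np.all([table[f] < medians[f] for f in features], axis=0)]
    return list(above), list(below)


@dataclass
class RankTestResult:
    statistic: float
    pvalue: float
    n_a: int
    n_b: int
    method: str


def stratify_and_compare(
    values_a: Iterable[float], values_b: Iterable[float], exact_max_n: int = 10
) -> RankTestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test between two groups.

    Exact when both groups have at most ``exact_max_n`` observations and
    there are no ties; otherwise the tie-corrected normal approximation.
    """
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ConfigError("rank-sum comparison requires two non-empty groups")
    combined = np.concatenate([a, b])
    has_ties = np.unique(combined).size < combined.size
    if a.size <= exact_max_n and b.size <= exact_max_n and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return RankTestResult(
        statistic=float(res.statistic),
        pvalue=float(min(res.pvalue, 1.0)),
        n_a=int(a.size),
        n_b=int(b.size),
        method=method,
    )
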