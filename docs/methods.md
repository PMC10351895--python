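# Methods

## Coordinate conventions

All internal coordinates are 0-based half-open; GTF I/O converts to the
format's 1-based closed convention. The *donor* of an intron is its first
intronic base in transcript orientation (`start` on '+', `end − 1` on '−');
the *acceptor* is the last intronic base. In all donor-anchored profiles,
offset 0 is the first intronic base and exonic (upstream) positions are
negative, so a signal "30 nt upstream of the 5′SS" sits at offset −30 on
either strand.

## Synthetic data generator

The generator produces a toy genome, a matching GTF, and pre-aligned
CLIP/RNA-seq SAM files, plus machine-readable truth tables. It emulates
the statistical structure the analysis assumes, not sequencing physics.

**Gene architecture.** Genes of 2–4 exons (150–300 nt) separated by
introns drawn from a two-component length mixture (defaults: 40% in
300–900 nt, 60% in 1200–2600 nt, so both sides of the 1-kb analysis
threshold are populated). Genes are placed with 1-kb flanks on synthetic
chromosomes; strand is random. Contaminant references (rRNA and the
snRNAs U1/U2/U4/U5/U6) are separate sequences with approximately
realistic lengths.

**Donor strength classes.** Every intron gets a donor 9-mer planted as
the canonical CAG|GTAAGT consensus with class-specific mismatches
(defaults: consensus = 0, medium = 1, weak = 2 mismatches). Mismatch
positions are *disjoint* between classes. This matters: if two classes
shared a mismatch position, the substituted base could become the majority
base at that position in a PWM trained on all annotated donors, and the
trained score would no longer decrease monotonically with mismatch count.
With disjoint positions the consensus base keeps the plurality at every
position and the classes separate perfectly by construction. Positions
+1/+2 (GT) are never mutated, so all introns remain GT…AG. Acceptor
(polypyrimidine + CAG) and branch-point (TACTAAC, ending 25 nt upstream
of the 3′ end) motifs are planted with small random per-intron
perturbations so 3′-side strength features vary across the transcriptome
without carrying class information.

**CLIP reads.** Each library draws contaminant reads (default ~13% of the
library), a uniform gene-body background (default 25% of gene-derived
reads; real CLIP libraries always carry diffuse non-specific signal, and
the candidate peak caller's percentile threshold is only meaningful
against such a background), and donor-targeted reads. A targeted read
picks a bound intron, decides spliced vs unspliced from the per-class
spliced fraction, and draws a cross-link offset from Normal(−mean, sd)
(default mean 30 nt upstream, sd 3). The cross-link nucleotide is placed
uniformly within the read. This choice is deliberate: it makes the
per-base coverage kernel around a cross-link triangular with its apex at
the cross-link, so the averaged coverage metaprofile peaks exactly at the
configured offset. Anchoring reads at an end (or centering them) instead
produces a flat-topped plateau whose argmax is undefined at base
resolution. Spliced reads crossing the junction are emitted with a gapped
CIGAR whose gap is exactly the intron (or the cryptic-donor junction when
a planted cryptic donor is used).

**RNA-seq reads.** A read picks a gene (expression weights uniform in WT),
then samples a molecule: each intron is independently retained with its
condition-specific retention probability, spliced introns may use a
planted cryptic donor, and the position is uniform along the molecule.
Knockout conditions multiply the retention of planted-class (weak)
introns by `2^planted_intron_log2fc` (default 1.5, capped at retention 1)
and down-weight the expression of genes hosting planted introns by
`2^planted_gene_log2fc` (default −0.5). The gene-level down-regulation
models the degradation of mis-spliced transcripts and is what makes the
"up-regulated intron inside a non-up-regulated gene" selection reachable
at all; without it, increased intron retention alone drags host-gene
counts upward.

**Determinism.** All randomness flows from `config.seed` through fixed
`numpy` generator substreams (layout, contaminants, one per library), so
identical configs give byte-identical FASTA/GTF/SAM/TSV outputs.

**What the generator does not model** (and what passing tests therefore do
not show about real data): sequencing errors and quality scores,
paired-end reads, fragment-length distributions, alignment ambiguity
(every simulated read is emitted as a unique, perfectly placed alignment),
overlapping genes and alternative isoforms (one transcript per gene), and
PCR duplication. The read-preprocessing and categorization code paths are
exercised with synthetic truth labels rather than realistic error modes.

## Expressed-set selection

Genes with positive abundance and transcripts with positive abundance are
kept; donors are deduplicated across kept transcripts, and each donor site
keeps its shortest containing intron for feature analyses. On synthetic
data the abundance tables are raw WT read counts: any positive-scaling
unit (FPKM/TPM) preserves a "> 0" threshold, so the unit is irrelevant to
the rule. Both the gene and the transcript filter must pass for a donor
to count. Real-data mode accepts externally computed abundance tables.

## Junction classification and cryptic-site detection

A donor-overlapping read is **spliced** when one of its junction gaps
coincides exactly with the annotated intron, **unspliced** when it is
contiguous across the exon|intron boundary with at least `k = 5` aligned
nt on each side, and ignored otherwise. The overhang guards against
alignment-edge artifacts; it is configurable. The per-donor ratio table
keeps donors of introns >1 kb with ≥50 reads in ±100 bp over all samples
(all overlapping reads are counted, not only boundary-crossing ones) and
with both spliced and unspliced totals >10 — the conjunctive reading of
the count rule; a flag switches to the looser either-count rule.

Novel events are junction gaps sharing exactly one annotated edge: a
shared acceptor edge with a different donor edge is a novel 5′SS (the
symmetric case a novel 3′SS); retained-intron events use the
unspliced/spliced counts as inclusion evidence. Each event is tested with
a two-sided Fisher exact test on the pooled 2×2 table (alternative vs
annotated junction reads × condition), BH-corrected over all events with
>30 reads, and kept at FDR <0.01 with |Δ inclusion| >0.1. This is a
deliberate desk-scale surrogate for a likelihood-ratio splicing model
(e.g. rMATS): it reproduces the selection thresholds and decisions, not
another tool's exact p-values, and pooling replicates discards
between-replicate variance.

## Signal profiles and peaks

Coverage matrices use full read footprints of uniquely mapping,
sense-strand reads (a flag switches to literal genomic-forward strand, or
to 5′-end-only counting as a cross-link proxy), scaled to counts per
million uniquely mapped reads and averaged across replicates. Row
ordering is stable descending by a reference key so one sample's order
can be applied to another. Metaplot peaks break ties toward the smallest
offset and flag all-flat profiles as degenerate.

Candidate peaks are maximal runs of coverage ≥ a threshold (default: the
90th percentile of nonzero coverage of the track); the discriminating
layer is the reproducibility filter: overlap with the other replicate,
width >35 nt (strict), and >5 reads (strict, both replicates combined)
within ±25 nt of the candidate's own center. Surviving candidates are
merged into union intervals. An intron is a *target* when a kept peak
intersects `[donor − 100, donor + 50)` in transcript orientation — the
window is not dictated by the upstream literature, so it is explicit and
configurable; the default covers the observed binding footprint (peak at
−30 with an intronic tail).

## Splice-site strength

Position weight matrices with pseudocount 1 and a uniform background are
trained on the annotated sites of the expressed transcriptome; scores are
log₂-odds sums in bits. The branch-point score is the best heptamer
whose last base lies 18–44 nt upstream of the intron 3′ end — a bounded
search matching known branch-point positioning; the training windows are
taken at the modal position (25 nt). These PWMs replace external
maximum-entropy scorers: they are self-contained and preserve the rank
structure every downstream comparison uses, but absolute values are not
comparable to other scorers, and independence between positions is
assumed. Group comparisons use the two-sided Wilcoxon rank-sum test,
exact when both groups have ≤10 untied observations and the tie-corrected
normal approximation otherwise.

## Differential expression

Counting follows standard summarization rules: gene mode assigns a
uniquely mapped, correctly stranded read overlapping exactly one gene by
≥1 nt; intron mode requires ≥10 nt of aligned overlap and allows
multi-feature assignment. Simulated libraries are sense-stranded, so the
default strandedness is "sense"; a "reverse" mode covers real
reverse-stranded chemistry.

The test is a negative-binomial Wald test: median-of-ratios size factors;
per-feature method-of-moments dispersion estimates moderated through a
least-squares mean–dispersion trend `α(μ) = a₀ + a₁/μ` fitted across all
features (raw, possibly negative, moment estimates enter the fit so it is
unbiased; only fitted values are floored at 10⁻⁸); Wald statistic
log₂FC / SE against a standard normal; BH adjustment over features passing
the minimum-total-count prefilter (genes 200, introns 110; CHX designs
80/40; ribosome-profiling genes 10). The trend moderation is essential
with two replicates per condition, where per-feature moment estimates are
mostly noise and flooring them would inflate type-I error; with the trend
the null rejection rate is calibrated (checked by simulation in the test
suite). Zero group means are floored at half a size-factor-scaled read.
Thresholds: genes padj <0.01 and |log₂FC| >1; introns padj <0.05 and
|log₂FC| >0.5. *Mis-spliced* introns are up-regulated introns whose host
gene has log₂FC <0 (unthresholded — the selection restricts to
non-activated transcription, not to significantly down genes). This
estimator reproduces the decision logic of a DESeq2-based analysis, not
DESeq2's shrinkage estimators or exact p-values.

## Pipeline

`run_pipeline` executes simulate → classify → junctions → profile →
peaks → strength → introndiff → novel with all stage defaults equal to
the thresholds above, writes per-stage TSV/BED artifacts, a
deterministic `metrics.json` (sorted keys, floats rounded to 10 decimal
places) and a log of the effective configuration. Stage toggles drop a
stage and every metric depending on it while leaving upstream metrics
unchanged. In the bundled demo and test configurations the simulation
sizes (10–100 genes, 3,000–40,000 reads per library) are chosen so the
count prefilters and peak filters operate in the same regime as a
genome-scale analysis while a full run stays in the minutes range on a
single core.

## Known limitations

- The read categorization's "mRNA" tier uses generator truth labels in
  synthetic mode; with real data it expects the id sets of an external
  alignment cascade.
- `run_pipeline` wires only the synthetic path end to end; real
  alignments are analysed through the per-stage CLI commands or library
  calls.
- Fisher-based event testing pools replicates; with strong
  between-replicate variability it is anticonservative relative to a
  replicate-aware model.
- PWM scores assume positional independence; donors with strong
  interdependencies (e.g. +4/+5 compensation) are ranked only
  approximately.
- The NB-Wald test relies on the cross-feature dispersion trend; with
  very few features (<~50) the trend itself is poorly estimated.
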