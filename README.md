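# clipsplice

Analysis toolkit for studying RNA-binding proteins that act at 5′ splice
sites (5′SSs), written for the kind of experiment where CLIP-seq maps where
a splicing factor contacts pre-mRNA and RNA-seq of knockout cells shows
which introns fail to splice without it. The package answers four
questions end to end:

1. **Where does the protein bind?** Per-base CLIP coverage anchored at
   annotated donors (±200 nt, cpm-normalized, replicate-averaged) as
   heat-map matrices and metaplots, plus hierarchical read triage
   (rRNA → mRNA → genome) and snRNA occupancy profiles.
2. **Does it bind spliced or unspliced RNA?** Donor-overlapping reads are
   classified as spliced (junction gap exactly matching an annotated
   intron) or unspliced (contiguous read across the exon|intron boundary,
   ≥5 nt overhang each side), with the per-donor log₂(spliced/unspliced)
   ratio table filtered as in the study design (introns >1 kb, ≥50 reads in
   ±100 bp, both counts >10).
3. **Which introns does it regulate?** Reproducible CLIP peaks (inter-
   replicate overlap, width >35 nt, >5 combined reads in a 50-bp window)
   define *target introns*; a negative-binomial Wald test with
   median-of-ratios normalization flags introns up-regulated in knockout
   (padj <0.05, log₂FC >0.5) inside non-up-regulated genes (log₂FC <0).
4. **Is 5′SS choice affected?** Junction gaps sharing an annotated
   acceptor but not the donor are cryptic (novel) 5′SS events, tested per
   intron with a 2×2 Fisher test and kept at FDR <0.01, inclusion-level
   difference >0.1 and >30 reads.

Splice-site strength is scored with log-odds position weight matrices
trained on the annotated transcriptome: donor 9-mers (3 exonic + 6
intronic), acceptor 23-mers (20 + 3) and the best branch-point heptamer
18–44 nt upstream of the 3′ end, with scores in bits,
`score(s) = Σᵢ log₂ p(sᵢ|i) / q(sᵢ)`.

A first-class synthetic-data generator emulates the whole study: genes
with planted donors of graded strength, condition-specific spliced
fractions, CLIP cross-links at a configurable offset upstream of donors,
contaminant reads, and knockout effects planted only in weak-donor
introns — so every stage is verifiable against ground truth without any
downloads. Real aligned data (SAM/BAM + FASTA + GTF) can be fed to each
stage through the CLI or the library functions.

## Worked example

```sh
clipsplice run --seed 21 --outdir demo
```

simulates two conditions (WT, KO) × two replicates of CLIP and RNA-seq
over 40 genes and runs every stage. `demo/metrics.json` then contains,
among others:

```json
"profile":   {"WT": {"peak_offset": -30}, "KO": {"peak_offset": -30}},
"strength":  {"donor_consensus": "CAGGTAAGT"},
"introndiff": {"KO": {"introns_up": 28,
                      "misspliced": 24,
                      "target_fraction_pct": 28.235,
                      "misspliced_vs_other_targets":
                        {"donor_score_ranksum_p": 1.47e-12,
                         "misspliced_median": 13.85,
                         "other_median": 14.85}}}
```

Read: the CLIP metaprofile peaks 30 nt upstream of the 5′SS (the planted
cross-link mode); the trained donor PWM recovers the canonical CAG|GTAAGT
consensus; 24 introns are up-regulated in KO inside down-regulated genes,
confined to the weak-donor class, so mis-spliced target introns have
significantly weaker donors than unaffected targets (rank-sum
p ≈ 1.5×10⁻¹²).

The same stages are available individually (`clipsplice simulate |
classify | junctions | profile | peaks | strength | introndiff`) and as
library functions (`clipsplice.signal_profile`, `clipsplice.junctions`,
`clipsplice.intron_de`, ...).

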