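# firstintron

Analysis of evolutionary conservation and regulatory chromatin in the
**first introns** of multi-exon genes.

First introns are unusual: they are the longest introns, they carry more
blocks of conserved sequence than any downstream intron, and they are
enriched for marks of active regulatory chromatin (DNase I
hypersensitivity, transcription-factor binding, H3K4me1/H3K4me3), a
pattern consistent with purifying selection acting on intronic regulatory
elements. This package implements the full analysis needed to quantify
that pattern from standard genomics inputs — gene models (GTF/BED12), a
per-base conservation score track (bedGraph/wiggle, e.g. PhastCons), a
repeat mask (BED), peak sets per regulatory mark (BED/narrowPeak) and an
expression table (TSV of log2(RPKM+1)) — together with a synthetic-genome
generator that plants every effect the analysis is meant to detect, so the
whole pipeline can be validated end to end by parameter recovery.

## What it computes

For each transcript, introns are extracted and ranked by ordinal position
from the 5' end (the first intron is ordinal 1). The cohort filters follow
the standard protocol: introns shorter than 1 kb are dropped, introns
longer than Q3 + 1.5·IQR of the pooled surviving lengths are dropped as
outliers, 300 bp are trimmed from both intron ends to avoid splicing
signals, and repeat-masked bases are removed. On the remaining *analysis
regions* the package computes:

* **conserved fraction** — the proportion of bases with conservation score
  ≥ 0.5 (inclusive), compared across ordinal groups with Wilcoxon
  rank-sum tests (first vs each group and vs the pooled rest);
* **signal coverage** — the proportion of bases under each mark's peaks,
  and its Kendall tau-b correlation with conservation across first
  introns, smoothed by binning genes into groups of 10 by conservation;
* **exon-count regressions** — OLS of per-group mean conserved fraction
  (or coverage) on the gene's exon count, genes grouped G1 = 2 exons …
  G20 = 21 exons;
* **expression correlations** — tau-b between first-intron conservation
  and expression level per tissue, genes binned in groups of 50;
* **gene-wise log-odds enrichment** — each first intron is partitioned
  into conserved and non-conserved bases and, per mark, a 2×2 base-count
  table (SC, NC, SN, NN) yields `log OR = ln[(SC·NN)/(NC·SN)]` with the
  Woolf-type 95% CI `log OR ± 1.96·√(1/SC + 1/NC + 1/SN + 1/NN)`
  (Haldane–Anscombe 0.5 correction on a single zero cell); the cohort
  tally counts genes significant at p < 0.01 in each direction;
* **confounder controls** — a promoter-spillover filter (drop genes whose
  promoter + first-exon coverage is at least as high as the intron's), an
  overlapping-gene filter (drop first introns intersecting another gene's
  exons or 2 kb flanks), a TSS-distance-matched first-vs-second intron
  comparison inside the 500–1000 bp window where their distances overlap,
  and a five-bin positional scan of where the strongest signal sits along
  the intron.

## Worked example

Generate a 500-gene synthetic bundle with planted effects, then run the
full report:

```bash
firstintron simulate --n-genes 500 --seed 4 --outdir demo
firstintron report \
    --gtf demo/genes.gtf --conservation demo/conservation.bedGraph \
    --mask demo/repeats.bed --expression demo/expression.tsv \
    --peaks DHS=demo/peaks_DHS.bed --peaks TFBS=demo/peaks_TFBS.bed \
    --peaks H3K4me1=demo/peaks_H3K4me1.bed --peaks H3K4me3=demo/peaks_H3K4me3.bed \
    --peaks H3K9me3=demo/peaks_H3K9me3.bed --peaks CTCF=demo/peaks_CTCF.bed \
    --outdir demo_out
```

`demo_out/ordinal_conservation.tsv` shows the ordinal decay of
conservation (medians 6.6% → 3.9% → 1.8% → 0.4% over ordinals 1–4):

```
ordinal  n    median     q1         q3        mean
1        286  0.0664432  0.0396333  0.09749   0.0760445
2        418  0.0393961  0.0158078  0.0773291 0.0525929
3        384  0.0179314  0          0.0441691 0.0306759
4        345  0.00360918 0          0.0240101 0.0186724
```

`demo_out/signal_correlations.tsv` gives the conservation–signal Kendall
correlations in first introns (binned in groups of 10 genes, raw pairs
alongside): active marks correlate positively (binned tau ≈ 0.83 for DHS,
0.82 for H3K4me3, 0.83 for TFBS, all p < 1e-12), the repressive mark
H3K9me3 weakly negatively (−0.39), CTCF not at all (−0.13, p = 0.34).

`demo_out/odds_tally.tsv` is the gene-wise enrichment tally — of 279
testable genes, 265 are significantly (p < 0.01) enriched for DHS in the
conserved part of their first intron and 0 in the non-conserved part,
while H3K4me1 skews the other way (0 vs 47):

```
mark     n_total  n_sig_positive  n_sig_negative
CTCF     279      4               0
DHS      279      265             0
H3K4me1  279      0               47
H3K4me3  279      247             0
H3K9me3  279      0               9
TFBS     279      253             0
```

The remaining tables cover the exon-count regressions, expression
correlations, both exclusion filters (with audit logs), the TSS-matched
comparison and the positional-bias scan. Every table starts with a
provenance header (`# firstintron run config=… seed=…`).

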