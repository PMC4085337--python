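# Methods

## Coordinates and interval arithmetic

All region math is done on 0-based half-open intervals; GTF input
(1-based inclusive) is converted on read, BED is native. Merge,
intersection and subtraction operate on sorted numpy arrays of
starts/ends; touching intervals are fused and empty intervals dropped.
These primitives are the foundation of every measured fraction, so the
test suite checks them (and everything built on them: conserved fraction,
peak coverage, conservation partition, the gene-wise 2×2 table) against
per-base set-arithmetic oracles on hundreds of randomized instances.

## Cohort assembly

Introns are the gaps between consecutive exons of a transcript, ranked
from the transcript's 5' end; on the minus strand the genomically
rightmost gap is ordinal 1. Filters run in this order:

1. **length floor** — raw length < 1 kb removed (inclusive at the
   boundary: exactly 1 kb survives);
2. **outlier ceiling** — raw length > Q3 + 1.5·IQR removed, with the
   quartiles computed by linear interpolation over the *pooled*
   post-floor lengths of all ordinals (no per-ordinal stratification);
   the comparison is strictly greater, so with zero IQR nothing is
   removed. Because re-applying this rule to its own output lowers Q3 and
   can remove more introns, the filter is a single pass, not a fixpoint;
3. **end trim** — 300 bp removed from both genomic ends, to keep splice
   regulatory signals out of the conservation estimate;
4. **repeat handling** — default `mask` mode subtracts repeat-masked
   bases from the analysis regions; a stricter `drop` mode discards any
   intron whose trimmed body overlaps a repeat. Both are exposed
   (`--repeat-mode`); `mask` is the default.

A transcript whose first intron fails the filters is excluded from
first-intron analyses, but its other introns still contribute to their
ordinal groups. Gene-keyed analyses (expression, gene-wise odds,
controls) use one representative transcript per gene: most exons, ties
broken by genomic span, then lexicographically smallest transcript id
(the choice of rule is a convention; any deterministic rule would do).
Flanks are 2 kb beyond the first/last exon, clipped at position 0; the
upstream flank proxies the promoter. TSS distance of an intron is the
unspliced genomic distance from the first exon's 5' start to the
intron's 5' boundary.

## Conservation and coverage

A score track is a sparse set of step intervals; bases without a step
score 0, matching the distribution format of genome-wide conservation
tracks where unaligned bases are absent. A base is conserved when its
score is ≥ the threshold (0.5 by default, inclusive, raw float compare —
no rounding). Conserved fraction and peak coverage are exact base counts
via interval intersection; a region with zero analysable bases yields NaN
(never 0/0 → 0) and is excluded downstream. Replicate peak files for one
mark/cell line are merged by union; different cell lines are never
merged.

## Statistics

* **Rank-sum tests** use exact enumeration for ≤ 10 per side without
  ties, otherwise the normal approximation with tie correction; with all
  observations tied the one-sided p is 1. Ordinal comparisons report
  first-vs-each-group and first-vs-pooled-rest p-values (both, because
  either reading of "higher than all other groups" is defensible).
* **Kendall tau-b** (tie-corrected) is computed on both the binned means
  and the raw pairs; the binned value mirrors the smoothing used for
  presentation (bins of 10 genes by conservation, 50 by expression), the
  raw value is the statistically stable one — with bins of 10 over ~10³
  genes the binned series has only ~10² points and a null sampling sd of
  ≈ 0.07–0.09, so calibration claims are made on the raw statistic.
  Pairs where both variables are exactly 0 are dropped by default
  (regions with neither conservation nor signal carry no information;
  retaining them only strengthens positive associations, and a flag
  allows it). The incomplete trailing bin is dropped.
* **Exon-count regressions** regress the per-group *mean* value on the
  exon count itself (2…21), so slopes are per-exon; groups beyond
  max_group are discarded; fewer than two non-empty groups yields NaN.
* **Gene-wise enrichment** builds the 2×2 table in *bases* (SC/NC/SN/NN),
  not peak counts — the odds ratio is defined on the proportion of
  signal-covered sequence, and base counting is the only unit that makes
  the table and the ratio consistent. `log OR` gets a Woolf-type CI and
  Wald p; one zero cell triggers the Haldane–Anscombe +0.5 correction
  (flagged per gene), two or more zero cells make the gene undefined and
  excluded from tallies. Significance for the tally is p < 0.01 while the
  CI is 95%; both are reported as is (they answer different questions).
  No multiple-testing correction is applied anywhere, by design.

## Confounder controls

* **Spillover filter**: per mark, a gene is kept only when its
  first-intron coverage strictly exceeds the pooled coverage of the
  union of its 2 kb promoter and first exon ("at least as high" excludes,
  so 0 vs 0 excludes). The pooled-region reading (one fraction over the
  union) was chosen over max-of-two-fractions.
* **Overlap filter**: a gene is dropped when its raw first intron
  intersects any exon or any 2 kb flank of a different gene.
* **TSS-matched comparison**: introns with TSS distance in [500, 1000]
  (both edges inclusive) are split into five 100 bp bins (the edges are a
  declared default, configurable); per bin, medians and a one-sided
  rank-sum p (first > second) are reported, omitted below 3 introns per
  side.
* **Positional bias**: first introns at or above the cohort median raw
  length are cut into five equal bins of their trimmed span (5'→3' in
  transcript orientation); the bin with the highest signal density
  (coverage for peaks, mean score for tracks) is recorded, ties resolved
  to the 5'-most bin; introns with no signal are skipped and counted.
  Fractions sum to 1 over non-skipped introns.

## Synthetic genome generator

The generator emits GTF + bedGraph + BEDs + TSV + a truth JSON through
the same readers the pipeline uses on real data, with all structure
planted and parameterized:

* **Gene structure.** Exon counts are 2 + a negative binomial (n = 3,
  p = 0.3), truncated at 25. First-intron lengths are a lognormal
  mixture — 75% long (median 7 kb, σ = 0.4) and 25% short (median 400 bp,
  σ = 0.6); downstream introns are lognormal (median 2.3 kb, σ = 0.7).
  The short subpopulation matters: only genes with a sub-kb first intron
  put *second* introns into the 500–1000 bp TSS-distance window, so the
  matched comparison has data on both sides, as in real annotation (the
  short first introns themselves fall to the 1 kb floor). Genes are laid
  out on 8 chromosomes with 6 kb intergenic gaps — no overlaps unless
  nested genes are requested to exercise the overlap filter. Optional
  shorter second isoforms exercise representative-transcript selection.
* **Conservation.** Blocky, not i.i.d.: alternating conserved blocks
  (geometric lengths, mean 40 bp, scores U[0.5, 1]) and sub-threshold
  decoy blocks (scores U[0.05, 0.45], rate 0.04) from a stationary
  renewal process, so the downstream interval logic is exercised by
  realistic block structure. Per-base conserved occupancy is c₁ > c₂ >
  c₃ > c₄ = c₅ … with defaults (0.08, 0.05, 0.03, 0.02); the first-intron
  rate is modulated per gene by a lognormal propensity (σ = 0.5). Exons
  carry high conservation (0.4), flanks low (0.03).
* **Couplings.** Intron-1 conservation is realized *first*; exon counts
  and expression are then drawn by Gaussian copula against the normal
  scores of the realized trimmed conserved fraction (ρ = sin(πτ/2),
  defaults τ = 0.3 for both), with normal scores taken within each
  length stratum so the coupling is homogeneous across the short/long
  mixture rather than concentrated in the high-dispersion short genes.
  Coupling to the realized (measurable) fraction rather than the latent
  propensity means recovery is limited only by mask subtraction and
  tissue noise, not by block-sampling attenuation. Expression is
  monotone in the coupled latent plus per-tissue noise (σ = 0.3),
  reported as log2(RPKM+1) for four pseudo-tissues.
* **Regulatory marks.** Inside raw first introns the signal indicator is
  per-base i.i.d.: rate p₀ on non-conserved bases (per mark) and p₁ on
  conserved bases with logit(p₁) = logit(p₀) + λ, so the planted log-odds
  λ is realized exactly and the per-base 2×2 sampling model of the Wald
  test is correct — block-correlated placement would inflate the Wald z
  by roughly √(2·width) and destroy type-I calibration, which is exactly
  the property the null cohort is used to verify. Outside first introns,
  peaks are a blocky renewal process with mark-specific mean widths
  (narrow: DHS 150, TFBS 200, CTCF 300, H3K4me3 400; broad: H3K4me1 800,
  H3K9me3 900 bp), so detectability asymmetries of broad marks can still
  be studied everywhere the gene-wise test does not look. Default planted
  log-odds follow the qualitative pattern expected of active vs
  repressive marks: DHS/TFBS +1.0, H3K4me3 +0.8, H3K4me1 −0.4,
  H3K9me3 −0.3, CTCF 0. An optional elevated first-intron background
  rate per mark plants the "signals highest in first introns" pattern.
* **Null mode** zeroes every planted effect: flat ordinal conservation,
  λ = 0, no elevated first-intron rates, τ = 0.
* **Repeats** are a stationary renewal mask (density 0.08, mean 250 bp)
  placed independently of everything else.
* **Spillover spiking** appends, per chosen gene, one peak covering the
  promoter, first exon and 5' half of the first intron, guaranteeing the
  spillover filter must exclude it.

Identical configs and seeds produce byte-identical bundles (single RNG
stream, fixed draw order, fixed formatting), and identical pipeline runs
produce byte-identical tables.

### What the generator does and does not emulate

It reproduces the statistical structure the analysis assumes — ordinal
conservation decay, conservation-coupled signal placement, exon-count and
expression couplings, length asymmetries between first and later introns
— but not genome realism: no nucleotide sequence, no GC or repeat-family
structure, no real chromosome lengths, no promoter-biased H3K4me3 by
default, and first-intron signal without peak-width structure (see
above). Passing recovery tests therefore demonstrates correctness of the
measurement and inference machinery under the assumed data-generating
model, not robustness to every artefact of real epigenomic data (peak
autocorrelation in particular makes the real gene-wise Wald test
anticonservative, which is worth remembering when reading such tallies).

## Problem sizes and numerical choices

Validation runs use a 2000-gene planted cohort, a 1000-gene null cohort
and a 300-gene spillover cohort — large enough that every recovery
tolerance is several sampling sds wide (e.g. positional-bias fractions:
sd ≈ 0.017 at ~560 introns against a ±0.05 band) while the whole suite
runs in a couple of minutes on one CPU. Quantiles use linear
interpolation throughout (the numpy default), matching the documented
outlier rule. Undefined values are NaN sentinels, never silent zeros.
Ties in positional bins resolve 5'-ward; ties in representative selection
resolve to the smaller transcript id; rank-sum ties take the corrected
normal approximation.

## Known limitations

* The outlier ceiling depends on the cohort composition (pooled lengths),
  so adding or removing transcripts changes which introns survive.
* The gene-wise Wald test inherits the per-base independence assumption;
  on real data with wide peaks its p-values are optimistic (see above).
* The spillover filter compares noisy coverage fractions; for marks with
  broad peaks the promoter estimate is high-variance and the filter
  removes a visible share of clean genes — harmless for trend checks,
  but the exclusion logs should be consulted before gene-level claims.
* Multiple transcripts per gene are handled by representative selection
  only; no isoform-aware intron deduplication is attempted.
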