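# Methods

`florastage` re-implements, as a tested library, the analysis chain of a
stage-resolved bulk RNA-seq study of *Arabidopsis* flower development: one
sequencing library per stage (inflorescence meristem, early flowers, stage-4
flowers, near-mature flowers, seedlings, male meiocytes), quantified to RPKM,
compared pairwise with Fisher's exact test, summarized by Z-score
specificity profiles, triangulated against EST and array evidence, and mined
for gene-family structure.

## Quantification

RPKM for gene *g* in sample *s* is

    RPKM_gs = 10^9 · C_gs / (N_s · L_g)

with *C* the uniquely mapped read count, *N* the total mapped reads of the
library and *L* the cDNA length (bp) of the gene's longest splice variant.
No effective-length or GC correction is applied. A gene is "expressed" in a
sample when *C* ≥ 10 reads (configurable `min_reads`); the union over
samples is the organ-wide expressed set. Log transformation is
log2(RPKM + pseudocount) with pseudocount 1.0 by default — the value is a
package choice (it keeps zeros finite and preserves ordering) and is
exposed everywhere it matters.

## Differential expression

With a single library per stage there are no replicates, so a gene's
differential status between two stages is tested by Fisher's exact test on
the 2×2 table `[[C_a, N_a−C_a], [C_b, N_b−C_b]]`, two-sided by the standard
convention (sum of the probabilities of all tables at the observed margins
that are no more likely than the observed one). A gene is a DEG at raw
P < 0.01; Benjamini–Hochberg correction is available behind
`bh_correct=True` but off by default to match the uncorrected convention
of single-library designs. Fold changes are computed on RPKM with a
1-RPKM pseudocount, `(a+1)/(b+1)`, so zeros stay finite.

**Known limitation (measured, by design of the test, not a defect of the
implementation):** Fisher's exact test models each library as a binomial
draw and therefore assumes Poisson-level noise. Under negative-binomial
overdispersion `var = μ + 0.1·μ²` the test is strongly anticonservative:
on a simulated null (2,000 genes, two 10^6-read libraries, dispersion 0.1)
the measured fraction of P < 0.01 calls is ≈ 0.31, versus ≈ 0.006 in the
Poisson limit (dispersion → 0), where the test is in fact conservative.
The Poisson-limit rate is the correctness check; the overdispersed rate is
asserted in the test suite as a frozen regression value and documented here
as the known cost of applying Fisher's test to overdispersed libraries.
This is why single-library Fisher comparisons of real stage libraries
produce DEG lists in the thousands.

## Stage-specific genes

A gene is specific to stage *s* at fold *f* when its pseudocounted RPKM
ratio over **every** other stage is strictly greater than *f* **and** its
pairwise Fisher test against every other stage is significant at α = 0.01
(a fold-only mode exists for sensitivity analysis). Sets are nested across
the standard fold ladder 1/2/4/8. Genes are additionally groupable by the
stage of their maximal expression (the D1/D2/D3-style partition); exact
ties go to the earliest stage in the declared order and are logged.

Because the fold condition must hold against every competitor stage
simultaneously, noise sets a hard ceiling on sensitivity: with
negative-binomial dispersion 0.1 (count CV → √0.1 ≈ 0.32) an 8-fold planted
gene passes the >4-fold filter against 5 competitor stages with probability
≈ 0.81 even at arbitrarily high expression (Monte-Carlo of the
gamma–Poisson ratio; ≈ 0.89 with only 2 competitors). Measured end-to-end
sensitivity on the default simulation is ≈ 0.70 with a false-discovery rate
of ≈ 0 — the detection rule is precise but conservative under this noise
level, and no parameter of the pipeline can lift the ceiling without
changing the rule itself.

## Z-score specificity

Z = (X − μ)/σ per gene, where X is the log2(RPKM+1) value in a stage and
μ, σ are the gene's mean and standard deviation across the selected stages.
The input is the log2 scale (the operative convention here; the raw-RPKM
reading would make the score scale-dependent). σ uses the sample (n−1)
denominator by default — with only 3–4 stages the convention is material,
so `ddof=0` is exposed. σ = 0 genes get z = 0 plus a degenerate flag rather
than being dropped, keeping matrices aligned. Histograms use 0.25-wide bins
over the observed range; counts conserve the number of non-degenerate
genes.

## Cross-platform consensus

Three detection technologies are combined as gene sets: RNA-seq
(count threshold), EST support (≥ 1 EST, binary), and tiling array
(intensity above background). The tiling background is derived from the
data: probe-present genes absent from both the RNA-seq and EST sets are
mostly silent DNA — transposons and pseudogenes dominate the set — and
their mean log2 intensity is the expressed/unexpressed threshold.
Intensity calls use strict `>` (the choice is documented and configurable).
Expression microarrays use a fixed log2 background of 5.0 instead. The
three sets are partitioned into the seven Venn regions; "reliably
expressed" is reported under two conventions: membership in ≥ 2 platforms
(the general rule) and the RNA-seq-anchored variant (triple region plus the
two RNA-seq pairwise regions) used for headline totals.

## Families, enrichment, tandem arrays

Families are Pfam-style labels; a gene carrying several domains counts once
in each family. Detection tables report per family the annotated total, the
members inside a gene set, and the fraction rounded half-up to 2 decimals
(matching printed-table precision). Enrichment is a two-sided Fisher's
exact test of family membership against an **explicit** universe parameter
(typically all annotated genes — there is no hidden default population),
uncorrected by default with BH available. Gene-set overlap significance
uses the same test on the 2×2 membership table given a stated universe
size. Tandem arrays — the signature of tandem duplication — are maximal
runs of same-family genes along a chromosome allowing ≤ `max_intervening`
non-family genes (default 1) and an optional bp cap between consecutive
members; only runs of ≥ 2 are reported.

## Synthetic data generator

The generator produces the full input side of the pipeline with planted
truth:

- **Annotation** — gene lengths log-normal (median 1.5 kb, ln-sd 0.6,
  truncated at 200 bp by redraw); genes laid out without overlap along five
  chromosomes (1-based inclusive coordinates) so table adjacency is genomic
  adjacency; gene types coding/transposon/pseudogene at 0.80/0.15/0.05;
  family labels drawn from a configurable catalog; a small fraction of
  coding genes tagged with transcription-factor families.
- **Programs** — baseline expression log-normal on the RPKM scale with
  ln-mean 4.0 and ln-sd 1.5 (median ≈ 55, mean ≈ 170 RPKM), matching the
  tens-to-hundreds RPKM averages reported for detected floral genes.
  Transposons and pseudogenes are scaled down (×0.02 / ×0.05): they are
  transcriptionally silenced in most tissues, which also makes the
  tiling-specific background set transposon/pseudogene-dominated as in real
  flower data. A `specific_fraction` of genes is planted stage-specific:
  the planted stage's true mean is exactly `specific_fold` × the mean
  elsewhere. Planted genes keep their full (un-downscaled) baseline —
  a stage-activated transposon transcribes at ordinary levels, as
  meiocyte-expressed transposons do. One designated family can be forced
  into one stage (`family_specific_bias`), emulating family-coherent
  specificity.
- **Counts** — negative-binomial via a gamma–Poisson mixture with
  `var = μ + dispersion·μ²` (default dispersion 0.1; dispersion → 0 is the
  Poisson limit) and expected count `mean · (L/10^3) · (N/10^6)` — the RPKM
  identity inverted, so RPKM (not raw counts) recovers the program.
  Default library size 10^6 reads per stage.
- **Platform evidence** — EST support Bernoulli with logistic probability
  in log2 expression (slope 2.0, midpoint 1.0); tiling intensity affine in
  log2 expression (floor 5.0, gain 0.5, Gaussian noise sd 0.5, floored at
  the background); microarray intensity likewise for a 0.7 probed fraction.

One root seed drives `numpy.random.SeedSequence` streams spawned in a fixed
order (annotation → programs → counts → evidence), so each stage and the
whole run are reproducible.

**What the generator does not emulate:** read-level artifacts (mapping
bias, multimapping, positional coverage), isoform structure and alternative
splicing, correlated expression programs between adjacent stages, batch
effects between platforms, and probe-level cross-hybridization. Passing
recovery tests therefore demonstrates the pipeline's statistical behaviour
under its stated noise model, not performance on real libraries.

## Numerical and degenerate-input choices

- Fisher P-values come from `scipy.stats.fisher_exact`; the test suite
  checks them against an independent brute-force hypergeometric enumeration
  written from binomial coefficients.
- Fold change of two zeros is defined (= 1) by the pseudocount.
- `stage_specific` evaluates the cheap fold filter first and runs the exact
  tests only on surviving candidates; identical count pairs share one test.
- Percent columns round half-up (not banker's rounding) to match printed
  tables.
- Empty tiling-specific sets make the derived threshold undefined and raise
  rather than guessing.
- Simulated library sizes are raised to the realized column sum in the rare
  case the drawn counts exceed the nominal library, preserving the
  count-sum ≤ library invariant (this rescales simulated RPKM by a common
  per-sample factor and leaves every ratio-based statistic unchanged).

## Problem sizes used in the checks

The bundled verification runs use 5,000-gene × 6-stage simulations for
recovery metrics, 2,000 genes for the null-rate measurement, 40 replicate
800-gene simulations for family-enrichment ranking, and exhaustive 2×2
enumeration up to table total 18 plus randomized margins to 200 for oracle
equivalence — sizes at which every quantity above is stable to well within
the tolerances asserted.
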