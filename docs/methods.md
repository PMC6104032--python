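# Methods

## The breeding scheme and its expectations

A pre-breeding line (PBL) descends from `exotic/elite1//elite2`: an exotic
gene-bank accession is crossed to an elite line, the F1 is topcrossed to a
second elite, and the topcross progeny are selfed `g` generations by
single-seed descent (default g = 4, i.e. TC₁F₁ → TC₁F₅).  With fully
inbred founders this fixes two analytic expectations the package leans on
everywhere:

* the expected exotic genome fraction of a line is **25%** (one gamete of
  the exotic×elite1 F1 contributes half the genome, and half of that
  gamete is exotic on average);
* at loci where the exotic allele differs from the (identical) elite
  alleles, the residual heterozygote rate is **0.5 · 2⁻ᵍ** (the topcross
  individual is heterozygous with probability ½, halved each selfing) —
  3.125% at g = 4.

Any selection during line development removes exotic-linked alleles
preferentially, so realized exotic fractions fall below 25%; the package's
two estimators (SNP-based A/B/H fractions and the block-map imprint) are
designed to quantify exactly that.

## Simulator

**Founders.**  Every founder haplotype is a mosaic deviation from an
elite-pool consensus.  Deviation states follow a two-state jump process
along the cM map: the state resamples at exponentially distributed
distances (scale `elite_segment_cm` = 30 for elites, `exotic_segment_cm`
= 3 for exotics) to Bernoulli(p), so the *marginal* flip probability at
each marker is exactly p while nearby markers co-segregate in tracts.
The segment scales encode the field reality that elite pools share long
identical-by-descent haplotypes from recent breeding ancestry while
gene-bank accessions carry short-range LD; they are what makes "fewer,
larger blocks in elites than in exotics" an emergent property rather than
an assumption.  For elites, p is solved from the configured pairwise
elite–elite difference rate d via 2p(1−p) = d; for exotics p equals the
configured elite–exotic difference rate (default 0.35).

**Meiosis.**  Haldane model: crossover counts per chromosome are
Poisson(length/100), positions uniform on the cM axis, no interference.
Interference is irrelevant at the ~1 cM marker resolution used here.

**Bookkeeping.**  Each line carries two chromatid arrays of founder-origin
labels (exotic / elite1 / elite2) alongside its alleles; every operation
propagates both, so calls can be re-derived from founder genomes plus
truth (a conservation test in the suite does exactly this).  RNG streams
are keyed by (seed, operation, cross, line): adding lines or crosses never
perturbs existing draws.

**Phenotypes.**  value = environment mean + Σ active QTL effects
(homozygous carriers of the QTL allele string; heterozygous or missing at
any QTL marker ⇒ no effect, adequate for panels with ~3% residual
heterozygosity) + polygenic term (a random-marker-effect model, so its
covariance is proportional to the realized genomic relationship) +
N(0, residual).  QTLs are active per environment, which is how the
"advantage under heat, no penalty under irrigation" pattern is planted.

**Selection.**  The real programme's multi-generation "selected bulk" is
approximated by truncation selection on a simulated trait at configurable
retained fractions; bulk-population bookkeeping would add state without
changing the expectations under test.

**The planted scenario** (`planted_scenario`) is the standard test-bed: 6
chromosomes × 200 markers (≈0.75 cM spacing, comparable to a genotyping-
by-sequencing consensus map), 20 crosses × 15 lines = 300 lines.  A
3-marker allele string on chromosome 2 is given to 5 of the 10 exotic
founders — emulating a gene-bank haplotype shared by related donors (as a
wild-relative-derived tract recurring among synthetic wheats would be) —
and to zero elites, making it exotic-private by construction.  Donor
exotics parent half the crosses, so homozygous carriers land at ≈10% of
lines, spread over many small families.  That spread matters: if one
donor parented a few large families, carrier status would be nearly
collinear with genome-wide kinship and the mixed model would rightly
absorb much of the signal; the many-small-families design mirrors the
real programmes (hundreds of lines from >100 crosses) in which rare
haplotypes remain testable.  The planted effect defaults to +1 residual
SD on grain yield under heat only; days to heading is simulated with no
QTL and serves as the confounder scan.

## QC

Order matters and is fixed: lines above the missing-data cutoff (75%)
first, then unmapped markers, MAF < 0.05, the Hardy–Weinberg exact test
(p < 0.001) where applicable, finally co-located markers collapsed to the
first in (cM, id) order.  A panel of selfed inbreds violates HWE at every
marker, so `hwe_mode="skip_inbred"` (default) disables the HWE cut when
the panel heterozygote rate is under 2%; `"apply"` enforces it for
outbred panels.

## Blocks

Two-locus haplotype frequencies come from an EM that counts phase-known
genotypes directly and splits double heterozygotes between coupling and
repulsion (tolerance 1e-8, ≤1000 sweeps); on inbred panels this reduces
exactly to gamete counting, which the suite asserts.  D′ confidence
bounds: with allele frequencies held at their estimates, the multinomial
log-likelihood is evaluated on a 101-point D′ grid, the likelihood mass
normalized, and the 5th/95th percentiles of its CDF reported.  The
strong-LD bounds (0.98/0.7) follow the confidence-interval block
definition; the strong-recombination bound (upper < 0.90) comes from the
same block-building literature and is configurable.

Candidate intervals are runs of consecutive mapped markers whose total
span is ≤ the LD window (default 5 cM — the hard-window reading of an
"average LD distance of 5 cM" is the only deterministic one); an interval
is accepted when ≥95% of its informative (non-inconclusive) pairs are
strong LD, with any monomorphic pair disqualifying the interval.
Accepted candidates are taken greedily — most markers, then widest span,
then leftmost — without overlap, and named `HB<chromosome index>.<rank>`
left-to-right (1A→1 … 7D→21).  The greedy order plus the (cM, id)
tie-break makes output invariant to line order and marker renaming; cM
values are written with `%.17g` and parsed in round-trip mode so
file-backed reruns reproduce block names bit-for-bit.

Haplotype classes are the allele strings of lines homozygous at every
member marker; heterozygous/missing lines are unassigned for that block.
Between-block multi-allelic D′ collapses each class pair to 2×2 and
weights |D′ᵢⱼ| by the marginal class frequencies; a block against itself
gives 1, independent blocks ≈ 0.

## Origin tracing

A marker is informative for a cross iff all three parents are homozygous,
elite1 = elite2, and exotic ≠ elites; any heterozygous parent makes the
marker unidentified (U) for the whole cross.  U is stored distinctly from
missing, and summaries always emit both the raw fractions (U and missing
in the denominator) and the classified-only renormalization, because the
two denominators answer different questions.  The exotic estimate adds
half the heterozygous fraction to the B fraction (each het carries one
exotic allele).  A PBL block is exotic-specific iff ≥1 of its observed
classes occurs in the exotic parent panel and in zero elites; presence
means ≥1 carrier line (parent panels are small).  On diverse exotic
panels this presence rule flags liberally — the imprint fraction is a
sharing-sensitive quantity, and the suite asserts only its direction
(more elite–exotic sharing ⇒ smaller imprint), not its level.

## Association scan

Kinship is the VanRaden centered cross-product (missing imputed to the
marker mean for this computation only); PCA covariates use the same
imputation with a deterministic sign convention.  The number of PCs per
trait is the BIC argmin over ML fits of the null model (ML, not REML,
because REML likelihoods are not comparable across fixed-effect
structures; REML supplies the final variance components).  The null model
is fitted by eigendecomposition of K and 1-D bounded optimization of
log λ (λ = σ²g/σ²e, |log λ| ≤ 12, coarse grid then Brent), giving O(n)
likelihood evaluations.

Feature tests are P3D: the null components define V = σ²g K + σ²e I once
per trait-environment scan; for each feature, lines missing the feature
are dropped, the corresponding V submatrix Cholesky-whitens the data, and
the haplotype-class dummies (reference = most frequent class; classes
under 1% pooled into "rare-other") are tested by an F-test of the full
vs. null regression.  With K = I this is exactly one-way ANOVA, the
suite's oracle.  Exact per-feature REML is available behind
`per_feature_reml=True`.

Significance is two-condition: p at or below the threshold (a fixed value
per trait family — 0.001 for yield, 0.0001 for disease is the convention
supported — or the empirical bottom-0.1-percentile of the scan's p-value
distribution) **and** QQ deviation, i.e. the observed p falls below the
pointwise 5% quantile of its Beta(i, n−i+1) order-statistic distribution.
The QQ gate makes the effective bar for the top-ranked p of an n-test
scan ≈ 1−0.95^(1/n), slightly stricter than the fixed threshold.

## Rare-haplotype screen

A candidate is a haplotype class with frequency ≤ `rare_max` (default
15%, covering reported rare classes at 6–14%) and ≥ `min_support` = 3
carrier lines, in a block that is scan-significant for the target trait
in ≥ `min_instances` environments and **not** significant for the
phenology confounder (days to heading; the confounder scan is mandatory —
a missing scan is an error, because a stress advantage can be a maturity
escape).  Favorability and penalty are judged on class means, mirroring
how such results are presented, but only in environments where the
block's scan is significant: a mean deficit where nothing is significant
is noise, not a penalty.  The comparison baseline is the best *supported*
other class (≥3 lines; singleton class means are too noisy to anchor a
comparison).  Penalty tolerance is 0.25 trait SD (the "no penalty"
criterion needs a tolerance; none is standard).  Ranking: most
significant instances, then smallest scan p, then class-mean advantage.

## Problem sizes and what the tests show

The suite's statistical claims use: 300 lines × ~2,100 markers (21
chromosomes) for the Mendelian/ABH checks; the planted scenario (300 ×
1,200, 6 chromosomes) for power (50 replicates, seeds 1–50) and screen
recovery (25 replicates, seeds 1–25); 200 permutations for type-I error.
Per-replicate detection power at the planted conditions is ≈0.9, so
individual seeds can be honest misses; aggregate rates are what the
suite asserts.  Single-example tests use a demonstration seed where the
signal is recovered.

The simulator emulates founder-pool LD structure, Mendelian transmission,
selection and environment-specific QTL, but not genotyping error beyond
uniform missingness, mutation, epistasis, GxE beyond on/off environment
activity, or phenotype distributions heavier-tailed than Gaussian.
Passing tests therefore demonstrate the *pipeline's* correctness and
calibration under the stated genetic model, not robustness to assay
artifacts.

## Degenerate inputs and numerical choices

Monomorphic pairs raise a degenerate-pair signal and disqualify their
intervals; blocks with <2 observed classes are degenerate for
multi-allelic D′; constant traits fit with both variance components zero;
features with one observed class return p = 1 with 0 df; all-U lines
report a missing exotic estimate rather than 0.  EM tolerance 1e-8, D′
grid 101 points, eigenvalue clipping at 0, Cholesky ridge 1e-10, BIC ties
to the smaller model — all fixed constants, configurable where a user
would plausibly change them (grid density, bounds, pooling threshold).
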