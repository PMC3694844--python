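# Methods

## The design and the measurement model

The package targets paired intervention studies on Infinium-450K-style
arrays.  Each CpG site is measured by one probe as a pair of intensities
(methylated allele M, unmethylated U); the methylation fraction is

    β = M / (U + M + offset),      offset = 100 intensity units.

The offset regularizes low-intensity probes: β stays strictly below 1 and is
shrunk toward 0 by a factor total/(total+100), about 1% at a typical total
intensity of 10,000.  Statistical testing happens on the logit scale,
M-value = log₂(β/(1−β)), which stabilizes the variance of β near its 0/1
boundaries; results are reported back on the β scale because percentage
methylation is the interpretable unit.  β values of exactly 0 or 1 are
clamped to [1e-6, 1−1e-6] before the logit (with a warning); the β↔M round
trip is exact to 1e-12 inside that range.

## Preprocessing chain

1. **Detection.** The negative-control probes define a per-sample background
   distribution; a probe's detection p is the upper-tail normal probability
   of its total intensity under the control mean and sd.  Probes with mean
   p ≥ 0.01 across samples are dropped (strict <, so a probe at exactly the
   threshold is removed).  The channel-resolved rule used by the scanner
   vendor is proprietary; a one-sided normal tail on total intensity is our
   documented simplification.
2. **Background correction.** Each sample's median control M-value is
   subtracted from every probe in that column.  Controls have no β; we carry
   the control intensity through the same β chain as a pure methylated
   channel (β = I/(I+offset)).  This is an interpretation choice — the
   operation itself only needs *some* per-sample control median on the M
   scale — and with the generator's control level centred on the offset the
   correction is near zero on synthetic data.
3. **Quantile normalization** (paired per-CpG track only) forces every
   sample column onto the mean of the column order statistics.  Ties within
   a column receive the mean of the reference values over the tied rank
   span, the common convention; the transform is idempotent.
4. **Batch adjustment** is the parametric empirical-Bayes location/scale
   model: per probe, data are standardized conditional on the protected
   covariate (timepoint), per-batch location γ and scale δ² are estimated,
   shrunk toward pooled priors (normal for γ, moment-matched inverse-gamma
   for δ²) by the standard fixed-point iteration (tolerance 1e-4), and
   removed.  The implementation reproduces the reference R implementation
   (sva::ComBat, parametric priors) to 1e-14 on a frozen synthetic fixture.
   A batch aligned 1:1 with timepoint makes the model unidentifiable and is
   rejected.  Note that EB shrinkage with few samples per batch leaves a
   residual of order (estimation noise)/2 even for a pure constant shift;
   exact removal holds only in the no-shrinkage limit.

Two tracks share the chain.  The **paired per-CpG track** uses the full
chain and keeps SNP-overlapping probes, because subjects are their own
controls and within-pair genotype is constant.  The **global track** omits
quantile normalization (which would distort absolute category levels) and
removes blacklisted probes: cross-reactive over ≥ 49 bases, or directly
affected by a SNP with MAF > 5% (strict >).

## Testing and multiplicity

The paired contrast per CpG is a two-tailed Wilcoxon signed-rank test on
per-subject M-value differences, zeros dropped.  For n ≤ 12 remaining pairs
the p-value is exact by enumeration of all 2ⁿ sign assignments; midranks
make the enumeration a valid exact conditional test under ties.  Above 12
(including the target study size of 23) the normal approximation with tie
and continuity corrections is used; the genome-wide engine is a vectorized
implementation of the same formula, verified row-by-row against
scipy.stats.wilcoxon.

q-values use the π₀-scaled step-up: q₍ⱼ₎ = min over the sorted tail of
π̂₀·m·p₍ⱼ₎/j.  With π₀ fixed at 1 this is exactly Benjamini–Hochberg.  The
smoother mode estimates π̂₀(λ) = #{p>λ}/(m(1−λ)) on a λ grid (0–0.9 step
0.05), smooths the trend with a degree-3 polynomial least-squares fit,
evaluates at the largest λ and clips to [0.05, 1].  A polynomial trend
stands in for the df-3 smoothing spline of the canonical procedure; at the
package's family sizes the two are practically indistinguishable, and the
fixed-π₀ path is checked against an independent step-up oracle.  Families
smaller than 10 fall back to π₀ = 1 with a warning.

DMS calling is nested: (i) q < 0.05; (ii) additionally |mean β after −
mean β before| ≥ 5 percentage points.  The ≥5% filter applies to the
difference of group means, not per-subject differences.  Fold change is
(after−before)/before, undefined (flagged) at a zero baseline.  Candidate
gene panels are intersected with set (i) only — no effect-size filter — so
sub-5% sites in candidate genes are retained; a panel gene is
"inverse-coupled" when its expression q < 0.05 and at least one site moved
opposite in sign to the expression change (this handles genes with
mixed-direction sites).

Age drift control: per-probe OLS slope of baseline M on age with a
two-tailed t-test, flagged at p < 1e-5; plus exact (chromosome, position)
overlap counting against published age-associated position lists.

Enrichment compares DMS category incidences (a multi-region probe counts in
each listed category) with the analyzed background by chi-square goodness of
fit, df = k−1; categories with expected count < 5 are pooled into "other"
with a warning.

## Synthetic studies

The generator's defaults encode the study conditions the pipeline targets:
23 paired subjects; 20,000 probes (a desk-scale stand-in for the array's
~480k) with 72% Infinium II (the array's actual assay composition); island
context mix roughly matching the array (31% island, 23% shores, 10%
shelves, 36% open sea); baseline β uniform per context in island (0.09,
0.21), shore (0.31, 0.44), shelf/open-sea (0.67, 0.76); 2,000 spiked sites
with β differences in (0.002, 0.109) — the observed significant range — and
92% increases, matching the reported 16,470/1,505 direction split; two
batches assigned by whole subject; 600 negative controls at intensity
N(100, 20) clipped at 10, i.e. background on the scale of the β offset.

Effects are additive on the M scale: a spiked site's M shift is
logit₂(β₀+δ) − logit₂(β₀), so the recorded truth δ is the β difference at
the population mean.  Spikes whose shifted mean would leave (0.01, 0.99)
are clamped and the realized δ recorded.  Subject effects (sd 0.25 M) are
shared across the two timepoints of a subject; measurement noise (sd
0.12 M) is independent — together they reproduce the within-group β sds of
2–5 percentage points typical of tabulated sites.  Batch shifts are
per-probe N(0, 0.1 M).  Expression: gene baselines 2^U(4,9), 8%
multiplicative noise; 30% of genes carrying spiked probes move opposite in
sign to the gene's net methylation change by 10–30% of baseline.

What the generator does **not** model: probe sequence/GC content (probe-type
differences beyond the label), color-channel chemistry and dye bias, missing
values, SNP genotypes, cellular heterogeneity, and correlated neighbouring
CpGs.  Passing recovery tests therefore demonstrate the pipeline's
statistical behaviour under the assumed noise structure, not robustness to
those artifacts.

## Benchmarks and problem sizes

`methylpair.benchmarks` runs the full paired track (intensities →
q-values) and scores it against ground truth.  Spike recovery uses 20
seeded studies at 23 subjects × 20,000 probes with 2,000 spikes δ ~
U(0.02, 0.11): pooled observed FDR of the doubly-filtered call set is ~0
(the 5% effect filter removes essentially all null calls), power on spikes
with true δ ≥ 0.05 is ~87%, and the mean estimation bias is about −0.008 β
units — an attenuation produced by quantile normalization acting on a
strongly direction-biased signal plus the offset shrinkage.  Null
calibration uses 10 no-spike studies at 5,000 probes: ~5% of probes give
signed-rank p < 0.05, and enrichment chi-square p-values on uniform draws
are uniform.  These sizes keep the whole benchmark suite under a minute
while leaving the per-test sampling error well inside the asserted bounds.

## Numerical choices and edge cases

* Signed-rank: all-zero difference vectors return p = 1 flagged; fewer than
  3 non-zero pairs is an error.
* q-values are monotone in p and invariant to input order (stable sort).
* Quantile normalization of a single sample returns it unchanged with a
  warning.
* Value matrices reject missing values outright and name the offending
  (probe, sample) cell in every range error.
* Genomic coordinates are 1-based in memory and in manifests; conversion to
  0-based half-open happens only at BED export (score = |Δβ|·1000 capped at
  1000).
* A probe annotated to several regions counts once in each region for every
  category summary; probes without gene annotation form the Intergenic
  category.
* The run report JSON is derived entirely from the emitted TSVs and is
  byte-identical across reruns on the same inputs and seed.
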