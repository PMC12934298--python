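# Methods

## Model and procedure

`staarlite` performs gene-centric set-based association tests of rare
variants against a dichotomous (or continuous) trait. The analysis has four
stages.

**Null model.** For a binary trait, logistic regression of the outcome on
user-chosen covariates (intercept always included), fitted by iteratively
reweighted least squares (tolerance 1e-8 on the coefficients, 50 iterations;
non-convergence and quasi-separation raise rather than clip). With a kinship
matrix `K`, the model gains a polygenic random effect `b ~ N(0, τK)` and is
fitted by penalised quasi-likelihood: the working response is updated with
the current BLUP of `b`, the fixed effects by generalised least squares, and
τ by average-information REML steps (tolerance 1e-6, 100 iterations). A
Bernoulli outcome has no free dispersion, so a τ driven only by the kinship
diagonal is unidentifiable noise; the variance component is therefore
retained only when the REML score test at τ = 0 exceeds the one-sided 5%
normal critical value, otherwise the fit degrades to the fixed-effects
model. PQL τ̂ estimates for binary traits carry the method's known downward
bias; the score-test projection used downstream is consistent with the
fitted model either way. Continuous traits use ordinary least squares.

**Score statistics.** All set tests are score tests needing only
`S = Gᵀ(y − μ̂)` and `Σ = GᵀPG`, with `P = W − WX(XᵀWX)⁻¹XᵀW` (binary:
`W = diag(μ̂(1−μ̂))`) or the analogous mixed-model projection
`V⁻¹ − V⁻¹X(XᵀV⁻¹X)⁻¹XᵀV⁻¹`, `V = W⁻¹ + τK`. Missing dosages are
mean-imputed (2 × alt-allele frequency among observed genotypes, minor
flip applied afterwards) inside test statistics only — never in allele
counting, because cMAC is a count of observed alleles.

**Masks.** Variants join to annotations by the `chrom:pos:ref:alt` key.
Per gene: coding masks pLoF, DS, pLoF∪DS, missense (⊇ DS), synonymous; one
mask per non-coding category (UTR, upstream, downstream, promoter/enhancer
by CAGE and DHS evidence); an ncRNA mask. The rarity filter keeps variants
with in-sample MAF < 0.01 and MAC ≥ 1, recomputed within each analysis
sample (no external reference frequencies). Ultra-rare means MAC < 10.

**Tests and omnibus.** Burden, SKAT and ACAT-V run under Beta(MAF) weight
settings (1,25) and (1,1) and across annotation channels (MAF-only plus
aPC1–9, CADD, LINSIGHT, FATHMM-XF); an annotation channel multiplies the
Beta weight by the PHRED percentile `1 − 10^(−s/10)`. ACAT-V combines
single-variant score p-values (MAC ≥ 10; Cauchy weight `u²·maf(1−maf)` with
`u` the full per-variant weight) with one pooled burden component over the
ultra-rare subset, entering at the subset's mean Cauchy weight — the pooled
weight convention is isolated in one function so it can be swapped. The
omnibus is the equal-weight Cauchy combination of all kept grid entries.
Legacy mode keeps everything (and couples the gene's DS channels into the
missense pool); modified mode applies the five safeguards and records
exactly one exclusion reason per excluded entry (the all-ultra-rare reason
wins over the low-cMAC one when both hold, being the more specific
diagnosis; the low-cMAC rule fires only when the ultra-rare subset is
non-empty, since without one ACAT-V has no pooled component to distrust).

## Numerical choices

* **Quadratic-form tails.** Davies' characteristic-function inversion
  (AS 155), ported in full with its truncation-error bounds and
  convergence-factor machinery, term evaluation vectorised and chunked.
  Accuracy escalates: a first pass at 1e-6 absolute, refined at 1e-9 when
  the p-value falls below 1e-5, so small p-values are resolved to ~1e-9
  without paying the ~30× term-count cost on unremarkable sets. Returns
  outside (0,1] — including the exact zeros Davies produces beyond its
  resolvable range — fall back to the Liu moment-matching approximation
  (floored at 1e-300; an exact zero is never emitted). A single eigenvalue
  is an exactly scaled χ²₁ and is evaluated in closed form, which also makes
  the single-variant collapse identity exact. Eigenvalues below 1e-12 of
  the largest are truncated to stabilise near-singular Σ from correlated
  rare variants.
* **Cauchy combination.** `tan((0.5−p)π)` with the tail substitution
  `1/(pπ)` below p = 1e-16; p = 1 clipped to 1−1e-16; for combined
  statistics beyond 1e15 the arctan is replaced by its asymptote to avoid
  catastrophic cancellation.
* **Degenerate channels.** A missing annotation score contributes
  percentile 0, dropping the variant from that channel; a channel in which
  every weight vanishes contributes p = 1 (uninformative) rather than an
  error.
* **Single-variant p-values** use the plain normal-approximation score test
  — deliberately, since its fragility for ultra-rare variants is the
  behaviour the safeguards address; a corrected test can be plugged in at
  the same interface.

## Synthetic data

The generator emulates the study regime the framework targets: unlinked
bi-allelic rare variants with a site-frequency spectrum putting 55% of mass
on singleton/doubleton-scale MAFs, 10% on MAC≈5 and 35% log-uniform in
[1e-3, 9e-3]; a binary trait from a logistic model on covariates with the
intercept bisected to a 37% case fraction (the dichotomous-trait regime of
interest); Gamma(2, 4)-shaped PHRED annotation scores, shifted upward by a
configurable offset at causal variants. All randomness flows from a single
seed; runs are bit-identical.

Three pathological fixtures reproduce the aggregate structures that motivate
the safeguards, using a strong continuous covariate so that some cases have
very low covariate-predicted risk — planting rare alleles on those
individuals creates the extreme score-test residuals the pathologies need:

* `ssna1_like` — 3 SNVs, MACs {1,1,12}; the planted singleton carrier is an
  extreme-residual case with high conservation-channel scores, so the
  ACAT-V ultra-rare burden component goes extreme while full-set burden and
  SKAT stay flat.
* `lcnl1_like` — 2 SNVs, MACs {2,9}: all ultra-rare (cMAC 11), the exact
  regime where ACAT-V equals the burden test.
* `phlda1_like` — 12 missense SNVs of which exactly 2 are ultra-rare DS
  (MACs {2,3}, carriers all cases); the other 10 are null with MACs 1–15.
* `null_gene` — 8 variants from the default spectrum, no effect.

What the generator does *not* emulate: linkage disequilibrium (all tests
consume the covariance of realized genotypes, so unlinked sites exercise the
full machinery but correlated-variant behaviour is only covered through the
eigenvalue truncation), population structure, sequencing artifacts, and
case-control sampling at disease-prevalence scale. Passing tests therefore
demonstrate the statistical machinery and the safeguard logic, not
robustness to confounding in real cohorts.

## Calibration study sizes

The null type-I-error harness fits one null model and simulates independent
gene sets against it. The test suite runs 10,000 replicate sets at
n = 4,000 with three annotation channels, stratified by cMAC band (<10,
10–19, ≥20) and by the all-ultra-rare condition; empirical rejection rates
at α = 0.01 are compared to the exact binomial 99% acceptance region. The
acceptance script runs the same harness at 2,000 replicates, a size chosen
to keep the whole from-scratch reproduction in the minutes range while
leaving the α = 0.01 comparison meaningful.

## Known limitations

* PQL/AI-REML underestimates τ for binary traits (inherent to the working
  linear model); score tests remain valid because they use the fitted null.
* No saddlepoint correction for case-control imbalance; at prevalences far
  from the simulated 37% the normal-approximation score test is
  anti-conservative for ultra-rare variants — which is the phenomenon the
  safeguards mitigate at the omnibus level, not a bug in the fixtures.
* The missense/DS decoupling is the only cross-category coupling removed;
  whether pLoF couples into pLoF∪DS the same way is not addressed — only
  the missense coupling is implemented, in both its legacy and modified
  behaviours.
* Kinship handling is dense internally; it is intended for the cohort sizes
  used here (thousands), not biobank-scale sparse solvers.
* The leave-one-variant-out contract is structural: n removals plus the
  full-set reference, with modification triggers re-evaluated per reduced
  set (removing a variant can flip a set into the all-ultra-rare regime).
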