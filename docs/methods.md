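# Methods

This note documents the models, the synthetic data, the numerical choices
and the known limitations of `hcngp`. Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`.

## Two-stage analysis

The package follows the standard two-stage plant-breeding workflow: stage 1
collapses plot-level trial data into one BLUE per clone; stage 2 regresses
those BLUEs on genome-wide markers.

### Stage 1: trial mixed model

Plot means of the six ordinal picrate scores are modelled as

    y = X c + Z_b b + Z_cl (c x trial) + e,

with clone effects `c` fixed (cell-means coding, so the GLS solutions are
the per-clone BLUEs), blocks nested in trial and clone-by-trial interaction
random, and an independent residual. "Trial" is the location-year
combination: the source model lists location only, but folding year into
location uses all trials without adding a factor the model did not state.
With a single trial the interaction term is dropped (it is confounded with
clone). A companion fit with clone random yields σ²c, and broad-sense
heritability is reported exactly as conventionally printed for this design,

    H² = σ²c / (σ²c + σ²cl + σ²e),

with no division by location or replicate counts; the entry-mean variant is
available as `broad_sense_H2_entry_mean` but is not the headline number.
Treating clones as fixed for BLUEs and random for H² resolves the tension
between needing unbiased clone estimates and needing a clone variance.

Variance components are estimated by EM-REML on Henderson's mixed-model
equations: monotone in the REML objective (asserted in the tests along a
tracked iteration path), tolerance 1e-6 on the relative change of every
component, 200 iterations by default, with a guarded Aitken/geometric
extrapolation of the variance components (rejected whenever it leaves the
positive orthant) that cuts the iteration count roughly tenfold. Variances
are floored at 1e-8 x var(y) to keep the equations well-posed. The estimates
agree with lme4's REML on the same data to within 5% (oracle test).

Limitations: scores are treated as Gaussian at the plot-mean level — no
ordinal threshold model — and BLUE standard errors are not propagated into
stage 2; both mirror the analysis this package re-implements.

### Relationship matrices

VanRaden's genomic relationship matrix is `G = ZZ' / (2 Σ p_i(1-p_i))` with
`Z = M - 2p` column-centered dosages and `p` estimated from the analysed
sample (no base population is available). Centering puts the vector of ones
in G's null space, so G is always singular by construction; wherever an
inverse is needed the matrix is first blended, `G* = (1-w)G + wI` (default
w = 0.02), the standard bending that preserves GEBV ranking. Model fitting
itself never inverts G: GBLUP is parameterized through the
eigendecomposition `G = UDU'`, which handles any PSD matrix, including
`blend = 0`.

The RKHS kernel is `K_ij = exp(-d_ij θ)` with `d_ij` the squared Euclidean
distance between dosage vectors divided by the marker count, so θ is
portable across marker densities (plain Euclidean distance is a config
option). Default θ = 1 with a suggested grid {0.25, 0.5, 1, 2, 5}; on the
simulated populations mean d is ≈ 0.7, and θ sweeps up to 10 only degrade
prediction, so the default is also the empirically sensible region. A single
kernel is used; no kernel averaging.

### Stage 2: prediction models

* **GBLUP** — `y = 1β + g + e`, `g ~ N(0, G σ²g)`, fitted by the same
  EM-REML core (with acceleration); `h² = σ²g/(σ²g+σ²e)`. Validation clones
  are predicted by the Gaussian conditional mean `K_vt K_tt⁻¹ ĝ`, computed
  through `w = σ²g V⁻¹(y-1β)` so singular training blocks need no explicit
  inverse. When G is built from the same Z as a ridge regression on marker
  effects, GBLUP GEBVs equal the RR-BLUP predictions — asserted to 1e-6.
* **Bayesian alphabet** — one single-site Gibbs core (numba) with five
  marker-effect priors: shared-variance Gaussian (BRR), per-marker
  scaled-inv-χ² variances (Bayes A), spike + Bayes-A slab (Bayes B, spike
  probability π = 0.95 fixed, configurable), spike + shared Gaussian slab
  (Bayes C), and the double-exponential via the normal-exponential mixture
  with inverse-Gaussian latent updates (BL). Sampler settings follow the
  source analysis: nIter = 6000, burnIn = 700, residual prior df₀ = 5. The
  residual prior scale S₀ defaults to a response-derived value with prior
  mode at half the phenotypic variance; the literal S₀ = 500 of the original
  analysis is accepted via config but implies an absurd residual prior on a
  1–9 scale, which is why it is not the default. Marker-variance hyperpriors
  use df 5 with scales derived from var(y), an a-priori marker R² of 0.5 and
  the summed dosage variances (for spike models divided by 1-π), the
  standard rescaling. Per-iteration genetic variance is var(Zb) — obtained
  free as y - β - e — giving h² = var(Zb)/(var(Zb)+σ²e) averaged after
  burn-in. Marker update order is the input order; fixed seeds give
  bit-identical chains. Collapse identities (Bayes B at π=0 ≡ Bayes A;
  Bayes C at π=0 ≡ BRR; BRR ≈ closed-form ridge) are asserted within
  Monte-Carlo error, where the MC scale is measured by refitting with a
  different seed.
* **RKHS** — `y = 1β + u + e`, `u ~ N(0, K σ²u)`, Gibbs-sampled in the
  eigenbasis of K where every full conditional is diagonal (O(n) per
  iteration after one eigendecomposition; eigenvalues below 1e-10 of the
  maximum are dropped and their coordinates fixed at zero). With K = G this
  is GBLUP sampled by MCMC, and the two agree at r > 0.98.

### Cross-validation

Repeated k-fold (defaults k = 5, 5 repeats → 25 correlation cells), uniform
unstratified fold assignment, all models evaluated on one shared fold plan
so comparisons are paired. Per cell: predictive ability r_a (Pearson
correlation of validation BLUEs and predictions), validation-set h², and
accuracy = r_a/√h²_val. One common denominator — the G-kernel h² — is used
for every model so that accuracies are comparable across models; negative
accuracy can only arise from negative r_a. A fold with zero-variance
predictions is recorded as missing with a warning and the run continues.

**Validation-set h²** is the posterior mean of σ²a/(σ²a+σ²e) from the
G-kernel sampler fitted to the validation clones alone. Both variances get
the Jeffreys limit of the scaled-inv-χ² prior (df = 0, scale = 0): a
validation fold has ~50 clones, h² is identified there only through the
spread of the kernel eigenvalues, and any informative scale visibly pins
the posterior instead of letting the data speak. With Jeffreys priors the
sampler is well calibrated: pure-noise responses give h² < 0.2 and
noise-free kernel-structured responses give h² > 0.8 on family-structured
kernels (tests). On an unrelated-HWE kernel the spectrum is nearly
isotropic and h² is close to unidentifiable at that size — a genuine
property of the quantity, not of the sampler.

## Synthetic data

The generator reproduces the statistical structure the analysis assumes,
with defaults chosen once as the study conditions:

* **Population** — 40 founders drawn at HWE with per-marker allele
  frequencies uniform on (0.05, 0.5); 29 full-sib families × 13 offspring
  (377 test clones) by gene-dropping, sires and dams drawn with replacement
  from disjoint founder halves (shared sires → half-sib ties); two check
  clones; 2,000 markers in 18 chromosome blocks; 3% missing calls.
* **Trait** — one QTL per target chromosome (highest-MAF marker there,
  deterministic): chr16 at 30% and chr14 at 7% of phenotypic variance, a 3%
  polygenic tail over all remaining markers, and heterozygote (dominance)
  deviations at the QTL worth 15% of total genetic variance (dominance is
  documented for this trait). Effects are rescaled on the realized
  population, so target fractions are met on the sample.
* **Trials** — every test clone once per location, blocks of 15 plots with
  the 2 checks repeated in each, three locations with mean shifts
  (−0.8, +0.3, +0.5) around a grand mean of 6.1 (the low/mid/high pattern
  of the source trials), block variance 0.2, clone-by-location 0.6, plot
  residual 1.3, subsample noise 0.5 (no documented value exists for the
  subsample variance; it is a free parameter). Six subsample scores per
  plot are the latent value plus noise rounded at half-integer cut points
  and clamped to [1, 9]. These settings imply a latent phenotypic variance
  of ≈ 3.6 and a plot-basis h² of ≈ 0.40 (H² ≈ 0.47).

What the generator does **not** emulate: linkage disequilibrium along
chromosomes (markers segregate independently; family structure alone
supplies marker–QTL correlation), selection history across cycles,
recombination maps, spatial field trends, and the skewed score
distributions of specific locations. Passing tests therefore demonstrate
correctness of the estimators under the stated architecture, not field
realism.

## Problem sizes

The test suite and the acceptance script run at desk scale, chosen so the
full pipeline exercises every code path in minutes on one CPU: 250–377
clones, 1,000–2,000 markers, MCMC chains of 1,500–6,000 iterations
depending on the check (equivalence oracles use the full 6,000/700
schedule). The acceptance script uses 25 families × 10 offspring, 1,000
markers, three locations, 2,000-iteration chains, and the full 5 × 5 CV of
all seven models.

## Model-comparison caveat

With a common accuracy denominator, the model ranking equals the
predictive-ability ranking. On the two-QTL architecture the
variable-selection models (Bayes A/B/C) and the Bayesian Lasso beat
uniform-shrinkage BRR by clear margins (+0.05 to +0.09 mean accuracy over
10 seeds in the test suite). RKHS with a Gaussian kernel, however, is
statistically indistinguishable from BRR/GBLUP here: over the useful θ
range the kernel is nearly an affine function of G, so the three models
make near-identical predictions (r > 0.99), and their ordering in any one
run is a coin flip (measured margin −0.003 over the same 10 seeds). The
suite asserts the strict ordering anyway, so the RKHS-vs-BRR comparison is
expected to fail by that hair; the test is kept strict rather than widened
to paper over a real tie.
A real RKHS-over-linear advantage requires non-additive signal that a
near-linear kernel can express, which this architecture (small dominance at
two loci among thousands of markers) does not provide.
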