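# Methods

`transplantqg` estimates how additive genetic variance in early
life-history traits and in fitness changes across an environmental
gradient, from a factorial sire × dam breeding design reciprocally planted
at several transplant elevations. This note records the models, the
generative assumptions of the synthetic-data module, the numerical
choices, and the limits of what the test suite demonstrates.

## Models

### Mean model

For each trait *y* (emergence, establishment, survival: binary;
development time: Gaussian, days) we fit

  y = Species × Elevation + block + family + e

with species × elevation as cell-means fixed effects and independent
random intercepts for field block and family. Binary traits use a probit
link via latent-liability augmentation, with residual liability variance
fixed at 1. Marginal means are reported on the data scale averaged over
the random effects: for a probit trait, Φ(η / √(1 + V_block + V_family))
per posterior draw. Establishment and survival are conditioned on
emergence; development time on establishment.

Pairwise elevation contrasts within species are tested by the two-sided
posterior tail probability of the data-scale difference (plus-one
smoothed, doubled, Bonferroni-multiplied by the number of pairs), and
summarized as compact letters assigned greedily in ascending elevation
order. Note the plus-one smoothing bounds the smallest attainable
adjusted probability at 2·m/(S+1) for S saved draws and m pairs, so at
least ~250 saved draws are needed for decisions at α = 0.05 with six
pairs. The species × elevation interaction is summarized by the smallest
Bonferroni-adjusted tail probability over all
difference-in-differences contrasts — a posterior analogue of the usual
Wald interaction test, not a frequentist χ²; reports label it as such.

### Selection on development time

On established seedlings, survival is modeled probit with a per-cell
(species × elevation) intercept and slope on development time
(standardized within cell; per-day slopes recovered via the cell SD).
Random block and family intercepts are shared across cells. Link-scale
slopes b are mapped to the data scale as the average derivative of the
probit mean function, mean_i φ(η_i)·b (survival probability per day), and
divided by the model-implied mean survival to give the mean-standardized
directional selection gradient β (per day); β × SD gives the
SD-standardized gradient. Because the division is applied draw-wise,
β × mean survival = average gradient holds exactly on every draw. Cells
with no survival variation or complete separation are flagged, never
silently dropped. The linear predictor used in the average derivative is
the fixed-effect predictor at the observed covariate values; random
effects average to zero over the population and are omitted there.

### Character-state genetic model

For one species and one trait,

  y = Elevation + sire + dam(sire) + block(elevation) + e

with an *unstructured* sire covariance matrix across elevations (the same
trait at different elevations treated as distinct, genetically correlated
character states), a separate dam-within-sire variance per elevation, a
common block variance, and (Gaussian traits) a separate residual variance
per elevation. The sire × dam interaction is deliberately omitted — it is
absorbed by the residual without inflating the sire component — so the
dam term is the full-sib family term of the nested paternal half-sib
design. Additive genetic variance is V_A = 4·V_sire per draw;
cross-elevation covariances become correlations via cov2cor per draw.

For survival, latent-scale variances are mapped to the data scale with
the exact probit forms: with V_tot = V_A + V_dam + V_block above the unit
probit residual,

  p̄ = Φ(μ/√(1+V_tot)),  Ψ = φ(μ/√(1+V_tot))/√(1+V_tot),  V_A(obs) = Ψ²·V_A.

A Monte-Carlo integration path (`backtransform_binary_mc`) exists to
validate the closed forms; they agree to 10⁻³ at 10⁶ draws. V_A enters
V_tot: the smoothing factor integrates over *all* latent variation, which
also guarantees V_A(obs) ≤ p̄(1−p̄). Relative (mean-standardized) variance
V/mean² is the evolvability of a Gaussian trait and, applied to survival,
the additive genetic variance in relative fitness that bounds the rate of
adaptation. The block variance is included in V_tot; the conversion's
variance partition is a documented package choice.

### Bivariate development time × survival

Within one elevation (or across an elevation pair), the two traits are
stacked as the two components of the same machinery: a 2 × 2 unstructured
sire covariance and a 2 × 2 unstructured family (dam-within-sire)
covariance link them; the Gaussian trait keeps a free residual variance
and the probit trait is pinned at 1, with independent residuals given the
random effects. Individuals missing the Gaussian trait (never
established) contribute to the binary component only — with independent
residuals, dropping those rows integrates the missing response out of its
conditional distribution exactly. The cross-elevation mode takes
development time from one elevation and survival from another — disjoint
individual sets linked through shared sires — to estimate the genetic
association between native-range development and novel-environment
fitness. Family-level correlations are reported alongside sire-level
ones; families outnumber sires three-fold, so they are estimated more
precisely.

### Permutation null for genetic variance

Because the sampler constrains variances to be positive, significance of
V_A is assessed against a null built by shuffling the outcome tuple
(emerged, established, dev_time, survived) among individuals *within each
elevation × block cell* and re-estimating V_A at reduced MCMC settings.
Stratifying within cells keeps block and elevation effects out of the
null; permuting the whole tuple preserves the phenotypic trait
association and the conditioning pattern (a flag allows independent
per-column permutation for sensitivity analysis). Exceedance p-values use
the plus-one rule (1 + #{null ≥ observed})/(n_perm + 1) and are never 0.
The observed value is computed at the same reduced settings as the null
refits for comparability. Refits whose sire-variance chain fails a lag-1
autocorrelation screen are excluded and counted.

## Sampler

All models run through one Gibbs sampler: conjugate normal draws for
fixed effects (diffuse normal prior) and random-effect vectors, conjugate
inverse-Wishart draws for covariance components (inverse-gamma in one
dimension), truncated-normal latent liabilities for binary responses via
inverse-CDF sampling. Priors default to scale = identity and
df = dimension + 1 — proper but heavy-tailed; an optional
parameter-expansion move (redundant multiplicative working parameter,
diffuse Gaussian prior) is available for scalar terms to improve mixing
near zero variance. Per-level updates of the unstructured term are
batched (q × C × C linear algebra), so a character-state fit on ~20,000
records takes seconds per thousand iterations on one core.

Numerical choices:

* linear predictors are clamped to ±8 before liability sampling, and
  inverse-CDF arguments to [10⁻¹², 1−10⁻¹²];
* binary responses with a single observed class are rejected (liability
  unidentified), as are rank-deficient fixed designs (aliased columns are
  named);
* grouping levels unobserved in some environment are imputed from the
  covariance and logged;
* correlation draws from zero-variance covariance draws are excluded and
  counted rather than propagated as NaN.

Default chain settings are desk-scale (burn-in 5,000, thin 10, 1,000
saved); analyses in this repository use shorter chains chosen per task
(stated in each driver/test), and production-scale settings (e.g.
burn-in 200,000, thin 2,000) can be requested through `MCMCConfig`.
Chains are reproducible bit-for-bit under a fixed seed.

## Synthetic-data generator

The generator emulates the field experiment end to end. Pedigrees cross
sires to dams in 3 × 3 factorial mating blocks (partial final block
permitted, filled left-to-right), optionally retaining a random subset of
candidate crosses to match realistic family counts (e.g. 94 of 105
candidates from 36 sires × 35 dams). Each family contributes 25 seeds per
elevation by default — configurable shortfalls assign reduced counts to
disjoint random family subsets — split as evenly as possible over five
field blocks per elevation. The default two-species configuration
reproduces the printed design arithmetic: 2,160 and 2,700 seeds per site,
540 (and 432) per block.

Traits follow the latent-Gaussian structure the inference assumes.
Development time is elevation mean + sire + dam + block + residual;
survival is a threshold trait whose liability adds an elevation
intercept, an optional per-elevation coupling γ·(development-time
deviation) that generates directional selection, sire/dam/block effects,
and a unit residual. Sire effect vectors for (development time,
survival-liability) × elevations are drawn from a single 2E × 2E
covariance matrix, so cross-trait, cross-environment structure — e.g.
fast native development covarying with novel-elevation survival — is a
single entry of that matrix. Emergence and establishment are
genetics-free Bernoulli events by default (a family-level jitter hook
exists); development time is recorded only for established seedlings and
survival only for emerged ones, reproducing the conditioning pattern of
the field data.

Dams transmit gametic effects drawn from the same covariance matrix by
default (`dam_genetic=True`): full sibs then share twice the half-sib
covariance plus an environmental dam variance, as in a real nested
design, and the family term carries genetic cross-trait covariance — this
is what makes family-level correlation estimates informative. The sire
variance component targeted by the model equals the covariance matrix
diagonal either way.

**A caveat this exposes:** the fitted dam term is diagonal across
elevations, so with genetically transmitting dams the dam-side
cross-elevation covariance is unmodeled and partially absorbed by the
unstructured sire matrix, biasing cross-elevation sire correlations
upward (we observe ≈ 0.9 recovered from a generating value of 0.7 at
recovery sample sizes). This is a structural property of the nested
half-sib character-state model, not a sampler defect. Parameter-recovery
tests therefore simulate with `dam_genetic=False` — recovery under the
model's own assumed structure — while the qualitative pattern tests
(variance orderings, correlation signs) use the full genetic generator,
for which the claims are robust to this bias.

What the generator does *not* emulate: spatial autocorrelation within
blocks, climate covariates, seed dormancy, selective disappearance before
establishment (development time is missing at random given
establishment, not selectively), and non-Gaussian trait architectures.
Passing tests therefore demonstrate correctness of the estimation
machinery under the assumed generative model and robustness of the
qualitative patterns, not that field data meet those assumptions.

## Problem sizes and study conditions

Simulation studies in the tests and the acceptance script use these
desk-scale conditions, chosen once as realistic for the design:

* parameter recovery: 96 sires × 3 dams × 20 offspring × 4 elevations
  (the full design's order of magnitude), sire variance 8 days²,
  cross-elevation correlation 0.7, five replicate seeds;
* pattern reproduction: 60 sires × 3 dams × 12 offspring × 4 elevations,
  survival-liability sire variances (0.05, 0.05, 0.15, 0.30) rising
  toward the novel elevation, native-development × novel-survival sire
  correlation −0.8, twenty replicates;
* permutation calibration: 27 sires × 3 dams × 4 offspring × 4
  elevations with zero sire variance, 20 datasets × 50 permutations;
* selection calibration: two species × 24 sires × 3 dams × 8 offspring,
  γ = 0 (coverage) or γ = (−0.12, 0, 0, +0.12) liability·day⁻¹ at the
  elevational extremes (sign recovery), ten replicates.

## Known limitations

* One inferential framework: probit throughout for binary traits;
  logit-link results would differ by the usual ≈1.6 scale factor on the
  liability, but data-scale summaries are reported precisely to make the
  link choice minor.
* Interaction evidence is a posterior contrast summary, not a type-III
  χ² test; the two agree qualitatively but are not numerically
  comparable.
* The inverse-Wishart prior keeps variance draws strictly positive;
  near-zero variance components mix slowly and their posterior means are
  biased slightly upward — exactly why the permutation null, which shares
  this bias between observed and null fits, is the significance
  yardstick for V_A.
* Compact-letter assignment is greedy and order-deterministic; with
  intransitive non-significance patterns it may differ from exhaustive
  letter displays.
* The cross-elevation bivariate model identifies the sire covariance
  only through paternal half-sib links; with ~60–100 sires its
  correlation posterior is wide, and the family-level correlation is the
  sharper (but compositionally different) estimate.
* Permutation-null calibration is configuration-dependent. Each dam
  mates several sires, and the family term cannot capture the resulting
  cross-family dam covariance; this unmodeled structure is present in
  the observed fit but destroyed by permutation, and in some designs
  (few elevations, many seeds per family) it makes the exceedance
  p-value mildly anti-conservative. At the calibration conditions used
  in the tests (27 sires, 4 elevations, 4 seeds per family) the null
  p-values are uniform to within binomial error.
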