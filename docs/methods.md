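# Methods

## Two-sample Mendelian randomization

### Harmonization

Exposure and outcome summary statistics are inner-joined on variant id.
When the outcome study's effect/other alleles are the mirror image of the
exposure study's, the outcome beta is sign-flipped; alleles that are
neither matched nor swapped mark the variant as inconsistent and it is
dropped (counted separately from variants simply missing from the outcome
study). Strand-ambiguous A/T and C/G variants cannot be oriented without
allele frequencies, which many summary files omit; they are kept with a
warning by default and a flag drops them. Harmonization is idempotent, and
the retained + dropped counts always partition the exposure set.

### Instrument QC

Three per-variant filters, applied in a fixed order for count attribution
(p-value, strength, exclusion list):

| filter | statistic | default |
|---|---|---|
| exposure association | GWAS p-value | p < 5×10⁻⁸ |
| instrument strength | F = (β̂_X / se_X)² | F ≥ 10 |
| pleiotropy | id ∈ exclusion list | empty list |

F is the squared Wald z — the only instrument-strength statistic
computable from summary data alone; it coincides with the single-variant
regression F at large n. The exclusion list is a plain text file of
variant ids, typically compiled from a phenotype-association database
query done outside this package.

### Estimators

*IVW (fixed-effect).* Closed-form weighted regression of β̂_Y on β̂_X
through the origin with weights 1/se_Y²; equivalently an inverse-variance
meta-analysis of Wald ratios with first-order SEs se_Y/|β̂_X|. The
fixed-effect form assumes a single common causal effect; no multiplicative
random-effect inflation is offered in this version. Two-sided p-values are
normal.

*Weighted median.* Wald ratios are sorted (stable sort, so ties keep input
order); normalized weights wⱼ = 1/se_ratioⱼ² define cumulative midpoints
pⱼ = Σ_{k≤j} w_k − wⱼ/2, and the estimate linearly interpolates the ratios
at p = 0.5. The point estimate is deterministic. The SE is a parametric
bootstrap (default 1000 replicates): β̂*_X ~ N(β̂_X, se_X), β̂*_Y ~
N(β̂_Y, se_Y), recompute, take the SD. The conventional inverse-variance
weights (1/se²) are used rather than 1/se.

*Outlier resampling (MR-PRESSO style).* For each variant j, the
leave-one-out IVW slope β̂₍₋ⱼ₎ predicts β̂_Yj; the observed weighted RSS
(weights 1/se_Y²) is compared against simulations β̂_Yj* ~
N(β̂₍₋ⱼ₎β̂_Xj, se_Yj) with the leave-one-out slopes recomputed per
simulated table. The global p-value is the empirical exceedance fraction
with a +1/(n_sim+1) continuity correction, so it lies in (0, 1]. Per-variant
outlier p-values compare each observed squared residual with its simulated
distribution and are Bonferroni-multiplied by the number of variants;
variants below α = 0.05 are removed and IVW re-run. The smallest attainable
adjusted p is n_snps/(n_sim+1), so n_sim must exceed n_snps/α for the test
to have any power — with the default 1000 simulations that covers up to
~50 variants at α = 0.05. The companion distortion test of the original
resampling method is not implemented; only outlier removal plus corrected
estimate is used here. All resampling is driven by a user-supplied seed and
is bit-reproducible.

## Cohort models

### Follow-up and exposure coding

Follow-up runs from enrollment to the earliest of diagnosis, death, loss
to follow-up, and the administrative end of follow-up (years = days/365.25,
ISO-8601 dates); only a diagnosis at that earliest date is an event. The
first-year sensitivity analysis removes subjects *diagnosed* before one
year while keeping early-censored subjects. Continuous exposures are
scaled by the complete-case sample SD (denominator n−1); the binary
overweight threshold defaults to 24 kg/m² (waist 80 cm), configurable.
Quartiles use the linear-interpolation percentile definition with
boundary ties assigned to the lower group and Q1 as the reference.

### Partial-likelihood fitting

Damped Newton–Raphson on the Cox partial likelihood: the full step is
halved until the likelihood does not decrease; convergence requires
max |score| < 1e-8 or relative log-likelihood change < 1e-10, within 100
iterations. Efron's approximation handles tied event times by default —
less biased than Breslow under the day-level ties of real cohorts — and
Breslow is available for cross-checks (the two coincide without ties, a
tested invariant). Covariates are mean-centered internally (the partial
likelihood and coefficients are invariant; exponentials stay bounded).
Covariance is the inverse observed information. Monotone likelihood
(separation) leaves a vanishing score at a diverging coefficient, so it
cannot be caught by the score criterion; it is detected after convergence
as an absurd standard error on the standardized-covariate scale (SE × SD
of the covariate > 50, i.e. a CI spanning dozens of log-hazard units) and
raised as an error — or downgraded to a warning inside bootstrap
replicates, where a diverged rare-binary nuisance term (e.g. zero events
among the ~2% of diuretics users in a resample) is harmless to the effect
terms. Complete-case analysis throughout; no imputation.

The adjustment sets are nested: model 1 = age, smoking, drinking,
education, marital status, enrollment batch; model 2 adds parity, age at
menopause, mastitis history, diuretics, antibiotics, and hormone-therapy
use; model 3 adds the co-exposure (the mediator when modelling the
exposure and vice versa).

### Proportional-hazards check

Scaled Schoenfeld residuals (Grambsch–Therneau scaling d·V̂·sᵢ, with the
risk-set means computed under the fitted coefficients) are Pearson-
correlated with event time per term; p < 0.05 flags a drifting hazard
ratio. The risk-set mean uses the Breslow form at tied times — with the
effectively continuous simulated times this matches Efron exactly, and the
discrepancy under heavy ties is negligible relative to the test's
resolution. A literal time×exposure interaction term was considered and
rejected: it needs episode-splitting machinery disproportionate to the
diagnostic role, and the residual test estimates the same alternative.

## Mediation

The decomposition assumes no exposure–mediator interaction in the outcome
model (an interaction-capable variant was deliberately left out of this
version: with it, NDE/NIE depend on the reference level a*, and the simple
product structure below no longer holds) and a rare outcome, so the Cox
log-HR behaves like a log-OR for the product method. Then

- NDE = θ₁Δa, NIE = θ₂β₁Δa, TE = NDE + NIE exactly by construction,
- proportion mediated PM = NIE/TE, invariant to rescaling the mediator,
- Var(NDE) = Δa²·Var(θ₁); Var(NIE) = Δa²(β₁²Var(θ₂) + θ₂²Var(β₁)),
  treating the two models as independent (standard two-model practice);
  the TE variance additionally keeps the within-Cox covariance of θ₁, θ₂.

Δa defaults to one sample SD of the exposure; under the no-interaction
specification only the difference a − a* matters, so no reference level is
reported. The delta method gives no PM interval; the subject-resampling
bootstrap (percentile CIs, point estimates kept at full-data values,
≤10% non-converged replicates tolerated) is the recommended interval for
reporting and does provide one. Opposite-signed NDE/NIE make PM fall
outside [0, 1]; it is still reported, with a warning.

## Synthetic data

### GWAS generator

Per-variant true exposure effects β_Xj ~ N(0.03, 0.01) — a typical
effect-size scale for anthropometric GWAS of >100k samples on transformed
traits — with reported SEs 0.002 (exposure) and 0.003 (outcome), so median
instrument F ≈ 200 and nearly all variants clear genome-wide significance.
Observed betas add sampling noise at those SEs on both sides; outcome
effects are θ·β_Xj plus optional pleiotropic shifts αⱼ ~ N(μ_α, σ_α) on a
configurable fraction of variants (balanced: μ_α = 0; directional:
μ_α > 0, the mode that exercises the outlier test). Default 60 variants,
matching the tens-of-instruments scale of the motivating analyses. Because
weights concentrate on β̂_X² ≈ 1e-3 against noise variance 4e-6, weak-
instrument attenuation of IVW is below 0.5% — negligible against its SE.

### Cohort generator

Defaults emulate a cohort of ~20,000 postmenopausal women followed 8.2
years: exposure ~ N(24.3, 3.5²) kg/m²; mediator = intercept + 6.0·exposure
+ N(0, 72²) μmol/l, giving marginal SD ≈ 75 and mean 273; a correlated
second adiposity measure (waist, r ≈ 0.8); covariates drawn independently
of exposure at realistic prevalences (so adjusted ≈ unadjusted; a
`confounded` mode ties age to both exposure and hazard for testing
adjustment). Event times are inverse-transform samples from a Weibull
baseline hazard (shape 1.1, scale 9.44e-4) multiplied by
exp(θ₁(A−μ_A) + θ₂(M−μ_M)); centering makes the baseline rate directly
control the incidence of an average subject, and the scale is tuned
analytically so cumulative incidence at the administrative censoring time
(8.2 years) is ≈1% (~200 events) at the default effects θ₁ = ln(1.25)/SD_A
and θ₂ = ln(1.05)/(β₁·SD_A). The implied ground-truth proportion mediated,
ln(1.05)/ln(1.3125) ≈ 0.179, is written into the fixture manifest so
recovery tests are self-describing. Optional uniform dropout and
missingness injection are off by default.

What the generator does *not* emulate: linkage disequilibrium or genotype-
level structure on the GWAS side; on the cohort side, staggered calendar
enrollment, covariate-dependent censoring, measurement error in the
biomarker, and real missing-data mechanisms. Passing recovery tests
therefore demonstrates correctness of the estimators under their stated
assumptions, not robustness to those real-data features.

## Problem sizes in the test suite

Recovery and calibration checks run at the generator's native scale
(n = 20,000, ~1% events) with 50 replicate cohorts; resampling-based
checks use 200 seeds (outlier-test specificity), 300 seeds (IVW null
coverage), and 200–1000 bootstrap/simulation replicates per call. These
counts give Monte-Carlo SEs an order of magnitude below the tested effect
sizes while keeping the full suite in the low minutes.

## Known limitations

- No MR-Egger, mode-based, multivariable-MR or contamination-mixture
  estimators; no LD clumping (sources are assumed to report independent
  variants); no allele-frequency-based strand inference.
- Fixed-effect IVW only; heterogeneity-robust variants are out of scope.
- No competing risks, time-varying covariates or multiple imputation in
  the Cox layer.
- Single mediator; no exposure-induced mediator–outcome confounding; the
  exposure–mediator interaction path is not implemented.
- The delta-method mediation CIs inherit the two-model independence
  assumption; use the bootstrap when the mediator and outcome models share
  strong finite-sample coupling.
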