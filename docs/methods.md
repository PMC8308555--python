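# Methods

## The estimation problem

The package estimates the causal effect θ of plasma homocysteine
(natural-log scale, per within-sample SD) on metabolic syndrome
(binary, ≥3 of 5 NCEP-ATP III-style components) using genetic variants
as instruments, in two designs:

* **one-sample**: genotype, exposure and outcome measured on the same
  individuals; estimation by Wald ratio for a single variant or by
  two-stage least squares with a weighted genetic risk score (GRS);
* **two-sample**: per-SNP summary statistics from an exposure GWAS and
  one or more outcome cohorts; estimation by IVW, weighted median and
  MR–Egger after fixed-effect pooling of the outcome associations and
  allele harmonization.

All causal estimates are reported as log-odds of MetS per 1 SD of
log-Hcy; a Wald 95% CI (estimate ∓ 1.959964·SE) is attached
throughout. Exposure effects are converted to SD units before ratio
estimation (per-SNP ratio = per-allele outcome log-OR over per-allele
exposure effect in SD/allele); without that convention ratios would
estimate θ/σ in log-µmol/L units.

## Synthetic cohort model

`simulate_cohort` draws, for a configured set of unlinked variants
with effect-allele frequencies f:

* dosages ~ Binomial(2, f), i.e. Hardy–Weinberg genotype proportions
  ((1−f)², 2f(1−f), f²), with independent missingness at a configured
  rate (mean-imputed wherever a sum over dosages is needed; regressions
  instead drop incomplete samples per variant);
* log-Hcy = intercept + Σᵢ βᵢ·dosageᵢ + c_X·U + ε, with U a standard
  normal confounder and ε ~ N(0, σ²);
* five MetS components, each Bernoulli with logit
  logit(prevⱼ) + s(θ)·z + (c_Y/5)·U + Σᵢ s(αᵢ)·dosageᵢ, where z is
  standardized log-Hcy; MetS = (Σ components ≥ 3).

**Calibrated liability shares.** The five components share the
exposure effect equally. The shared per-component coefficient s(θ) is
*not* θ/5: thresholding the component sum at ≥3 deflates the aggregate
effect, and a literal θ/5 share would make the induced marginal
log-odds of MetS per SD roughly 0.4–0.6·θ, leaving θ uninterpretable.
Instead s(θ) solves

    [logit P(MetS | z = +1) − logit P(MetS | z = −1)] / 2 = θ

with P(MetS | z) computed exactly as a Poisson-binomial tail over the
five components (Brent root-find, tolerance 1e-12). Per-variant direct
(pleiotropic) effects αᵢ — log-odds per allele bypassing the exposure
— are calibrated the same way. The confounder's outcome effect c_Y is
a nuisance path and keeps the plain c_Y/5 share.

Defaults emulate a middle-aged Korean community cohort: exposure
intercept 2.56 and noise SD 0.25 log-µmol/L (median log-Hcy ≈ 2.56,
IQR ≈ 0.35 in such cohorts), component baseline prevalences
(0.30, 0.35, 0.45, 0.35, 0.30) giving ~25–35% MetS, per-allele
exposure effects 0.03–0.06 for causal variants (the magnitude of the
strongest Hcy loci), covariates (age, sex, area, smoking, drinking,
RFS, BMI) drawn with realistic marginals but independent of genotype,
matching the MR exchangeability assumption. Seeding: one master seed;
stage seeds (genotypes, confounder, noise, components, covariates)
spawned via `numpy.random.SeedSequence`, so any stage reproduces in
isolation.

An auxiliary generator `simulate_ld_block` produces blocks of mutually
correlated variants (pairwise dosage r² equal to a target, via copying
from a shared latent haplotype) used to exercise LD-clumping; no
haplotype or coalescent model is implied.

## Summary-level simulator and what the tests show

`simulate_summary_stats` draws per-SNP GWAS estimates directly from
their large-sample distributions: β̂ˣᵢ ~ N(βˣᵢ, σ²/(n·2f(1−f))) and
β̂ʸᵢ ~ N(θβˣᵢ/σ + αᵢ, 1/(n·π(1−π)·2f(1−f))) for a logistic outcome
GWAS at prevalence π. Estimator calibration experiments (bias,
CI coverage, intercept-test size, breakdown under pleiotropy) run on
this generator: with an individual-level binary outcome the marginal
per-allele log-OR is not exactly θβˣ/σ (non-collapsibility of the odds
ratio plus the component thresholding), so cohort-level simulation
cannot separate estimator error from generative attenuation.
Summary-level simulation is the standard validation design for
summary-data MR estimators and realizes the intended conditions
exactly.

Consequently, passing tests demonstrate correct estimator behaviour
given summary statistics that obey the stated sampling model; they do
not certify the biases real data introduce (LD with untyped causal
variants, population structure, sample overlap between exposure and
outcome GWAS, winner's curse in instrument selection), none of which
the generators emulate.

Reference conditions for the stochastic checks: k = 25 instruments,
per-allele βˣ evenly spaced 0.03–0.06, MAF evenly spaced 0.2–0.5,
exposure GWAS n = 50,000, two outcome cohorts of n = 20,000 at π =
0.35, θ = 0.7. The exposure size is chosen so that I²GX ≈ 0.96, the
near-NOME regime in which MR–Egger's reference distribution is valid
(at n = 20,000 the Egger slope carries its documented regression-
dilution of about (1 − I²GX)·θ ≈ 0.05). Two properties sit near their
nominal values by construction and are worth knowing about:

* the NOME-weighted Cochran Q (weights βˣᵢ²/σʸᵢ², exposure error
  ignored) has expectation (k−1)·(1 + θ²σˣ²/σʸ²) ≈ 1.09·(k−1) at these
  conditions, not exactly k−1;
* the Egger intercept test uses a multiplicative overdispersion scale
  floored at 1 with a t(k−2) reference, which makes its size mildly
  conservative relative to the exact t test.

## QC, association and instrument rules

* QC order is fixed — missing-call rate > 0.01, then monomorphism
  (no minor allele), then HWE p < 1e-6 — so report counts are
  unambiguous; the filter is idempotent. The HWE test defaults to the
  1-df chi-square goodness of fit with the allele frequency estimated
  from counts (the conventional array-QC choice); an exact conditional
  test (mid-p by default) is available via `exact=True`. Monomorphic
  count triples return p = 1 (nothing to test).
* The logistic IRLS core declares convergence when the relative
  log-likelihood change drops below 1e-10 (≤50 iterations,
  step-halving), and raises a separation error when any coefficient
  passes ±30. Linear p-values use the t reference; logistic p-values
  the normal.
* Instrument selection is strict: p < 4 × 10⁻⁸ (Bonferroni for a
  ~420k-variant array), ties in the subsequent ordering broken
  lexicographically by SNP id so runs are deterministic.
* Clumping is greedy by ascending p with retention iff r² < threshold
  against every already-retained SNP; r² is the squared Pearson
  correlation of dosages over pairwise-complete samples, with
  zero-variance vectors defined as r² = 0. The default threshold is
  0.01; 0.1 is also in circulation for this analysis and both are
  exposed via configuration.
* Harmonization aligns outcome effects to the exposure's effect
  allele, resolving swapped and reverse-strand-complement reports,
  dropping irreconcilable allele pairs with a report entry.
  Palindromic (A/T, G/C) SNPs are dropped when the exposure EAF is
  known and MAF > 0.42 (strand unresolvable by frequency); with no
  frequency available they are kept but flagged. Finally (βˣ, βʸ) are
  jointly sign-flipped so βˣ ≥ 0, the orientation MR–Egger requires;
  estimates are invariant to any prior allele recoding.
* Outcome log-OR and SE can be reconstructed from a published OR and
  95% CI as β = ln OR, SE = (ln hi − ln lo)/(2·1.959964); the packaged
  five-SNP fixture uses exactly this rule, and its unpublished
  non-effect alleles are synthetic non-palindromic placeholders
  (documented in the file headers).

## Estimator details

* **IVW** defaults to fixed-effect (a single β/SE is what this
  analysis reports); multiplicative random effects (SE scaled by
  max(1, √(Q/(k−1)))) is available and suggested in the diagnostics
  when Q's p < 0.05. With k = 1 IVW reduces exactly to the Wald ratio.
* **Weighted median**: ratios sorted ascending, weights βˣᵢ²/σʸᵢ²
  normalized, weighted empirical CDF built on midpoint cumulative
  weights sᵢ = cumᵢ − wᵢ/2 and inverted at 0.5 by linear
  interpolation; estimates clamp to the extreme ratios outside
  [s₁, s_k]. SE is the SD of the estimator over 2000 seeded parametric
  resamples of the summary statistics. Note the interpolation means a
  SNP holding just over half the weight dominates asymptotically but
  does not exactly return its ratio at small k.
* **MR–Egger**: weighted least squares with free intercept, weights
  1/σʸᵢ²; SEs carry the overdispersion scale max(1, √(RSS_w/(k−2)))
  and p-values use t(k−2). Requires k ≥ 3 (positive residual df).
* **2SLS** uses the two-stage predictor-substitution form: OLS first
  stage, logistic second stage on the fitted exposure, coefficient
  rescaled by the SD of the *observed* exposure. This is faithful to
  the reported procedure but is not exactly the causal log-OR
  (non-collapsibility attenuates it by roughly 5–10% at θ ≈ 0.7); the
  result's diagnostics carry this note. The naive SE ignores
  first-stage uncertainty; a nonparametric bootstrap over samples
  (2000 resamples, percentile CI) is available. First-stage F below 10
  attaches a weak-instrument warning; the combined F is reported next
  to per-instrument values.
* **Meta-analysis placement**: outcome associations are pooled per SNP
  across cohorts (inverse-variance fixed effect, with a per-SNP
  across-cohort Q) *before* harmonization and MR; running MR per
  cohort and pooling afterwards is possible by calling the estimators
  per cohort.

## Degenerate inputs and numerical conventions

Zero exposure effect makes the Wald ratio undefined (error); |βˣ|/σˣ <
1 attaches a weak-instrument warning. I²GX truncates negative values
to 0 and returns 1 (flagged by convention) when all σˣ are exactly 0.
A perfect first-stage fit reports F = ∞. Empty QC output and empty
instrument selections raise and warn respectively rather than
propagating empty frames. p-values are floored at the smallest
positive float to keep downstream (0, 1] validation meaningful.

## Known limitations

* No LD-aware modelling beyond the clumping test block generator; no
  imputation from reference panels.
* The GRS/2SLS logistic second stage approximates the causal log-OR
  (see above); control-function estimators are out of scope.
* The packaged five-SNP fixture supports smoke runs of the report
  machinery, not value reproduction: the cohort-level outcome scans
  behind published multi-SNP MR estimates of this design are not
  public, and the printed per-SNP rows do not regenerate them under
  any standard estimator variant.
* Observational ORs are exposed in two exposure-unit conventions (per
  log-µmol/L and per SD) because published reports are ambiguous
  between them; the package never guesses which convention a given
  external number used.
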