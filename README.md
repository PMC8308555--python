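# hcymr

Mendelian randomization (MR) of homocysteine (Hcy) on metabolic
syndrome (MetS), packaged as a reusable, fully tested Python library.

Observationally, higher plasma Hcy accompanies MetS, but confounding
(diet, smoking, age) and reverse causation make the association hard to
interpret. MR sidesteps both by using genetic variants that raise Hcy —
*MTHFR* C677T (rs1801133) and other common loci — as instrumental
variables: genotypes are randomized at meiosis, so a genotype–MetS
association that flows through Hcy supports a causal effect. Individual
cohort records of the kind this analysis was designed for (Korean
community cohorts genotyped on a ~420k SNP array, MetS defined as ≥3 of
5 NCEP-ATP III components) are access-controlled, so the package ships
a synthetic cohort generator with the same statistical structure; every
stage is verifiable end to end without restricted data.

## What is implemented

* **`hcymr.synthdata`** — cohort simulator: genotypes in Hardy–Weinberg
  proportions, additive per-allele effects on log-Hcy, a shared
  confounder, liability-model MetS components scored ≥3-of-5, optional
  directional/balanced pleiotropy; plus a summary-statistics simulator
  for estimator calibration, and the MetS component/scoring rules
  (waist ≥90/85 cm by sex, BP ≥130/85 mmHg or treatment, TG ≥150,
  HDL <40/50, glucose ≥100 mg/dL — all configurable).
* **`hcymr.assoc`** — genotype QC (missingness >0.01, monomorphism,
  HWE p <1e-6; chi-square or exact test), per-SNP linear (exposure) and
  logistic (outcome) GWAS via an IRLS core, nested observational
  logistic models, quartile descriptive tables.
* **`hcymr.instruments`** — p < 4e-8 instrument selection, greedy
  LD-clumping at r² < 0.01 against reference genotypes, first-stage
  F-statistics, confounder screening, and harmonization of
  exposure/outcome summary statistics (allele alignment, strand
  complements, palindromic-SNP handling).
* **`hcymr.onesample`** — Wald ratio with delta-method SE, weighted
  genetic risk scores (additive/dominant), and two-stage least squares
  with a logistic second stage, reported per SD of log-Hcy.
* **`hcymr.twosample`** — IVW, weighted median (parametric-bootstrap
  SE), MR–Egger with intercept test, Cochran Q, I²GX, fixed-effect
  per-SNP meta-analysis across outcome cohorts, and a one-call
  `run_twosample` report.
* **`hcymr.pipeline` / CLI `hcymr`** — deterministic end-to-end runs
  with YAML config, per-stage artifacts and a manifest.

The estimators, for instruments i = 1..k with harmonized per-allele
effects (β̂ˣᵢ, σˣᵢ) on the exposure and (β̂ʸᵢ, σʸᵢ) on the outcome:

* Wald ratio: θ̂ᵢ = β̂ʸᵢ/β̂ˣᵢ,
  SE = √(σʸᵢ²/β̂ˣᵢ² + β̂ʸᵢ²σˣᵢ²/β̂ˣᵢ⁴)
* IVW: θ̂ = Σwᵢβ̂ˣᵢβ̂ʸᵢ / Σwᵢβ̂ˣᵢ², wᵢ = 1/σʸᵢ²
  (zero-intercept weighted regression of β̂ʸ on β̂ˣ)
* Weighted median: the weighted 50th percentile of the θ̂ᵢ with weights
  β̂ˣᵢ²/σʸᵢ², interpolated on midpoint cumulative weights
* MR–Egger: weighted regression β̂ʸᵢ = α + θβ̂ˣᵢ + εᵢ; slope = causal
  effect under InSIDE, intercept α = average directional pleiotropy
* Cochran Q = Σwᵢ(θ̂ᵢ − θ̂)², wᵢ = β̂ˣᵢ²/σʸᵢ²; I²GX = (Q_GX − (k−1))/Q_GX
  quantifies exposure-side measurement error (NOME diagnostic)

A five-SNP instrument table (rs12567136, rs1801133, rs2336377,
rs1624230, rs1836883 with their published per-allele effects on log-Hcy
and MetS) ships as a packaged fixture: `hcymr.load_five_snp_fixture()`.

## Worked example

```python
import numpy as np
from hcymr import simulate_summary_stats, run_twosample

exposure, outcomes = simulate_summary_stats(
    freqs=np.linspace(0.2, 0.5, 10),
    beta_exposure=np.linspace(0.03, 0.06, 10),   # log-umol/L per allele
    theta=0.7,                                   # true log-OR per SD
    n_exposure=50_000, n_outcome=(20_000, 20_000), seed=5)
report = run_twosample(exposure, outcomes, n_boot=2000, seed=5)
print(report["table"].round(3).to_string(index=False))
```

prints

```
         method  k  beta    se  ci_low  ci_high     p
weighted_median 10 0.644 0.034   0.578    0.710 0.000
            ivw 10 0.651 0.026   0.600    0.703 0.000
       mr_egger 10 0.564 0.122   0.325    0.804 0.002
```

with diagnostics `Q = 2.34 (p 0.98)`, Egger intercept `0.017 (p 0.48)`,
`I²GX 97.6%`: all three estimators bracket the generative effect of
0.7 log-odds of MetS per SD of log-Hcy (OR ≈ 2), the Q and intercept
tests find neither heterogeneity nor directional pleiotropy — there is
none by construction — and the high I²GX says exposure-side
measurement error is negligible, so the MR–Egger slope is trustworthy.
More scripts, one per capability, live in `examples/`.

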