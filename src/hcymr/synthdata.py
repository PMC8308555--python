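"""Synthetic cohort and summary-statistics generators.

Two levels of simulation are provided:

* :func:`simulate_cohort` draws individual-level data with the structure a
  Korean population-cohort MR analysis assumes: genotypes in
  Hardy-Weinberg proportions, additive per-allele effects on natural-log
  homocysteine (log µmol/L), a shared confounder, and a binary metabolic
  syndrome (MetS) phenotype scored as >=3 of 5 components, each component
  drawn from a logistic liability model carrying an equal share of the
  causal effect.

* :func:`simulate_summary_stats` draws per-SNP GWAS estimates directly
  from their sampling distributions at given cohort sizes.  This is the
  standard design for calibrating summary-data MR estimators (bias,
  coverage, test size): the generative per-allele outcome log-odds is
  exactly theta * beta_x / sd(exposure) plus any direct pleiotropic
  effect, so estimator error is not confounded with the non-collapsibility
  of the odds ratio that individual-level binary-outcome simulation
  necessarily introduces.

All randomness flows from one master seed through
``numpy.random.SeedSequence.spawn``, so each stage (genotypes,
confounder, noise, components, covariates) can be reproduced in
isolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit, logit

from .containers import GenotypeMatrix, ValidationError

__all__ = [
    "VariantSpec", "SimConfig", "simulate_genotypes", "simulate_ld_block",
    "simulate_cohort", "simulate_summary_stats", "mets_score",
    "derive_components", "COMPONENT_NAMES",
]

COMPONENT_NAMES = ["central_obesity", "high_tg", "low_hdl",
                   "high_bp", "high_glucose"]

#: default baseline component prevalences (central obesity, high TG,
#: low HDL, high BP, high glucose) chosen to give a MetS rate near the
#: ~35% seen in Korean community cohorts of this age range
DEFAULT_COMPONENT_PREVALENCES = (0.30, 0.35, 0.45, 0.35, 0.30)


@dataclass(frozen=True)
class VariantSpec:
    """One simulated variant: id, alleles and effect-allele frequency."""

    snp_id: str
    effect_allele: str
    other_allele: str
    frequency: float

    def __post_init__(self):
        if not (0.0 < self.frequency < 1.0):
            raise ValidationError(
                f"{self.snp_id}: allele frequency must be in (0,1), "
                f"got {self.frequency}")
        if self.effect_allele == self.other_allele:
            raise ValidationError(f"{self.snp_id}: alleles must differ")


@dataclass
class SimConfig:
    """Full generative specification for one synthetic cohort.

    Parameters
    ----------
    n_samples
        Cohort size.
    variants
        Variant specs; ids must be unique.
    beta_exposure
        Per-allele effect of each variant on log-Hcy (log µmol/L per
        effect allele); magnitudes ~0.03-0.06 are realistic for the
        strongest Hcy loci.
    theta
        Causal effect of 1 SD of log-Hcy on MetS liability
        (log-odds per SD).
    alpha_pleiotropy
        Per-variant direct variant -> outcome effect (log-odds per
        allele) bypassing the exposure; zero for valid instruments.
    confounder_effects
        (effect on exposure, effect on outcome liability) of one
        standard-normal confounder.
    exposure_noise_sd
        SD of the non-genetic, non-confounder exposure noise.
    missing_rate
        Per-call probability of a missing genotype.
    component_prevalences
        Baseline prevalence of each of the 5 MetS components at mean
        exposure; sets the liability intercepts.
    exposure_intercept
        Mean log-Hcy at zero dosage (log µmol/L).
    seed
        Master seed; all stage seeds are spawned from it.
    """

    n_samples: int
    variants: Sequence[VariantSpec]
    beta_exposure: Sequence[float]
    theta: float = 0.0
    alpha_pleiotropy: Sequence[float] | None = None
    confounder_effects: tuple[float, float] = (0.0, 0.0)
    exposure_noise_sd: float = 0.25
    missing_rate: float = 0.0
    component_prevalences: Sequence[float] = DEFAULT_COMPONENT_PREVALENCES
    exposure_intercept: float = 2.56
    seed: int = 0

    def __post_init__(self):
        if self.n_samples <= 0:
            raise ValidationError("n_samples must be positive")
        self.variants = [
            v if isinstance(v, VariantSpec) else VariantSpec(*v)
            for v in self.variants
        ]
        ids = [v.snp_id for v in self.variants]
        if len(set(ids)) != len(ids):
            raise ValidationError("variant ids must be distinct")
        if len(self.beta_exposure) != len(self.variants):
            raise ValidationError("beta_exposure length != number of variants")
        if self.alpha_pleiotropy is None:
            self.alpha_pleiotropy = [0.0] * len(self.variants)
        if len(self.alpha_pleiotropy) != len(self.variants):
            raise ValidationError("alpha_pleiotropy length != number of variants")
        if self.exposure_noise_sd < 0:
            raise ValidationError("exposure_noise_sd must be non-negative")
        if self.exposure_noise_sd == 0 and not any(self.beta_exposure):
            warnings.warn("exposure has zero variance (noise SD 0 and all "
                          "genetic effects 0)", UserWarning, stacklevel=2)
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValidationError("missing_rate must be in [0, 1)")
        if len(self.component_prevalences) != 5:
            raise ValidationError("need 5 component prevalences")
        for p in self.component_prevalences:
            if not (0.0 < p < 1.0):
                raise ValidationError("component prevalences must be in (0,1)")

    @property
    def frequencies(self) -> list[float]:
        return [v.frequency for v in self.variants]

    # -- YAML round trip -------------------------------------------------
    def to_yaml(self, path) -> None:
        doc = {
            "n_samples": self.n_samples,
            "variants": [[v.snp_id, v.effect_allele, v.other_allele,
                          float(v.frequency)] for v in self.variants],
            "beta_exposure": [float(b) for b in self.beta_exposure],
            "theta": float(self.theta),
            "alpha_pleiotropy": [float(a) for a in self.alpha_pleiotropy],
            "confounder_effects": [float(c) for c in self.confounder_effects],
            "exposure_noise_sd": float(self.exposure_noise_sd),
            "missing_rate": float(self.missing_rate),
            "component_prevalences": [float(p) for p in
                                      self.component_prevalences],
            "exposure_intercept": float(self.exposure_intercept),
            "seed": int(self.seed),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        doc["variants"] = [VariantSpec(*v) for v in doc["variants"]]
        doc["confounder_effects"] = tuple(doc.get("confounder_effects", (0, 0)))
        return cls(**doc)


def _variant_table(variants: Sequence[VariantSpec]) -> pd.DataFrame:
    return pd.DataFrame({
        "snp_id": [v.snp_id for v in variants],
        "chrom": ["1"] * len(variants),
        "pos": [1000 * (i + 1) for i in range(len(variants))],
        "effect_allele": [v.effect_allele for v in variants],
        "other_allele": [v.other_allele for v in variants],
    })


def _default_variants(freqs: Sequence[float]) -> list[VariantSpec]:
    return [VariantSpec(f"snp{i + 1}", "A", "G", float(f))
            for i, f in enumerate(freqs)]


def simulate_genotypes(freqs: Sequence[float], n: int,
                       missing_rate: float = 0.0,
                       seed: int | np.random.Generator = 0,
                       variants: Sequence[VariantSpec] | None = None,
                       ) -> GenotypeMatrix:
    """Draw unlinked genotypes in Hardy-Weinberg proportions.

    Each variant's dosage is Binomial(2, f) — genotype probabilities
    ((1-f)^2, 2f(1-f), f^2) — with calls knocked out independently at
    ``missing_rate``.
    """
    freqs = np.asarray(freqs, dtype=float)
    if freqs.ndim != 1 or freqs.size == 0:
        raise ValidationError("freqs must be a non-empty 1-D sequence")
    if not np.all(np.isfinite(freqs)) or np.any(freqs <= 0) or np.any(freqs >= 1):
        raise ValidationError("allele frequencies must be finite and in (0,1)")
    if not (0.0 <= missing_rate < 1.0):
        raise ValidationError("missing_rate must be in [0,1)")
    if n <= 0:
        raise ValidationError("n must be positive")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    dosage = rng.binomial(2, freqs, size=(n, freqs.size)).astype(float)
    if missing_rate > 0:
        dosage[rng.random(dosage.shape) < missing_rate] = np.nan
    if variants is None:
        variants = _default_variants(freqs)
    return GenotypeMatrix(
        sample_ids=np.array([f"s{i + 1}" for i in range(n)]),
        variants=_variant_table(variants),
        dosage=dosage,
    )


def simulate_ld_block(freq: float, n: int, block_size: int, r2: float,
                      seed: int | np.random.Generator = 0,
                      prefix: str = "blk") -> GenotypeMatrix:
    """Variants pairwise correlated at ~``r2`` (used to exercise clumping).

    Each variant's alleles copy a shared latent haplotype with
    probability c and are otherwise redrawn at frequency ``freq``; the
    pairwise dosage r^2 between block members is then c^4.
    """
    if not (0.0 <= r2 <= 1.0):
        raise ValidationError("r2 must be in [0,1]")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    # every variant copies the same latent haplotype, so a pair of block
    # variants correlates at c^2 on the dosage scale; c = r2^(1/4) makes
    # the pairwise dosage r^2 equal the target uniformly
    c = r2 ** 0.25
    hap_index = rng.random((n, 2)) < freq          # two haplotypes
    cols = []
    for _ in range(block_size):
        copy = rng.random((n, 2)) < c
        fresh = rng.random((n, 2)) < freq
        cols.append(np.where(copy, hap_index, fresh).sum(axis=1))
    dosage = np.column_stack(cols).astype(float)
    variants = [VariantSpec(f"{prefix}{j + 1}", "A", "G", freq)
                for j in range(block_size)]
    return GenotypeMatrix(
        sample_ids=np.array([f"s{i + 1}" for i in range(n)]),
        variants=_variant_table(variants),
        dosage=dosage,
    )


def mets_score(components) -> tuple[np.ndarray, np.ndarray]:
    """MetS score (0-5) and flag (score >= 3) from 5 binary components.

    Accepts a length-5 vector (one sample) or an (n, 5) array.  Missing
    values are an error: callers must impute or drop first.
    """
    arr = np.asarray(components, dtype=float)
    single = arr.ndim == 1
    if single:
        arr = arr[None, :]
    if arr.shape[1] != 5:
        raise ValidationError(f"expected 5 component flags, got {arr.shape[1]}")
    if np.isnan(arr).any():
        raise ValidationError("missing component flag; impute or drop first")
    if not np.isin(arr, (0.0, 1.0)).all():
        raise ValidationError("component flags must be 0/1")
    score = arr.sum(axis=1).astype(int)
    mets = score >= 3
    if single:
        return int(score[0]), bool(mets[0])
    return score, mets


#: configurable clinical cutoffs for the measured-value component flags
DEFAULT_CUTOFFS = {
    "waist_m": 90.0, "waist_f": 85.0,     # cm
    "tg": 150.0,                          # mg/dL
    "hdl_m": 40.0, "hdl_f": 50.0,         # mg/dL (low-HDL flag: below)
    "sbp": 130.0, "dbp": 85.0,            # mmHg
    "glucose": 100.0,                     # mg/dL fasting
}


def derive_components(waist_cm, sex, tg, hdl, sbp, dbp, glucose,
                      bp_treated, cutoffs: dict | None = None) -> np.ndarray:
    """Map measured values to the 5 MetS component flags.

    Central obesity uses sex-specific waist cutoffs (>=90 cm men,
    >=85 cm women); high blood pressure is >=130/85 mmHg *or* current
    antihypertensive treatment; TG / low-HDL / fasting-glucose flags
    follow the NCEP-ATP III cutoffs by default.  All comparisons at the
    cutoff are inclusive.  Returns an (n, 5) int array ordered as
    ``COMPONENT_NAMES``.
    """
    cut = dict(DEFAULT_CUTOFFS)
    if cutoffs:
        unknown = set(cutoffs) - set(cut)
        if unknown:
            raise ValidationError(f"unknown cutoff keys: {sorted(unknown)}")
        cut.update(cutoffs)
    waist = np.atleast_1d(np.asarray(waist_cm, dtype=float))
    sex = np.atleast_1d(np.asarray(sex))
    tg = np.atleast_1d(np.asarray(tg, dtype=float))
    hdl = np.atleast_1d(np.asarray(hdl, dtype=float))
    sbp = np.atleast_1d(np.asarray(sbp, dtype=float))
    dbp = np.atleast_1d(np.asarray(dbp, dtype=float))
    glucose = np.atleast_1d(np.asarray(glucose, dtype=float))
    bp_treated = np.atleast_1d(np.asarray(bp_treated)).astype(bool)
    for name, v in (("waist", waist), ("tg", tg), ("hdl", hdl),
                    ("sbp", sbp), ("dbp", dbp), ("glucose", glucose)):
        if not np.all(np.isfinite(v)):
            raise ValidationError(f"{name}: values must be finite")
        if np.any(v < 0):
            raise ValidationError(f"{name}: negative physiological value")
    if not np.isin(sex, ("M", "F")).all():
        raise ValidationError("sex must be 'M' or 'F'")
    male = sex == "M"
    obesity = np.where(male, waist >= cut["waist_m"], waist >= cut["waist_f"])
    high_tg = tg >= cut["tg"]
    low_hdl = np.where(male, hdl < cut["hdl_m"], hdl < cut["hdl_f"])
    high_bp = (sbp >= cut["sbp"]) | (dbp >= cut["dbp"]) | bp_treated
    high_glu = glucose >= cut["glucose"]
    return np.column_stack([obesity, high_tg, low_hdl,
                            high_bp, high_glu]).astype(int)


def _mets_prob_given_z(share: float, intercepts: np.ndarray,
                       z: float) -> float:
    """P(MetS | z): Poisson-binomial tail P(sum of 5 components >= 3)."""
    p = expit(intercepts + share * z)
    dist = np.array([1.0])
    for pj in p:
        dist = np.convolve(dist, [1.0 - pj, pj])
    return float(dist[3:].sum())


def _calibrate_component_share(theta: float, intercepts: np.ndarray) -> float:
    """Per-component liability coefficient such that the induced marginal
    effect of z on MetS equals theta.

    The 5 components share the exposure effect equally; a literal
    theta/5 share would make the marginal log-odds slope of MetS on z
    roughly 0.4-0.6 theta (thresholding at >=3 of 5 deflates the
    aggregate), so theta would lose its meaning as log-OR per SD.  The
    share is instead solved so that
    [logit P(MetS|z=+1) - logit P(MetS|z=-1)] / 2 = theta.
    """
    if theta == 0.0:
        return 0.0
    from scipy.optimize import brentq

    sign = 1.0 if theta > 0 else -1.0
    target = abs(theta)

    def gap(share: float) -> float:
        hi = _mets_prob_given_z(share, intercepts, 1.0)
        lo = _mets_prob_given_z(share, intercepts, -1.0)
        return 0.5 * (logit(hi) - logit(lo)) - target

    upper = max(2.0 * target, 1.0)
    while gap(upper) < 0:
        upper *= 2.0
        if upper > 1e3:
            raise ValidationError(f"cannot calibrate component share for "
                                  f"theta={theta}")
    return sign * brentq(gap, 0.0, upper, xtol=1e-12)


def _covariate_block(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Non-genetic covariates with realistic cohort marginals.

    Independent of genotype by construction, matching the MR
    exchangeability assumption.
    """
    return pd.DataFrame({
        "age": np.round(rng.normal(58.0, 9.0, n)).clip(40, 90),
        "sex": np.where(rng.random(n) < 0.53, "F", "M"),
        "area": np.where(rng.random(n) < 0.513, "urban", "rural"),
        "smoking": (rng.random(n) < 0.152).astype(int),
        "drinking": (rng.random(n) < 0.437).astype(int),
        "rfs": np.round(rng.normal(19.0, 8.0, n)).clip(0, 47),
        "bmi": np.round(rng.normal(24.4, 3.1, n), 1).clip(14, 45),
    })


def simulate_cohort(config: SimConfig) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Individual-level cohort: genotypes, exposure, components, MetS.

    Generative model::

        log_hcy = intercept + sum_i beta_i * dosage_i + c_X * U + eps
        z       = standardized log_hcy (within-cohort SD)
        P(component_j) = expit(logit(prev_j) + share(theta) z
                               + (c_Y/5) U + sum_i share(alpha_i) dosage_i)
        mets    = (sum_j component_j >= 3)

    The per-component shares of the exposure effect and of each direct
    (pleiotropic) variant effect are calibrated (see
    :func:`_calibrate_component_share`) so that theta reads as the
    induced marginal log-odds of MetS per SD of log-Hcy and alpha_i as
    the marginal log-odds per effect allele.  Missing dosages enter the
    exposure sum mean-imputed; the phenotype table stores both the
    score and the flag.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_geno, rng_conf, rng_noise, rng_comp, rng_cov = (
        np.random.default_rng(s) for s in ss.spawn(5))

    g = simulate_genotypes(config.frequencies, config.n_samples,
                           missing_rate=config.missing_rate,
                           seed=rng_geno, variants=config.variants)
    n = config.n_samples
    beta = np.asarray(config.beta_exposure, dtype=float)
    alpha = np.asarray(config.alpha_pleiotropy, dtype=float)
    c_x, c_y = config.confounder_effects

    u = rng_conf.standard_normal(n)
    eps = rng_noise.standard_normal(n) * config.exposure_noise_sd
    dose = g.mean_imputed()
    log_hcy = config.exposure_intercept + dose @ beta + c_x * u + eps

    sd = log_hcy.std(ddof=1)
    z = (log_hcy - log_hcy.mean()) / sd if sd > 0 else np.zeros(n)

    intercepts = logit(np.asarray(config.component_prevalences, dtype=float))
    # equal liability share per component; magnitude calibrated so theta
    # reads as log-OR of MetS per SD of log-Hcy
    share = _calibrate_component_share(config.theta, intercepts)
    alpha_share = np.array([_calibrate_component_share(a, intercepts)
                            for a in alpha])
    eta = (intercepts[None, :]
           + share * z[:, None]
           + (c_y / 5.0) * u[:, None]
           + (dose @ alpha_share)[:, None])
    comps = (rng_comp.random((n, 5)) < expit(eta)).astype(int)
    score, mets = mets_score(comps)

    pheno = _covariate_block(n, rng_cov)
    pheno.insert(0, "sample_id", g.sample_ids)
    pheno.insert(1, "log_hcy", log_hcy)
    for j, name in enumerate(COMPONENT_NAMES):
        pheno[name] = comps[:, j]
    pheno["mets_score"] = score
    pheno["mets"] = mets.astype(int)
    return g, pheno


def simulate_summary_stats(freqs: Sequence[float],
                           beta_exposure: Sequence[float],
                           theta: float,
                           *,
                           alpha_pleiotropy: Sequence[float] | None = None,
                           exposure_sd: float = 0.25,
                           outcome_prevalence: float = 0.35,
                           n_exposure: int = 20_000,
                           n_outcome: Sequence[int] = (20_000,),
                           seed: int | np.random.Generator = 0,
                           exposure_scale: str = "sd",
                           ) -> tuple[pd.DataFrame, list[pd.DataFrame]]:
    """Per-SNP GWAS estimates drawn from their sampling distributions.

    True effects: exposure beta_x per allele (log-Hcy units); outcome
    log-OR per allele ``theta * beta_x / exposure_sd + alpha``.  Sampling
    SEs use the standard large-sample forms for an additive-dosage
    regression: ``se_x = exposure_sd / sqrt(n 2f(1-f))`` and
    ``se_y = 1 / sqrt(n pi(1-pi) 2f(1-f))`` for a logistic outcome GWAS
    at prevalence pi.  One exposure table and one outcome table per
    cohort size in ``n_outcome`` are returned, all oriented to the same
    effect allele.

    With ``exposure_scale='sd'`` (default) the exposure table reports
    betas/SEs per SD of log-Hcy, the convention under which per-SNP
    ratios — and every downstream MR estimate — read directly as
    log-OR per 1-SD exposure increase (theta's scale);
    ``'unit'`` keeps raw log-µmol/L units, and ratios then estimate
    theta / exposure_sd.
    """
    if exposure_scale not in ("sd", "unit"):
        raise ValidationError("exposure_scale must be 'sd' or 'unit'")
    from scipy import stats

    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    freqs = np.asarray(freqs, dtype=float)
    beta_x = np.asarray(beta_exposure, dtype=float)
    k = freqs.size
    if beta_x.size != k:
        raise ValidationError("beta_exposure length != number of variants")
    alpha = (np.zeros(k) if alpha_pleiotropy is None
             else np.asarray(alpha_pleiotropy, dtype=float))
    if alpha.size != k:
        raise ValidationError("alpha_pleiotropy length != number of variants")
    het = 2.0 * freqs * (1.0 - freqs)
    ids = [f"snp{i + 1}" for i in range(k)]

    def _table(true_beta, se, n, trait):
        est = rng.normal(true_beta, se)
        return pd.DataFrame({
            "snp_id": ids, "effect_allele": "A", "other_allele": "G",
            "beta": est, "se": se,
            "p": np.maximum(2.0 * stats.norm.sf(np.abs(est / se)),
                            np.finfo(float).tiny),
            "n": n, "trait": trait, "eaf": freqs,
        })

    se_x = exposure_sd / np.sqrt(n_exposure * het)
    if exposure_scale == "sd":
        exposure = _table(beta_x / exposure_sd, se_x / exposure_sd,
                          n_exposure, "exposure")
    else:
        exposure = _table(beta_x, se_x, n_exposure, "exposure")

    true_y = theta * beta_x / exposure_sd + alpha
    pi = outcome_prevalence
    outcomes = []
    for nc in n_outcome:
        se_y = 1.0 / np.sqrt(nc * pi * (1.0 - pi) * het)
        outcomes.append(_table(true_y, se_y, nc, "outcome"))
    return exposure, outcomes
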