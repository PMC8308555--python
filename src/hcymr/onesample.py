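"""One-sample Mendelian randomization.

Wald-ratio estimator with delta-method SE, two-stage least squares with
a logistic second stage (two-stage predictor substitution), and
weighted genetic-risk-score construction.  Estimates are reported per
SD of the observed log-exposure.
"""

from __future__ import annotations

import numpy as np

from ._glm import design_matrix, fit_logistic, fit_ols
from .containers import GRS, GenotypeMatrix, MRResult, ValidationError, Z95
from .instruments import f_statistic

__all__ = ["wald_ratio", "build_grs", "tsls"]

WEAK_F_THRESHOLD = 10.0


def wald_ratio(beta_x: float, se_x: float, beta_y: float,
               se_y: float) -> MRResult:
    """Single-instrument causal estimate beta_y / beta_x.

    SE by the first-order bivariate delta method with independent
    numerator/denominator errors:
    sqrt(se_y^2/beta_x^2 + beta_y^2 se_x^2 / beta_x^4).  A weak
    instrument (|beta_x|/se_x < 1) attaches a warning rather than
    failing.
    """
    if beta_x == 0:
        raise ValidationError("beta_x = 0: Wald ratio undefined")
    if se_x < 0 or se_y < 0:
        raise ValidationError("standard errors must be non-negative")
    est = beta_y / beta_x
    se = np.sqrt(se_y ** 2 / beta_x ** 2
                 + beta_y ** 2 * se_x ** 2 / beta_x ** 4)
    warns = []
    if se_x > 0 and abs(beta_x) / se_x < 1.0:
        warns.append("weak instrument: |beta_x|/se_x < 1")
    return MRResult.from_wald("wald_ratio", float(est), float(se),
                              k_instruments=1, warnings=warns)


def build_grs(g: GenotypeMatrix, weights: dict[str, float],
              model: str = "additive") -> GRS:
    """Weighted count of exposure-increasing alleles per sample.

    ``weights`` map SNP id -> per-allele exposure effect, already
    oriented to the exposure-increasing allele of the dosage coding.
    The additive model sums weight x dosage; the dominant model replaces
    dosage with a carrier indicator (dosage >= 1).  Missing dosages are
    mean-imputed (indicator mean for the dominant model).
    """
    if model not in ("additive", "dominant"):
        raise ValidationError("model must be 'additive' or 'dominant'")
    absent = sorted(set(weights) - set(g.snp_ids))
    if absent:
        raise ValidationError(f"weights given for SNPs absent from "
                              f"genotypes: {absent}")
    score = np.zeros(g.n_samples)
    for snp, w in weights.items():
        dose = g.column(snp)
        if model == "dominant":
            carrier = np.where(np.isnan(dose), np.nan, (dose >= 1).astype(float))
            x = carrier
        else:
            x = dose
        mean = np.nanmean(x) if np.isnan(x).any() else None
        if mean is not None:
            x = np.where(np.isnan(x), mean, x)
        score += w * x
    return GRS(score=score, weights=dict(weights), model=model)


def tsls(iv, exposure, outcome, covariates=None,
         second_stage: str = "logistic", scale: str = "sd",
         se_method: str = "naive", n_boot: int = 2000,
         seed: int = 0) -> MRResult:
    """Two-stage least squares with a logistic second stage.

    Stage 1 regresses the exposure on the instrument(s) plus covariates
    by OLS; stage 2 regresses the binary outcome on the stage-1 fitted
    exposure (plus covariates) by logistic regression.  The coefficient
    on fitted exposure is rescaled to per-SD of the *observed* exposure
    when ``scale='sd'``.  This two-stage predictor substitution is not
    exactly the causal log-OR (non-collapsibility); the result carries a
    note in its diagnostics.

    ``iv`` may be a GRS, a 1-D score vector, a 2-D instrument matrix, or
    a GenotypeMatrix (mean-imputed dosages, all SNPs jointly).
    ``se_method`` is ``"naive"`` (stage-2 Wald, ignores first-stage
    noise) or ``"bootstrap"`` (nonparametric over samples, percentile
    CI).  A first-stage F below 10 attaches a weak-instrument warning.
    """
    if isinstance(iv, GRS):
        Z = iv.score[:, None]
    elif isinstance(iv, GenotypeMatrix):
        Z = iv.mean_imputed()
    else:
        Z = np.asarray(iv, dtype=float)
        if Z.ndim == 1:
            Z = Z[:, None]
    x = np.asarray(exposure, dtype=float)
    y = np.asarray(outcome, dtype=float)
    n = len(x)
    if Z.shape[0] != n or len(y) != n:
        raise ValidationError("instrument, exposure, outcome lengths differ")
    if second_stage not in ("logistic", "linear"):
        raise ValidationError("second_stage must be 'logistic' or 'linear'")
    if scale not in ("sd", "unit"):
        raise ValidationError("scale must be 'sd' or 'unit'")

    sd = x.std(ddof=1) if scale == "sd" else 1.0

    def _fit(Zb, xb, yb, covb):
        base, names = design_matrix(covb, len(xb))
        X1 = np.column_stack([base, Zb])
        s1 = fit_ols(X1, xb, names + [f"iv{j}" for j in range(Zb.shape[1])])
        fitted = X1 @ s1.beta
        X2 = np.column_stack([base, fitted])
        fitter = fit_logistic if second_stage == "logistic" else fit_ols
        s2 = fitter(X2, yb, names + ["fitted_exposure"])
        return s2.beta[-1] * sd, s2.se[-1] * sd

    est, se_naive = _fit(Z, x, y, covariates)
    f_stat, r2 = f_statistic(x, Z, covariates)
    warns = []
    if f_stat < WEAK_F_THRESHOLD:
        warns.append(f"weak instrument: first-stage F = {f_stat:.2f} < 10")

    diagnostics = {
        "first_stage_F": f_stat, "first_stage_r2": r2,
        "k_iv": Z.shape[1], "exposure_sd": float(sd),
        "note": ("two-stage predictor substitution with a logistic second "
                 "stage approximates, not equals, the causal log-OR; "
                 "naive SE ignores first-stage uncertainty"
                 if second_stage == "logistic" else ""),
        "se_method": se_method,
    }
    if se_method == "naive":
        return MRResult.from_wald("tsls", float(est), float(se_naive),
                                  k_instruments=Z.shape[1],
                                  diagnostics=diagnostics, warnings=warns)
    if se_method != "bootstrap":
        raise ValidationError("se_method must be 'naive' or 'bootstrap'")
    rng = np.random.default_rng(seed)
    import pandas as pd

    cov_df = covariates if covariates is None else pd.DataFrame(covariates)
    draws = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        covb = None if cov_df is None else cov_df.iloc[idx]
        try:
            draws[b], _ = _fit(Z[idx], x[idx], y[idx], covb)
        except Exception:
            draws[b] = np.nan
    draws = draws[np.isfinite(draws)]
    se = float(draws.std(ddof=1))
    lo, hi = np.percentile(draws, [2.5, 97.5])
    from scipy import stats as st

    res = MRResult(method="tsls", estimate=float(est), se=se,
                   ci_low=float(lo), ci_high=float(hi),
                   p=float(2 * st.norm.sf(abs(est / se))) if se > 0 else 0.0,
                   k_instruments=Z.shape[1], diagnostics=diagnostics,
                   warnings=warns)
    res.diagnostics["n_boot_effective"] = int(draws.size)
    return res
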