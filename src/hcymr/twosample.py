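"""Two-sample Mendelian randomization estimators and diagnostics.

Operates on harmonized per-SNP summary statistics: inverse-variance
weighted (IVW) estimator, weighted median, MR-Egger regression with its
intercept (directional-pleiotropy) test, Cochran's Q heterogeneity
statistic, the I2_GX measurement-error diagnostic for MR-Egger, and
fixed-effect meta-analysis of per-SNP outcome associations across
cohorts.  ``run_twosample`` wires the stages into one report.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import (HarmonizedInstrument, MRResult, ValidationError,
                         validate_summary_stats, Z95)
from .instruments import harmonize, orient_instruments

__all__ = ["meta_fixed", "ivw", "weighted_median", "mr_egger",
           "cochran_q", "i2_gx", "run_twosample"]


def _arrays(instr: list[HarmonizedInstrument]):
    bx = np.array([i.beta_x for i in instr], dtype=float)
    sx = np.array([i.se_x for i in instr], dtype=float)
    by = np.array([i.beta_y for i in instr], dtype=float)
    sy = np.array([i.se_y for i in instr], dtype=float)
    return bx, sx, by, sy


def meta_fixed(records: list[pd.DataFrame]) -> pd.DataFrame:
    """Inverse-variance fixed-effect pooling of per-SNP outcome betas.

    Each input table follows the summary-statistics schema; SNPs are
    pooled over the cohorts that report them (allele orientation is
    aligned to the first cohort, flipping swapped reports; an
    irreconcilable allele pair raises).  Adds a per-SNP across-cohort
    heterogeneity Q.
    """
    if len(records) < 1:
        raise ValidationError("need at least one cohort table")
    tables = [validate_summary_stats(t).set_index("snp_id") for t in records]
    base = tables[0]
    rows = []
    for snp in base.index:
        betas, ses, ns = [], [], []
        ea = base.loc[snp, "effect_allele"]
        oa = base.loc[snp, "other_allele"]
        for t in tables:
            if snp not in t.index:
                continue
            r = t.loc[snp]
            if (r["effect_allele"], r["other_allele"]) == (ea, oa):
                b = r["beta"]
            elif (r["effect_allele"], r["other_allele"]) == (oa, ea):
                b = -r["beta"]
            else:
                raise ValidationError(
                    f"{snp}: allele mismatch across cohorts "
                    f"({ea}/{oa} vs {r['effect_allele']}/{r['other_allele']}); "
                    "harmonize first")
            betas.append(float(b))
            ses.append(float(r["se"]))
            ns.append(int(r["n"]))
        w = 1.0 / np.square(ses)
        pooled = float(np.sum(w * betas) / np.sum(w))
        pooled_se = float(np.sum(w) ** -0.5)
        q = float(np.sum(w * (np.array(betas) - pooled) ** 2))
        q_df = len(betas) - 1
        row = {"snp_id": snp, "effect_allele": ea, "other_allele": oa,
               "beta": pooled, "se": pooled_se,
               "p": 2.0 * stats.norm.sf(abs(pooled / pooled_se)),
               "n": int(np.sum(ns)), "trait": base.loc[snp, "trait"],
               "n_cohorts": len(betas), "q_cohort": q,
               "q_cohort_p": float(stats.chi2.sf(q, q_df)) if q_df > 0 else np.nan}
        if "eaf" in base.columns:
            row["eaf"] = base.loc[snp, "eaf"]
        rows.append(row)
    return pd.DataFrame(rows)


def ivw(instr: list[HarmonizedInstrument],
        model: str = "fixed") -> MRResult:
    """Inverse-variance weighted estimate of the causal effect.

    Equivalent to a zero-intercept weighted regression of beta_y on
    beta_x with weights 1/se_y^2.  ``model='fixed'`` uses the analytic
    SE; ``'multiplicative_random'`` scales it by
    max(1, sqrt(Q/(k-1))).  With k=1 this reduces to the Wald ratio.
    """
    if len(instr) == 0:
        raise ValidationError("IVW needs at least one instrument")
    if model not in ("fixed", "multiplicative_random"):
        raise ValidationError("model must be 'fixed' or "
                              "'multiplicative_random'")
    bx, sx, by, sy = _arrays(instr)
    w = bx ** 2 / sy ** 2
    est = float(np.sum(bx * by / sy ** 2) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    k = len(instr)
    diagnostics = {"model": model}
    if k >= 2:
        q, q_df, q_p = cochran_q(instr, est)
        diagnostics.update(Q=q, Q_df=q_df, Q_p=q_p)
        if model == "multiplicative_random":
            se *= max(1.0, np.sqrt(q / (k - 1)))
        elif q_p < 0.05:
            diagnostics["suggestion"] = ("heterogeneity detected (Q p < "
                                         "0.05); consider "
                                         "multiplicative_random")
    return MRResult.from_wald("ivw", est, se, k_instruments=k,
                              diagnostics=diagnostics)


def _weighted_median_estimate(ratios: np.ndarray,
                              weights: np.ndarray) -> float:
    """Interpolated weighted median: the weighted empirical CDF built on
    midpoint cumulative weights is inverted at 0.5."""
    order = np.argsort(ratios, kind="mergesort")
    r = ratios[order]
    w = weights[order] / weights.sum()
    s = np.cumsum(w) - 0.5 * w
    if 0.5 <= s[0]:
        return float(r[0])
    if 0.5 >= s[-1]:
        return float(r[-1])
    j = int(np.searchsorted(s, 0.5, side="right") - 1)
    if s[j] == 0.5:
        return float(r[j])
    return float(r[j] + (r[j + 1] - r[j]) * (0.5 - s[j]) / (s[j + 1] - s[j]))


def weighted_median(instr: list[HarmonizedInstrument],
                    n_boot: int = 2000, seed: int = 0) -> MRResult:
    """Weighted median of per-SNP Wald ratios.

    Consistent when instruments carrying >= 50% of the weight are valid.
    Weights are beta_x^2/se_y^2 (inverse variance of each ratio under
    NOME); the SE is the SD of the estimator over ``n_boot`` parametric
    resamples of the summary statistics.
    """
    if len(instr) < 3:
        raise ValidationError("weighted median needs k >= 3 instruments")
    bx, sx, by, sy = _arrays(instr)
    ratios = by / bx
    weights = bx ** 2 / sy ** 2
    est = _weighted_median_estimate(ratios, weights)
    rng = np.random.default_rng(seed)
    k = len(instr)
    draws = np.empty(n_boot)
    for b in range(n_boot):
        bxb = rng.normal(bx, sx)
        byb = rng.normal(by, sy)
        ok = bxb != 0
        draws[b] = _weighted_median_estimate(
            byb[ok] / bxb[ok], bxb[ok] ** 2 / sy[ok] ** 2)
    se = float(draws.std(ddof=1))
    return MRResult.from_wald("weighted_median", est, se, k_instruments=k,
                              diagnostics={"n_boot": n_boot})


def mr_egger(instr: list[HarmonizedInstrument]) -> MRResult:
    """MR-Egger: weighted regression of beta_y on beta_x, free intercept.

    Instruments are oriented so beta_x >= 0; weights 1/se_y^2.  The
    slope estimates the causal effect under InSIDE; the intercept
    estimates average directional pleiotropy.  SEs carry a
    multiplicative overdispersion scale max(1, sqrt(RSS_w/(k-2))) and
    p-values use the t distribution with k-2 df.
    """
    if len(instr) <= 2:
        raise ValidationError("MR-Egger needs k >= 3 instruments "
                              "(k-2 residual df)")
    instr = orient_instruments(instr)
    bx, sx, by, sy = _arrays(instr)
    k = len(instr)
    w = 1.0 / sy ** 2
    X = np.column_stack([np.ones(k), bx])
    xtwx = (X * w[:, None]).T @ X
    coef = np.linalg.solve(xtwx, (X * w[:, None]).T @ by)
    resid = by - X @ coef
    rss_w = float(np.sum(w * resid ** 2))
    phi = max(1.0, rss_w / (k - 2))
    cov = np.linalg.inv(xtwx) * phi
    se = np.sqrt(np.diag(cov))
    slope, intercept = float(coef[1]), float(coef[0])
    slope_se, int_se = float(se[1]), float(se[0])
    slope_p = 2.0 * stats.t.sf(abs(slope / slope_se), k - 2)
    int_p = 2.0 * stats.t.sf(abs(intercept / int_se), k - 2)
    diagnostics = {
        "egger_intercept": intercept, "intercept_se": int_se,
        "intercept_p": float(int_p), "overdispersion_scale": phi,
        "i2_gx": i2_gx(instr),
    }
    return MRResult(method="mr_egger", estimate=slope, se=slope_se,
                    ci_low=slope - Z95 * slope_se,
                    ci_high=slope + Z95 * slope_se,
                    p=float(slope_p), k_instruments=k,
                    diagnostics=diagnostics)


def cochran_q(instr: list[HarmonizedInstrument],
              theta: float) -> tuple[float, int, float]:
    """Cochran's Q of per-SNP ratios about ``theta``.

    Q = sum w_i (ratio_i - theta)^2 with w_i = beta_x^2/se_y^2; df = k-1;
    p from the chi-square upper tail.
    """
    if len(instr) < 2:
        raise ValidationError("Cochran Q needs k >= 2 instruments")
    bx, sx, by, sy = _arrays(instr)
    ratios = by / bx
    w = bx ** 2 / sy ** 2
    q = float(np.sum(w * (ratios - theta) ** 2))
    df = len(instr) - 1
    return q, df, float(stats.chi2.sf(q, df))


def i2_gx(instr: list[HarmonizedInstrument]) -> float:
    """I2_GX: relative precision of the SNP-exposure estimates.

    Q_GX = sum (beta_x_i - weighted mean)^2 / se_x_i^2 on the oriented
    betas; I2_GX = max(0, (Q_GX - (k-1))/Q_GX).  Values near 1 mean the
    exposure effects are measured essentially without error (NOME
    holds); low values signal regression-dilution bias in MR-Egger.
    """
    if len(instr) < 2:
        raise ValidationError("I2_GX needs k >= 2 instruments")
    instr = orient_instruments(instr)
    bx, sx, _, _ = _arrays(instr)
    if np.all(sx == 0):
        return 1.0  # degenerate: no measurement error by construction
    w = 1.0 / sx ** 2
    mean = np.sum(w * bx) / np.sum(w)
    q_gx = float(np.sum((bx - mean) ** 2 / sx ** 2))
    if q_gx == 0.0:
        return 0.0
    return float(max(0.0, (q_gx - (len(instr) - 1)) / q_gx))


def run_twosample(exposure: pd.DataFrame,
                  outcomes: list[pd.DataFrame],
                  p_threshold: float | None = None,
                  ivw_model: str = "fixed",
                  n_boot: int = 2000, seed: int = 0,
                  drop_palindromic_maf: float = 0.42) -> dict:
    """Full two-sample MR on summary statistics.

    Pools outcome associations across cohorts per SNP (fixed-effect),
    harmonizes to the exposure's effect alleles, optionally re-applies
    the exposure p-value threshold, then runs IVW, weighted median and
    MR-Egger with Cochran Q and I2_GX diagnostics.  Returns a dict with
    a tidy per-method ``table`` (method, beta, CI, p — the layout of a
    standard MR report), the harmonized ``instruments`` frame, the
    ``meta`` pooled outcome table and a ``diagnostics`` dict.
    """
    exposure = validate_summary_stats(exposure)
    if p_threshold is not None:
        keep = exposure["p"] < p_threshold
        exposure = exposure[keep]
        if exposure.empty:
            raise ValidationError(f"no exposure SNP passes p < {p_threshold:g}")
    pooled = meta_fixed(outcomes) if len(outcomes) > 1 else \
        validate_summary_stats(outcomes[0])
    instr, harmon_report = harmonize(
        exposure, pooled, drop_palindromic_maf=drop_palindromic_maf)
    if len(instr) < 3:
        raise ValidationError(
            f"only {len(instr)} harmonizable instruments; need >= 3")
    res_ivw = ivw(instr, model=ivw_model)
    res_wm = weighted_median(instr, n_boot=n_boot, seed=seed)
    res_egger = mr_egger(instr)
    q, q_df, q_p = cochran_q(instr, res_ivw.estimate)
    i2 = i2_gx(instr)
    rows = []
    for res in (res_wm, res_ivw, res_egger):
        rows.append({"method": res.method, "k": res.k_instruments,
                     "beta": res.estimate, "se": res.se,
                     "ci_low": res.ci_low, "ci_high": res.ci_high,
                     "p": res.p})
    table = pd.DataFrame(rows)
    from .containers import instruments_to_frame

    return {
        "table": table,
        "results": {r.method: r for r in (res_ivw, res_wm, res_egger)},
        "instruments": instruments_to_frame(instr),
        "harmonization": harmon_report,
        "meta": pooled,
        "diagnostics": {
            "Q": q, "Q_df": q_df, "Q_p": q_p,
            "egger_intercept": res_egger.diagnostics["egger_intercept"],
            "intercept_se": res_egger.diagnostics["intercept_se"],
            "intercept_p": res_egger.diagnostics["intercept_p"],
            "i2_gx": i2,
        },
    }
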