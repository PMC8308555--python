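"""Per-SNP association engine and genotype QC.

Covers the GWAS stage of the pipeline: variant quality filters
(missingness, monomorphism, Hardy-Weinberg equilibrium), per-variant
linear regression of log-homocysteine on dosage, per-variant logistic
regression of metabolic-syndrome status on dosage, the nested
observational Hcy->MetS logistic models, and quartile descriptive
tables.  All regressions use an additive dosage coding and drop
samples with a missing dosage per variant.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from ._glm import design_matrix, fit_logistic, fit_ols
from .containers import (EmptyResultError, GenotypeMatrix, QCReport,
                         ValidationError, Z95)

__all__ = ["hwe_test", "qc_filter", "linear_assoc", "logistic_assoc",
           "observational_or", "quartile_summary"]


def hwe_test(counts, exact: bool = False, midp: bool = True) -> float:
    """Hardy-Weinberg equilibrium p-value from genotype counts.

    Parameters
    ----------
    counts
        ``(n_AA, n_Aa, n_aa)`` non-negative genotype counts (total > 0).
    exact
        If True use the exact conditional test on the number of
        heterozygotes (mid-p by default) instead of the default 1-df
        chi-square goodness-of-fit with the allele frequency estimated
        from the counts.

    A monomorphic triple (one allele absent) has nothing to test and
    returns 1.0.
    """
    n_aa, n_ab, n_bb = counts
    for c in (n_aa, n_ab, n_bb):
        if c < 0 or c != int(c):
            raise ValidationError("genotype counts must be non-negative integers")
    n = n_aa + n_ab + n_bb
    if n == 0:
        raise ValidationError("total genotype count is zero")
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n_bb + n_ab
    if n_a == 0 or n_b == 0:
        return 1.0  # monomorphic: no polymorphism to test
    if exact:
        return _hwe_exact(n_aa, n_ab, n_bb, midp=midp)
    p = n_a / (2 * n)  # frequency of the allele counted by n_aa
    expected = np.array([n * p ** 2, n * 2 * p * (1 - p), n * (1 - p) ** 2])
    observed = np.array([n_aa, n_ab, n_bb], dtype=float)
    stat = float(((observed - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(stat, 1))


def _hwe_exact(n_aa: int, n_ab: int, n_bb: int, midp: bool = True) -> float:
    """Exact HWE test: sum probabilities of heterozygote counts no more
    probable than the observed one, conditional on allele counts."""
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    rare = min(n_a, 2 * n - n_a)
    # heterozygote count shares parity with the rare-allele count
    het_values = range(rare % 2, rare + 1, 2)
    logs = {}
    for het in het_values:
        hom_rare = (rare - het) // 2
        hom_common = n - het - hom_rare
        logs[het] = (math.lgamma(n + 1)
                     - math.lgamma(hom_rare + 1) - math.lgamma(het + 1)
                     - math.lgamma(hom_common + 1)
                     + het * math.log(2)
                     + math.lgamma(rare + 1) + math.lgamma(2 * n - rare + 1)
                     - math.lgamma(2 * n + 1))
    mx = max(logs.values())
    probs = {h: math.exp(v - mx) for h, v in logs.items()}
    total = sum(probs.values())
    obs = probs[n_ab]
    tail = sum(v for v in probs.values() if v <= obs * (1 + 1e-12))
    p = (tail - 0.5 * obs) / total if midp else tail / total
    return float(min(max(p, 0.0), 1.0))


def qc_filter(g: GenotypeMatrix, max_missing: float = 0.01,
              hwe_alpha: float = 1e-6,
              hwe_exact: bool = False) -> tuple[GenotypeMatrix, QCReport]:
    """Variant QC in fixed order: missingness, monomorphism, HWE.

    Removes variants with missing-call rate strictly above
    ``max_missing``, then variants with no minor allele among the
    remaining calls, then variants whose HWE p-value falls below
    ``hwe_alpha``.  The order is fixed so the report counts are
    unambiguous.  Idempotent: re-filtering a filtered matrix removes
    nothing.
    """
    if g.n_variants == 0:
        raise ValidationError("empty genotype matrix")
    removed: dict[str, list[str]] = {"missingness": [], "monomorphic": [],
                                     "hwe": []}
    ids = g.snp_ids
    miss = g.missing_rate()
    surviving = []
    for j, snp in enumerate(ids):
        if miss[j] > max_missing:
            removed["missingness"].append(snp)
        else:
            surviving.append(snp)
    stage2 = []
    for snp in surviving:
        counts = g.genotype_counts(snp)
        n_a = 2 * counts[0] + counts[1]
        n_b = 2 * counts[2] + counts[1]
        if n_a == 0 or n_b == 0:
            removed["monomorphic"].append(snp)
        else:
            stage2.append(snp)
    retained = []
    for snp in stage2:
        if hwe_test(g.genotype_counts(snp), exact=hwe_exact) < hwe_alpha:
            removed["hwe"].append(snp)
        else:
            retained.append(snp)
    report = QCReport(
        n_input=g.n_variants,
        n_removed_missingness=len(removed["missingness"]),
        n_removed_monomorphic=len(removed["monomorphic"]),
        n_removed_hwe=len(removed["hwe"]),
        retained=retained,
        removed=removed,
    )
    if not retained:
        raise EmptyResultError(
            f"all {g.n_variants} variants removed by QC "
            f"(missingness {report.n_removed_missingness}, monomorphic "
            f"{report.n_removed_monomorphic}, HWE {report.n_removed_hwe})")
    return g.subset_variants(retained), report


def _per_variant_tables(g: GenotypeMatrix, y: np.ndarray, covariates,
                        fitter, trait: str, model: str) -> pd.DataFrame:
    y = np.asarray(y, dtype=float)
    if y.shape[0] != g.n_samples:
        raise ValidationError("phenotype length != number of samples")
    base, names = design_matrix(covariates, g.n_samples)
    rows = []
    for j, snp in enumerate(g.snp_ids):
        dose = g.dosage[:, j]
        keep = ~np.isnan(dose) & np.all(np.isfinite(base), axis=1) & np.isfinite(y)
        X = np.column_stack([base[keep], dose[keep]])
        fit = fitter(X, y[keep], names + ["dosage"])
        rows.append({
            "snp_id": snp,
            "effect_allele": g.variants.loc[j, "effect_allele"],
            "other_allele": g.variants.loc[j, "other_allele"],
            "beta": fit.beta[-1], "se": fit.se[-1],
            "p": max(fit.p[-1], np.finfo(float).tiny),
            "n": fit.n, "trait": trait,
            "eaf": float(np.nanmean(dose) / 2.0),
            "model": model,
        })
    return pd.DataFrame(rows)


def linear_assoc(g: GenotypeMatrix, y, covariates=None,
                 trait: str = "exposure") -> pd.DataFrame:
    """Per-variant OLS of a quantitative trait on dosage (+ covariates).

    Two-sided p-values come from the t reference distribution; samples
    with a missing dosage are dropped per variant.
    """
    return _per_variant_tables(g, y, covariates, fit_ols, trait, "linear")


def logistic_assoc(g: GenotypeMatrix, case, covariates=None,
                   trait: str = "outcome") -> pd.DataFrame:
    """Per-variant logistic regression of case status on dosage.

    Returns the per-allele log-odds ratio with Wald SE and normal
    two-sided p; raises on separation or non-convergence.
    """
    case = np.asarray(case, dtype=float)
    if set(np.unique(case[np.isfinite(case)])) - {0.0, 1.0}:
        raise ValidationError("case vector must be binary 0/1")
    return _per_variant_tables(g, case, covariates, fit_logistic,
                               trait, "logistic")


#: nested covariate sets of the observational analysis
OBSERVATIONAL_SETS = {
    "univariate": [],
    "multivariate_1": ["age", "sex", "area"],
    "multivariate_2": ["age", "sex", "area", "smoking", "drinking"],
    "multivariate_3": ["age", "sex", "area", "smoking", "drinking",
                       "rfs", "bmi"],
}


def observational_or(pheno: pd.DataFrame,
                     covariate_sets: dict[str, list[str]] | None = None,
                     scale: str = "unit") -> pd.DataFrame:
    """Observational logistic ORs of MetS on log-Hcy, nested covariates.

    ``scale`` selects the exposure unit: ``"unit"`` (per 1 log µmol/L)
    or ``"sd"`` (per within-sample SD of log-Hcy).  Both conventions are
    exposed because reported ORs are not comparable across them.
    """
    if scale not in ("unit", "sd"):
        raise ValidationError("scale must be 'unit' or 'sd'")
    for col in ("log_hcy", "mets"):
        if col not in pheno.columns:
            raise ValidationError(f"phenotype table lacks column {col!r}")
    sets = covariate_sets if covariate_sets is not None else OBSERVATIONAL_SETS
    x = pheno["log_hcy"].to_numpy(dtype=float)
    if scale == "sd":
        x = x / x.std(ddof=1)
    y = pheno["mets"].to_numpy(dtype=float)
    rows = []
    for label, cols in sets.items():
        covs = pheno[cols] if cols else None
        base, names = design_matrix(covs, len(pheno))
        X = np.column_stack([base, x])
        fit = fit_logistic(X, y, names + ["log_hcy"])
        b, se = fit.beta[-1], fit.se[-1]
        rows.append({
            "model": label, "covariates": ",".join(cols),
            "log_or": b, "se": se,
            "or": np.exp(b),
            "ci_low": np.exp(b - Z95 * se),
            "ci_high": np.exp(b + Z95 * se),
            "p": fit.p[-1], "n": fit.n, "scale": scale,
        })
    return pd.DataFrame(rows)


def quartile_summary(pheno: pd.DataFrame, variables=None,
                     by: str = "log_hcy",
                     normality_alpha: float = 0.01) -> pd.DataFrame:
    """Descriptive table by quartile of the exposure.

    Samples are cut at the 25/50/75 empirical percentiles of ``by``
    (right-closed intervals: a value equal to a cutpoint falls in the
    lower quartile).  Binary variables are summarized as % with a
    chi-square group test; continuous variables as mean (SD) with ANOVA
    when a normality test does not reject, otherwise median (IQR) with
    Kruskal-Wallis.
    """
    if len(pheno) < 4:
        raise ValidationError("need at least 4 samples for quartiles")
    x = pheno[by].to_numpy(dtype=float)
    try:
        quart = pd.qcut(x, 4, labels=["Q1", "Q2", "Q3", "Q4"])
    except ValueError as exc:
        raise ValidationError(
            "ties make a quartile empty; use fewer bins") from exc
    if variables is None:
        variables = [c for c in pheno.columns
                     if c not in ("sample_id", by)
                     and pd.api.types.is_numeric_dtype(pheno[c])]
    labels = ["Q1", "Q2", "Q3", "Q4"]
    rows = []
    for var in variables:
        v = pheno[var].to_numpy(dtype=float)
        groups = [v[np.asarray(quart == q)] for q in labels]
        uniq = np.unique(v[np.isfinite(v)])
        cells, test, pval = {}, None, np.nan
        if uniq.size <= 2:  # binary -> percentages + chi-square
            tab = np.array([[(gv == u).sum() for u in uniq] for gv in groups])
            for q, gv in zip(labels, groups):
                cells[q] = f"{100.0 * np.mean(gv == uniq.max()):.1f}%"
            test = "chi2"
            if tab.shape[1] == 2 and (tab.sum(axis=0) > 0).all():
                pval = float(stats.chi2_contingency(tab)[1])
            else:
                pval = 1.0
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                normal_p = stats.normaltest(v).pvalue if len(v) >= 20 else 1.0
            if normal_p >= normality_alpha:
                for q, gv in zip(labels, groups):
                    cells[q] = f"{gv.mean():.2f} ({gv.std(ddof=1):.2f})"
                test = "anova"
                if all(len(np.unique(gv)) > 1 for gv in groups):
                    pval = float(stats.f_oneway(*groups).pvalue)
                else:
                    f = stats.f_oneway(*groups)
                    pval = 1.0 if np.isnan(f.pvalue) else float(f.pvalue)
            else:
                for q, gv in zip(labels, groups):
                    q1, q3 = np.percentile(gv, [25, 75])
                    cells[q] = f"{np.median(gv):.2f} ({q1:.2f},{q3:.2f})"
                test = "kruskal"
                pval = float(stats.kruskal(*groups).pvalue)
        rows.append({"variable": var, **cells, "test": test, "p": pval})
    return pd.DataFrame(rows)
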