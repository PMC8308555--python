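"""Instrument construction for Mendelian randomization.

Selection of genome-wide-significant exposure SNPs, greedy LD-clumping
against a reference genotype matrix, first-stage F-statistics,
confounder screening of candidate instruments, and harmonization of
exposure/outcome summary statistics onto a common effect allele.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from ._glm import design_matrix, fit_logistic, fit_ols
from .containers import (ClumpResult, GenotypeMatrix, HarmonizedInstrument,
                         ValidationError, validate_summary_stats)

__all__ = ["select_instruments", "ld_r2", "ld_clump", "f_statistic",
           "confounder_screen", "harmonize", "orient_instruments"]

#: genome-wide threshold used for instrument selection (Bonferroni for
#: an array of ~420k variants, hence stricter than the usual 5e-8)
DEFAULT_P_THRESHOLD = 4e-8

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _order_by_p(stats: pd.DataFrame) -> pd.DataFrame:
    # ascending p, ties broken lexicographically by id: deterministic runs
    return stats.sort_values(["p", "snp_id"], kind="mergesort")


def select_instruments(stats: pd.DataFrame,
                       p_threshold: float = DEFAULT_P_THRESHOLD) -> list[str]:
    """SNPs with exposure p strictly below the threshold, best first.

    A p-value exactly equal to the threshold is *not* selected.  Returns
    an empty list (with a warning) when nothing passes.
    """
    stats = validate_summary_stats(stats)
    if "trait" in stats.columns and (stats["trait"] == "exposure").any():
        stats = stats[stats["trait"] == "exposure"]
    hits = _order_by_p(stats[stats["p"] < p_threshold])
    if hits.empty:
        warnings.warn(f"no SNP passes p < {p_threshold:g}", UserWarning,
                      stacklevel=2)
    return hits["snp_id"].tolist()


def ld_r2(dosage_a, dosage_b) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Computed over pairwise-complete samples; a zero-variance
    (monomorphic) vector yields r^2 = 0.
    """
    a = np.asarray(dosage_a, dtype=float)
    b = np.asarray(dosage_b, dtype=float)
    keep = ~np.isnan(a) & ~np.isnan(b)
    if keep.sum() < 2:
        raise ValidationError("need >= 2 samples with both dosages observed")
    a, b = a[keep], b[keep]
    va, vb = a.var(), b.var()
    if va == 0.0 or vb == 0.0:
        return 0.0
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def ld_clump(stats: pd.DataFrame, ref: GenotypeMatrix,
             r2_threshold: float = 0.01) -> ClumpResult:
    """Greedy LD-clumping: keep the best SNP of each correlated set.

    SNPs are visited by ascending p (ties by id); a SNP is retained iff
    its r^2 with every already-retained SNP is strictly below the
    threshold, otherwise it is attributed to the first retained SNP it
    clumps with.  Every stats SNP must be present in the reference
    genotypes.
    """
    stats = validate_summary_stats(stats)
    absent = sorted(set(stats["snp_id"]) - set(ref.snp_ids))
    if absent:
        raise KeyError(f"SNPs absent from reference genotypes: {absent}")
    retained: list[str] = []
    removed: dict[str, tuple[str, float]] = {}
    for snp in _order_by_p(stats)["snp_id"]:
        dose = ref.column(snp)
        hit = None
        for idx_snp in retained:
            r2 = ld_r2(dose, ref.column(idx_snp))
            if r2 >= r2_threshold:
                hit = (idx_snp, r2)
                break
        if hit is None:
            retained.append(snp)
        else:
            removed[snp] = hit
    return ClumpResult(retained=retained, removed=removed,
                       threshold=r2_threshold)


def f_statistic(exposure, iv_matrix, covariates=None) -> tuple[float, float]:
    """First-stage instrument-strength F and incremental R^2.

    F = (R2_incr / (1 - R2_full)) * (n - k - c - 1) / k, where R2_incr
    is the variance the k instruments explain beyond the c covariates.
    A perfect fit returns ``inf``.
    """
    y = np.asarray(exposure, dtype=float)
    Z = np.asarray(iv_matrix, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    n, k = Z.shape
    base, names = design_matrix(covariates, n)
    c = base.shape[1] - 1
    if n <= k + c + 1:
        raise ValidationError(f"need n > k + c + 1 = {k + c + 1}, got {n}")
    full = np.column_stack([base, Z])
    fit_full = fit_ols(full, y, names + [f"iv{j}" for j in range(k)])
    r2_full = fit_full.r2
    if c > 0:
        r2_base = fit_ols(base, y, names).r2
    else:
        r2_base = 0.0
    r2_incr = r2_full - r2_base
    denom = 1.0 - r2_full
    if denom <= np.finfo(float).eps:
        return float("inf"), float(r2_incr)
    f = (r2_incr / denom) * (n - k - c - 1) / k
    return float(max(f, 0.0)), float(r2_incr)


def confounder_screen(g: GenotypeMatrix, confounders: pd.DataFrame,
                      covariates: pd.DataFrame | None = None) -> pd.DataFrame:
    """Regress each confounder on each SNP's dosage (additive coding).

    Continuous confounders (RFS, BMI, ...) use linear regression; binary
    ones (smoking, drinking) logistic.  Adjusted for the supplied
    covariates (age, sex, area in the standard analysis).  Returns a
    tidy per-(SNP, confounder) table shaped like a beta (SE), p grid.
    """
    rows = []
    base, names = design_matrix(covariates, g.n_samples)
    for conf in confounders.columns:
        y = confounders[conf].to_numpy(dtype=float)
        uniq = np.unique(y[np.isfinite(y)])
        binary = uniq.size <= 2 and set(uniq) <= {0.0, 1.0}
        for j, snp in enumerate(g.snp_ids):
            dose = g.dosage[:, j]
            keep = ~np.isnan(dose) & np.isfinite(y)
            X = np.column_stack([base[keep], dose[keep]])
            fit = (fit_logistic if binary else fit_ols)(
                X, y[keep], names + ["dosage"])
            rows.append({"snp_id": snp, "confounder": conf,
                         "model": "logistic" if binary else "linear",
                         "beta": fit.beta[-1], "se": fit.se[-1],
                         "p": fit.p[-1], "n": fit.n})
    return pd.DataFrame(rows)


def _is_palindromic(a1: str, a2: str) -> bool:
    return {a1.upper(), a2.upper()} in ({"A", "T"}, {"C", "G"})


def orient_instruments(instruments: list[HarmonizedInstrument],
                       ) -> list[HarmonizedInstrument]:
    """Flip (beta_x, beta_y) jointly so every beta_x >= 0 (idempotent)."""
    out = []
    for ins in instruments:
        if ins.beta_x < 0:
            out.append(HarmonizedInstrument(
                snp_id=ins.snp_id, beta_x=-ins.beta_x, se_x=ins.se_x,
                beta_y=-ins.beta_y, se_y=ins.se_y,
                orientation_flipped=not ins.orientation_flipped,
                palindromic=ins.palindromic))
        else:
            out.append(ins)
    return out


def harmonize(exposure: pd.DataFrame, outcome: pd.DataFrame,
              drop_palindromic_maf: float = 0.42,
              orient: bool = True,
              ) -> tuple[list[HarmonizedInstrument], pd.DataFrame]:
    """Align outcome effects to the exposure's effect allele per SNP.

    For each shared SNP: if the outcome's effect allele matches the
    exposure's, the effect is copied; if it matches the exposure's other
    allele (directly or as the reverse-strand complement), the outcome
    beta is negated; anything else is irreconcilable and dropped.
    Palindromic (A/T, G/C) SNPs are flagged and dropped when the
    exposure effect-allele frequency is available and the minor-allele
    frequency exceeds ``drop_palindromic_maf`` (strand unresolvable by
    frequency); without frequency information they are kept flagged.
    Finally instruments are oriented so beta_x >= 0 (joint sign flip),
    the convention MR-Egger requires.

    Returns the instruments plus a per-SNP action report.
    """
    exposure = validate_summary_stats(exposure).set_index("snp_id")
    outcome = validate_summary_stats(outcome).set_index("snp_id")
    shared = [s for s in exposure.index if s in outcome.index]
    if not shared:
        raise ValidationError("no shared SNPs between exposure and outcome")
    instruments, report = [], []
    for snp in shared:
        ex, oc = exposure.loc[snp], outcome.loc[snp]
        ea_x, oa_x = ex["effect_allele"].upper(), ex["other_allele"].upper()
        ea_y, oa_y = oc["effect_allele"].upper(), oc["other_allele"].upper()
        palindromic = _is_palindromic(ea_x, oa_x)
        beta_y = None
        if (ea_y, oa_y) == (ea_x, oa_x):
            beta_y = oc["beta"]
        elif (ea_y, oa_y) == (oa_x, ea_x):
            beta_y = -oc["beta"]
        elif not palindromic:
            # reverse-strand report of the same SNP
            cea, coa = COMPLEMENT.get(ea_y, "?"), COMPLEMENT.get(oa_y, "?")
            if (cea, coa) == (ea_x, oa_x):
                beta_y = oc["beta"]
            elif (cea, coa) == (oa_x, ea_x):
                beta_y = -oc["beta"]
        if beta_y is None:
            report.append({"snp_id": snp, "action": "dropped",
                           "reason": f"irreconcilable alleles "
                                     f"{ea_x}/{oa_x} vs {ea_y}/{oa_y}"})
            continue
        if palindromic:
            eaf = ex.get("eaf", np.nan)
            maf = min(eaf, 1 - eaf) if np.isfinite(eaf) else np.nan
            if np.isfinite(maf) and maf > drop_palindromic_maf:
                report.append({"snp_id": snp, "action": "dropped",
                               "reason": f"palindromic with MAF {maf:.2f} > "
                                         f"{drop_palindromic_maf}"})
                continue
        instruments.append(HarmonizedInstrument(
            snp_id=snp, beta_x=float(ex["beta"]), se_x=float(ex["se"]),
            beta_y=float(beta_y), se_y=float(oc["se"]),
            palindromic=palindromic))
        report.append({"snp_id": snp, "action": "kept",
                       "reason": "palindromic (kept)" if palindromic else ""})
    if orient:
        instruments = orient_instruments(instruments)
    return instruments, pd.DataFrame(report)
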