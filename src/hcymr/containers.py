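"""Core data containers shared across the pipeline.

Genotypes are held as a dense dosage matrix (samples x variants) with
``numpy.nan`` marking missing calls; dosage counts copies of the effect
allele (0, 1, 2).  Per-SNP association results travel between stages as
pandas DataFrames with a fixed column schema (``SUMMARY_COLUMNS``), the
exchange format every estimator consumes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

#: two-sided 97.5% normal quantile used for every Wald CI
Z95 = 1.959964

#: mandatory column order for summary-statistics tables
SUMMARY_COLUMNS = ["snp_id", "effect_allele", "other_allele",
                   "beta", "se", "p", "n", "trait"]


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


class SeparationError(RuntimeError):
    """Raised when a logistic fit diverges (complete/quasi separation)."""


class ConvergenceError(RuntimeError):
    """Raised when an iterative fit fails to converge."""


class EmptyResultError(RuntimeError):
    """Raised when a filter or selection removes every record."""


@dataclass
class GenotypeMatrix:
    """Sample x variant dosage table with variant metadata.

    Parameters
    ----------
    sample_ids
        Length-``n`` array of unique sample identifiers.
    variants
        DataFrame with columns ``snp_id, chrom, pos, effect_allele,
        other_allele`` (positions 1-based).
    dosage
        ``n x m`` float array; entries in {0, 1, 2} or ``nan`` for missing.
        Dosage counts copies of the effect allele.
    """

    sample_ids: np.ndarray
    variants: pd.DataFrame
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids)
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.ndim != 2:
            raise ValidationError("dosage must be a 2-D samples x variants array")
        n, m = self.dosage.shape
        if len(self.sample_ids) != n:
            raise ValidationError(
                f"{len(self.sample_ids)} sample ids but {n} dosage rows")
        if len(self.variants) != m:
            raise ValidationError(
                f"{len(self.variants)} variant rows but {m} dosage columns")
        ids = self.variants["snp_id"]
        if ids.duplicated().any():
            dupes = sorted(ids[ids.duplicated()].unique())
            raise ValidationError(f"duplicate variant ids: {dupes}")
        finite = self.dosage[~np.isnan(self.dosage)]
        if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
            raise ValidationError("dosage values must be 0, 1, 2 or missing")
        self.variants = self.variants.reset_index(drop=True)

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosage.shape[1]

    @property
    def snp_ids(self) -> list[str]:
        return list(self.variants["snp_id"])

    def column(self, snp_id: str) -> np.ndarray:
        """Dosage vector for one variant (missing as nan)."""
        idx = self._index_of(snp_id)
        return self.dosage[:, idx]

    def _index_of(self, snp_id: str) -> int:
        match = np.flatnonzero((self.variants["snp_id"] == snp_id).to_numpy())
        if match.size == 0:
            raise KeyError(f"variant {snp_id!r} not present")
        return int(match[0])

    # -- derived quantities ---------------------------------------------
    def missing_rate(self) -> np.ndarray:
        """Per-variant fraction of missing calls."""
        return np.isnan(self.dosage).mean(axis=0)

    def genotype_counts(self, snp_id: str) -> tuple[int, int, int]:
        """(n_other_homo, n_het, n_effect_homo) among non-missing calls."""
        g = self.column(snp_id)
        g = g[~np.isnan(g)]
        return (int((g == 0).sum()), int((g == 1).sum()), int((g == 2).sum()))

    def effect_allele_freq(self) -> np.ndarray:
        """Per-variant effect-allele frequency from non-missing dosages."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosage, axis=0) / 2.0

    def mean_imputed(self) -> np.ndarray:
        """Dosage with missing entries replaced by the per-variant mean.

        A fully missing variant imputes to 0.
        """
        filled = self.dosage.copy()
        col_mean = np.nanmean(
            np.where(np.isnan(filled), np.nan, filled), axis=0)
        col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
        idx = np.where(np.isnan(filled))
        filled[idx] = col_mean[idx[1]]
        return filled

    def subset_variants(self, snp_ids: Sequence[str]) -> "GenotypeMatrix":
        """New matrix restricted to ``snp_ids`` (order preserved)."""
        cols = [self._index_of(s) for s in snp_ids]
        return GenotypeMatrix(
            sample_ids=self.sample_ids,
            variants=self.variants.iloc[cols].reset_index(drop=True),
            dosage=self.dosage[:, cols],
        )

    # -- I/O --------------------------------------------------------------
    def to_tsv(self, dosage_path, variants_path) -> None:
        """Write dosage (samples x variants, NA = missing) and metadata."""
        df = pd.DataFrame(self.dosage, columns=self.snp_ids)
        df.insert(0, "sample_id", self.sample_ids)
        df.to_csv(dosage_path, sep="\t", index=False, na_rep="NA",
                  float_format="%.0f")
        self.variants.to_csv(variants_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, dosage_path, variants_path) -> "GenotypeMatrix":
        df = pd.read_csv(dosage_path, sep="\t", na_values=["NA"])
        variants = pd.read_csv(variants_path, sep="\t")
        return cls(sample_ids=df["sample_id"].to_numpy(),
                   variants=variants,
                   dosage=df.drop(columns="sample_id").to_numpy(dtype=float))


@dataclass
class QCReport:
    """Bookkeeping for :func:`hcymr.assoc.qc_filter`."""

    n_input: int
    n_removed_missingness: int
    n_removed_monomorphic: int
    n_removed_hwe: int
    retained: list[str]
    removed: dict[str, list[str]] = field(default_factory=dict)

    @property
    def n_retained(self) -> int:
        return len(self.retained)


@dataclass
class ClumpResult:
    """Outcome of greedy LD-clumping."""

    retained: list[str]
    #: removed snp -> (index snp it clumped to, r^2 with that index snp)
    removed: dict[str, tuple[str, float]]
    threshold: float


@dataclass
class HarmonizedInstrument:
    """Per-SNP exposure/outcome effect pair aligned to a common allele.

    After orientation the exposure effect is non-negative, the convention
    MR-Egger requires; ``orientation_flipped`` records whether both betas
    were negated to achieve it.
    """

    snp_id: str
    beta_x: float
    se_x: float
    beta_y: float
    se_y: float
    orientation_flipped: bool = False
    palindromic: bool = False

    def __post_init__(self) -> None:
        if not (self.se_x > 0 and self.se_y > 0):
            raise ValidationError(
                f"{self.snp_id}: standard errors must be positive")


def instruments_to_frame(instruments: Sequence[HarmonizedInstrument]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(i) for i in instruments])


@dataclass
class MRResult:
    """Causal-effect estimate on the log-odds-of-MetS per SD-log-Hcy scale."""

    method: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    k_instruments: int
    diagnostics: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    @classmethod
    def from_wald(cls, method: str, estimate: float, se: float,
                  k_instruments: int, df: int | None = None,
                  diagnostics: dict | None = None,
                  warnings: list[str] | None = None) -> "MRResult":
        """Build a result with symmetric normal (or t) CI and p-value."""
        from scipy import stats

        if df is None:
            p = 2.0 * stats.norm.sf(abs(estimate / se)) if se > 0 else 0.0
        else:
            p = 2.0 * stats.t.sf(abs(estimate / se), df) if se > 0 else 0.0
        return cls(method=method, estimate=estimate, se=se,
                   ci_low=estimate - Z95 * se, ci_high=estimate + Z95 * se,
                   p=float(p), k_instruments=k_instruments,
                   diagnostics=diagnostics or {}, warnings=warnings or [])

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class GRS:
    """Per-sample genetic risk score (weighted exposure-increasing alleles)."""

    score: np.ndarray
    weights: dict[str, float]
    model: str  # "additive" | "dominant"


def validate_summary_stats(stats: pd.DataFrame) -> pd.DataFrame:
    """Check the mandatory summary-statistics schema; return a copy."""
    missing = [c for c in SUMMARY_COLUMNS if c not in stats.columns]
    if missing:
        raise ValidationError(f"summary table missing columns: {missing}")
    out = stats.copy()
    if (out["se"] <= 0).any():
        bad = out.loc[out["se"] <= 0, "snp_id"].tolist()
        raise ValidationError(f"non-positive SE for {bad}")
    if ((out["p"] <= 0) | (out["p"] > 1)).any():
        bad = out.loc[(out["p"] <= 0) | (out["p"] > 1), "snp_id"].tolist()
        raise ValidationError(f"p-values outside (0, 1] for {bad}")
    return out


def read_summary_stats(path) -> pd.DataFrame:
    return validate_summary_stats(pd.read_csv(path, sep="\t", comment="#"))


def write_summary_stats(stats: pd.DataFrame, path) -> None:
    validate_summary_stats(stats).to_csv(path, sep="\t", index=False)
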