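import numpy as np
import pandas as pd
import pytest

from hcymr.containers import GenotypeMatrix, HarmonizedInstrument


def make_instruments(k: int, seed: int, theta: float = 0.7,
                     alpha_sd: float = 0.0) -> list[HarmonizedInstrument]:
    """Random harmonized instruments with true slope ``theta``."""
    rng = np.random.default_rng(seed)
    bx = rng.uniform(0.05, 0.4, k)
    sx = rng.uniform(0.005, 0.05, k)
    sy = rng.uniform(0.01, 0.1, k)
    alpha = rng.normal(0.0, alpha_sd, k) if alpha_sd else np.zeros(k)
    by = theta * bx + alpha + rng.normal(0.0, sy)
    return [HarmonizedInstrument(f"snp{i + 1}", bx[i], sx[i], by[i], sy[i])
            for i in range(k)]


def make_genotypes(dosage, snp_ids=None) -> GenotypeMatrix:
    """GenotypeMatrix from a plain dosage array (A/G allele metadata)."""
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    ids = snp_ids or [f"snp{j + 1}" for j in range(m)]
    variants = pd.DataFrame({
        "snp_id": ids, "chrom": ["1"] * m, "pos": range(1, m + 1),
        "effect_allele": ["A"] * m, "other_allele": ["G"] * m,
    })
    return GenotypeMatrix(
        sample_ids=np.array([f"s{i + 1}" for i in range(n)]),
        variants=variants, dosage=dosage)


@pytest.fixture
def five_snp_fixture():
    from hcymr.fixtures import load_five_snp_fixture

    return load_five_snp_fixture()


@pytest.fixture
def small_cohort():
    """A modest simulated cohort with real genetic effects."""
    from hcymr.synthdata import SimConfig, simulate_cohort

    cfg = SimConfig(
        n_samples=2000,
        variants=[("v1", "A", "G", 0.3), ("v2", "C", "T", 0.4),
                  ("v3", "G", "A", 0.25)],
        beta_exposure=[0.06, 0.05, -0.04],
        theta=0.7, confounder_effects=(0.1, 0.3), seed=11)
    return simulate_cohort(cfg)
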