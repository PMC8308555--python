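"""Packaged five-SNP instrument fixture.

The exposure table carries the per-allele effects of the five
homocysteine-associated instruments (rs12567136, rs1801133, rs2336377,
rs1624230, rs1836883) on natural-log homocysteine in the KARE cohort;
the outcome table carries their log-odds-of-MetS per allele in the
merged HEXA+CAVAS cohorts, with SEs reconstructed from the published
95% CIs.  The non-effect alleles are unpublished and are synthetic
non-palindromic placeholders (see the file headers).
"""

from __future__ import annotations

import shutil
from importlib import resources
from pathlib import Path

import pandas as pd

from .containers import read_summary_stats

__all__ = ["load_five_snp_fixture", "materialize_fixtures"]

_FILES = ("five_snp_exposure.tsv", "five_snp_outcome.tsv")


def _data_path(name: str):
    return resources.files("hcymr.data").joinpath(name)


def load_five_snp_fixture() -> tuple[pd.DataFrame, pd.DataFrame]:
    """(exposure, outcome) summary-statistics tables for the 5 SNPs."""
    with resources.as_file(_data_path(_FILES[0])) as p:
        exposure = read_summary_stats(p)
    with resources.as_file(_data_path(_FILES[1])) as p:
        outcome = read_summary_stats(p)
    return exposure, outcome


def materialize_fixtures(out_dir) -> list[Path]:
    """Copy the fixture TSVs into ``out_dir``; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name in _FILES:
        with resources.as_file(_data_path(name)) as src:
            dst = out / name
            shutil.copy(src, dst)
            written.append(dst)
    return written
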