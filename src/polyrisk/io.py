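"""Readers and writers for the package's plain-text interchange formats.

Panels are TSV (rsid, chrom, beta, freq, source); cohorts are CSV with one
row per subject and missing genotype dosages encoded as empty fields; LD
tables are TSV (rsid_a, rsid_b, r2); baseline incidence tables are CSV
(age_lo, age_hi, rate_per_100k).  Output CSVs carry ``# key=value`` header
comments (seed, config hash) and are read back with ``comment='#'``.
"""
from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import RiskFactorSpec
from .genetic import GrsPanel, SnpSpec
from .projection import validate_incidence_table

__all__ = [
    "read_panel",
    "write_panel",
    "read_ld",
    "read_baseline",
    "read_cohort",
    "write_csv",
    "read_csv",
]

_PANEL_COLUMNS = ["rsid", "chrom", "beta", "freq", "source"]


def read_panel(path) -> GrsPanel:
    """Read and validate a SNP panel TSV; errors cite the offending line."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if df.empty and df.columns.size <= 1:
        warnings.warn(f"{path}: empty panel file", stacklevel=2)
        return GrsPanel([])
    missing = set(_PANEL_COLUMNS[:4]) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    if "source" not in df.columns:
        df["source"] = ""
    if df.empty:
        warnings.warn(f"{path}: empty panel file", stacklevel=2)
        return GrsPanel([])
    snps = []
    seen = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1-based + header
        try:
            beta, freq = float(row.beta), float(row.freq)
        except (TypeError, ValueError) as err:
            raise ValueError(f"{path}, line {i}: non-numeric beta/freq") from err
        if not (0.0 < freq < 1.0):
            raise ValueError(f"{path}, line {i}: freq must lie in (0, 1), got {freq}")
        if row.rsid in seen:
            raise ValueError(f"{path}, line {i}: duplicate rsid {row.rsid} (first at line {seen[row.rsid]})")
        seen[row.rsid] = i
        snps.append(SnpSpec(str(row.rsid), str(row.chrom), beta, freq, str(row.source or "")))
    return GrsPanel(snps)


def write_panel(panel: GrsPanel, path) -> None:
    panel.to_dataframe().to_csv(path, sep="\t", index=False)


def read_ld(path) -> pd.DataFrame:
    """Pairwise LD table (rsid_a, rsid_b, r2)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = {"rsid_a", "rsid_b", "r2"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing LD columns {sorted(missing)}")
    bad = df.index[(df["r2"] < 0) | (df["r2"] > 1)]
    if len(bad):
        raise ValueError(f"{path}, line {bad[0] + 2}: r2 outside [0, 1]")
    return df


def read_baseline(path) -> pd.DataFrame:
    """Age-specific baseline incidence table."""
    return validate_incidence_table(pd.read_csv(path, comment="#"))


def read_cohort(path, factor_specs: list[RiskFactorSpec] | None = None) -> pd.DataFrame:
    """Read a cohort CSV; empty dosage fields become missing (never 0).

    Passing the generating factor specs restores the declared category order
    (reference first) on the factor columns.
    """
    df = pd.read_csv(path, comment="#")
    for c in df.columns:
        if c.startswith("g_"):
            vals = df[c]
            if vals.notna().any() and not set(vals.dropna().unique()) <= {0, 1, 2}:
                raise ValueError(f"{path}: column {c} contains dosages outside {{0,1,2}}")
            df[c] = vals.astype("Int8")
    if factor_specs:
        for spec in factor_specs:
            if spec.name in df.columns and not all(
                isinstance(cat, (int, np.integer)) for cat in spec.categories
            ):
                df[spec.name] = pd.Categorical(
                    df[spec.name], categories=list(spec.categories), ordered=True
                )
    if "id" in df.columns:
        df = df.set_index("id", drop=False)
        df.index.name = None
    return df


def write_csv(df: pd.DataFrame, path, meta: dict | None = None, index: bool = False) -> None:
    """Write a CSV with ``# key=value`` provenance header lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, index=index)


def read_csv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", **kwargs)
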