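"""Bundled synthetic reference inputs.

The shipped panels, LD table and incidence table are *synthetic* stand-ins
with the structural properties the pipeline needs: a 24-SNP panel containing
the rs999737/rs10483813 surrogate pair, a 68-SNP panel containing the
retained moderately correlated pair rs6678914/rs4245739, and a 5-year
age-group incidence table spanning ages 20-85.  Panel weights are calibrated
so the two genetic scores carry the discrimination documented in
``docs/methods.md``; none of the values are measured data.
"""
from __future__ import annotations

from importlib import resources

import pandas as pd

from .genetic import GrsPanel
from .io import read_baseline, read_ld, read_panel

__all__ = ["load_default_panels", "load_default_incidence", "SURROGATE_PAIRS"]

#: (keep, drop) — the surrogate is dropped so its locus is not double-weighted
SURROGATE_PAIRS = [("rs999737", "rs10483813")]


def _data_path(name: str):
    return resources.files("polyrisk").joinpath("data", name)


def load_default_panels() -> tuple[GrsPanel, GrsPanel, pd.DataFrame]:
    """Return (24-SNP panel, 68-SNP panel, LD table)."""
    with resources.as_file(_data_path("synthetic_panel24.tsv")) as p:
        panel24 = read_panel(p)
    with resources.as_file(_data_path("synthetic_panel68.tsv")) as p:
        panel68 = read_panel(p)
    with resources.as_file(_data_path("synthetic_ld.tsv")) as p:
        ld = read_ld(p)
    return panel24, panel68, ld


def load_default_incidence() -> pd.DataFrame:
    """Synthetic age-specific baseline incidence (per 100,000 woman-years)."""
    with resources.as_file(_data_path("synthetic_incidence_rates.csv")) as p:
        return read_baseline(p)
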