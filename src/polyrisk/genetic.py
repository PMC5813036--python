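"""Genetic risk scores: observed weighted-allele sums and conditional simulation.

A genetic risk score (GRS) is the weighted sum of a subject's risk-allele
dosages, the weights being published per-allele log odds ratios.  Where a
subject was never genotyped, the score can instead be drawn from its
conditional normal distribution given case-control status ``d`` and
first-degree family history ``h``::

    GRS | d, h  ~  N(d*sigma2 + h*sigma2/2,  sigma2)

with ``sigma2 = sum_k 2 * beta_k**2 * f_k * (1 - f_k)`` — the population
variance of the score under Hardy-Weinberg equilibrium and linkage
equilibrium between the panel SNPs.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SnpSpec",
    "GrsPanel",
    "ScoreVector",
    "score_variance",
    "compute_grs_observed",
    "simulate_grs_conditional",
    "ld_exclude",
    "combine_scores",
]


@dataclass(frozen=True)
class SnpSpec:
    """One panel SNP: identifier, locus, per-allele log-OR weight, risk-allele frequency."""

    rsid: str
    chrom: str
    beta: float
    freq: float
    source: str = ""

    def __post_init__(self):
        if not np.isfinite(self.beta):
            raise ValueError(f"{self.rsid}: beta must be finite, got {self.beta}")
        if not (0.0 < self.freq < 1.0):
            raise ValueError(f"{self.rsid}: freq must lie in (0, 1), got {self.freq}")


@dataclass
class GrsPanel:
    """An ordered SNP panel with its derived score variance.

    ``sigma2`` is recomputed from the SNP list on construction; supplying it is
    only useful as a consistency check.
    """

    snps: list[SnpSpec] = field(default_factory=list)

    def __post_init__(self):
        rsids = [s.rsid for s in self.snps]
        dupes = {r for r in rsids if rsids.count(r) > 1}
        if dupes:
            raise ValueError(f"duplicate rsids in panel: {sorted(dupes)}")

    @property
    def rsids(self) -> list[str]:
        return [s.rsid for s in self.snps]

    @property
    def betas(self) -> np.ndarray:
        return np.array([s.beta for s in self.snps], dtype=float)

    @property
    def freqs(self) -> np.ndarray:
        return np.array([s.freq for s in self.snps], dtype=float)

    @property
    def sigma2(self) -> float:
        """Score variance ``sum_k 2 beta_k^2 f_k (1 - f_k)`` under HWE."""
        if not self.snps:
            return 0.0
        b, f = self.betas, self.freqs
        return float(np.sum(2.0 * b**2 * f * (1.0 - f)))

    @property
    def mean_score(self) -> float:
        """HWE population mean of the weighted dosage sum, ``sum_k 2 beta_k f_k``."""
        if not self.snps:
            return 0.0
        return float(np.sum(2.0 * self.betas * self.freqs))

    def subset(self, rsids) -> "GrsPanel":
        keep = set(rsids)
        return GrsPanel([s for s in self.snps if s.rsid in keep])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rsid": self.rsids,
                "chrom": [s.chrom for s in self.snps],
                "beta": self.betas,
                "freq": self.freqs,
                "source": [s.source for s in self.snps],
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "GrsPanel":
        return cls(
            [
                SnpSpec(str(r.rsid), str(r.chrom), float(r.beta), float(r.freq), str(r.source))
                for r in df.itertuples(index=False)
            ]
        )

    def __len__(self) -> int:
        return len(self.snps)


@dataclass
class ScoreVector:
    """A named per-subject score with per-subject provenance.

    ``values`` is indexed by subject id; ``provenance`` marks each entry as
    ``observed`` (computed from genotypes / factor categories) or ``simulated``
    (drawn from the conditional distribution).  Sums of mixed inputs are
    flagged ``mixed``.
    """

    name: str
    values: pd.Series
    provenance: pd.Series | None = None

    def __post_init__(self):
        self.values = pd.Series(self.values, dtype=float)
        if not np.all(np.isfinite(self.values.to_numpy())):
            raise ValueError(f"score {self.name!r} contains non-finite values")
        if self.provenance is None:
            self.provenance = pd.Series("observed", index=self.values.index)
        else:
            self.provenance = pd.Series(self.provenance).reindex(self.values.index)

    @property
    def index(self) -> pd.Index:
        return self.values.index

    def __len__(self) -> int:
        return len(self.values)


def score_variance(panel: GrsPanel) -> float:
    """Variance of the weighted allele-dosage sum under HWE and linkage equilibrium.

    Additive over disjoint sub-panels.  An empty panel yields 0 with a warning.
    """
    if len(panel) == 0:
        warnings.warn("empty panel: score variance is 0", stacklevel=2)
        return 0.0
    return panel.sigma2


def compute_grs_observed(
    dosages: pd.DataFrame, panel: GrsPanel, name: str = "GRS"
) -> ScoreVector:
    """Weighted sum ``score_i = sum_k beta_k * dosage_ik`` over complete subjects.

    ``dosages`` columns may be named either ``<rsid>`` or ``g_<rsid>``.
    Subjects with any missing dosage are excluded (they are the ones routed to
    conditional simulation).
    """
    cols = {}
    for rsid in panel.rsids:
        if rsid in dosages.columns:
            cols[rsid] = dosages[rsid]
        elif f"g_{rsid}" in dosages.columns:
            cols[rsid] = dosages[f"g_{rsid}"]
        else:
            raise KeyError(f"dosage column for {rsid} not found")
    mat = pd.DataFrame(cols).astype(float)
    complete = mat.notna().all(axis=1)
    mat = mat.loc[complete]
    bad = mat.to_numpy()
    if bad.size and not np.isin(bad, (0.0, 1.0, 2.0)).all():
        raise ValueError("dosages must be 0, 1 or 2")
    vals = pd.Series(mat.to_numpy() @ panel.betas, index=mat.index)
    return ScoreVector(name, vals, pd.Series("observed", index=mat.index))


def simulate_grs_conditional(
    d, h, sigma2: float, rng: np.random.Generator, name: str = "GRS", mu0: float = 0.0
) -> ScoreVector:
    """Draw unobserved scores from ``N(mu0 + d*sigma2 + h*sigma2/2, sigma2)``.

    ``d`` (case status) and ``h`` (family history) must be 0/1 vectors on a
    common index.  ``sigma2 = 0`` degenerates to the point mass at the mean.

    ``mu0`` defaults to 0, the convention for a score that is simulated for
    *every* subject (all downstream metrics are shift-invariant).  When the
    simulated draws are to be mixed with observed weighted-dosage scores,
    pass the panel's HWE population mean (:attr:`GrsPanel.mean_score`) so
    both provenances share a scale.
    """
    if sigma2 < 0:
        raise ValueError(f"sigma2 must be >= 0, got {sigma2}")
    d = pd.Series(d).astype(float)
    h = pd.Series(h).astype(float).reindex(d.index)
    for label, v in (("d", d), ("h", h)):
        if not np.isin(v.to_numpy(), (0.0, 1.0)).all():
            raise ValueError(f"{label} must be a 0/1 vector")
    mu = mu0 + d.to_numpy() * sigma2 + 0.5 * h.to_numpy() * sigma2
    draws = rng.normal(loc=mu, scale=np.sqrt(sigma2))
    return ScoreVector(name, pd.Series(draws, index=d.index), pd.Series("simulated", index=d.index))


def ld_exclude(
    panel: GrsPanel,
    ld: pd.DataFrame | None,
    r2_threshold: float = 0.3,
    surrogates: list[tuple[str, str]] = (),
) -> tuple[GrsPanel, pd.DataFrame]:
    """Apply the panel's linkage-disequilibrium policy.

    Designated surrogate pairs ``(keep, drop)`` are resolved by dropping the
    surrogate so its locus is not double-weighted.  Any other same-chromosome
    pair with R^2 above ``r2_threshold`` is *retained* but reported, mirroring
    the convention that moderate correlation is admitted as redundancy rather
    than grounds for exclusion.

    Returns the reduced panel and a report frame of flagged retained pairs
    (columns rsid_a, rsid_b, r2).
    """
    if not (0.0 <= r2_threshold <= 1.0):
        raise ValueError(f"r2_threshold must lie in [0, 1], got {r2_threshold}")
    present = set(panel.rsids)
    drop = set()
    for keep_id, drop_id in surrogates:
        if keep_id not in present or drop_id not in present:
            raise ValueError(f"surrogate pair ({keep_id}, {drop_id}) not present in panel")
        drop.add(drop_id)
    flagged = []
    if ld is not None and len(ld):
        bad = {"rsid_a", "rsid_b", "r2"} - set(ld.columns)
        if bad:
            raise ValueError(f"LD table missing columns: {sorted(bad)}")
        if ((ld["r2"] < 0) | (ld["r2"] > 1)).any():
            raise ValueError("LD R^2 values must lie in [0, 1]")
        surrogate_pairs = {frozenset(p) for p in surrogates}
        for row in ld.itertuples(index=False):
            pair = frozenset((row.rsid_a, row.rsid_b))
            if pair & drop or pair in surrogate_pairs:
                continue
            if pair <= present and row.r2 > r2_threshold:
                flagged.append((row.rsid_a, row.rsid_b, float(row.r2)))
    reduced = GrsPanel([s for s in panel.snps if s.rsid not in drop])
    report = pd.DataFrame(flagged, columns=["rsid_a", "rsid_b", "r2"])
    return reduced, report


_COMBINED_NAMES = {
    frozenset({"GRS24", "GRS68"}): "GRS92",
    frozenset({"NMRFS", "MRFS"}): "RFS",
}


def combine_scores(a: ScoreVector, b: ScoreVector) -> ScoreVector:
    """Elementwise sum of two scores over an identical subject set."""
    if not a.index.equals(b.index):
        if set(a.index) != set(b.index):
            diff = sorted(set(a.index) ^ set(b.index))
            raise ValueError(f"subject mismatch between {a.name} and {b.name}: {diff[:10]}")
        b = ScoreVector(b.name, b.values.reindex(a.index), b.provenance.reindex(a.index))
    name = _COMBINED_NAMES.get(frozenset({a.name, b.name}), f"{a.name}+{b.name}")
    prov = np.where(
        a.provenance.to_numpy() == b.provenance.to_numpy(), a.provenance.to_numpy(), "mixed"
    )
    return ScoreVector(name, a.values + b.values, pd.Series(prov, index=a.index))
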