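"""Synthetic case-control cohort generation.

Emulates the structure of a frequency-matched breast-cancer case-control
study: Hardy-Weinberg genotypes for a SNP panel, independently sampled
categorical risk factors (including a binary first-degree family history), a
logistic disease model over all covariates, exact case/control counts with
controls frequency-matched to cases on 5-year age bins, and subject-level
(whole-chip) genotype missingness.

The default configuration reproduces the study conditions this package is
exercised under: 1,732 cases and 1,910 controls aged 20-85, with genotyping
available for 1,138 cases and 1,239 controls.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from ._rng import child_rngs
from .genetic import GrsPanel

__all__ = [
    "RiskFactorSpec",
    "CohortConfig",
    "default_risk_factors",
    "generate_genotypes",
    "generate_risk_factors",
    "assign_status",
    "mask_genotypes",
    "simulate_cohort",
]

LN2 = math.log(2.0)


@dataclass(frozen=True)
class RiskFactorSpec:
    """A categorical risk factor: ordered categories (first = reference),
    sampling probabilities and true per-category log odds ratios."""

    name: str
    categories: tuple
    category_probs: tuple
    betas: tuple  # one per non-reference category; reference beta is 0
    modifiable: bool = False

    def __post_init__(self):
        p = np.asarray(self.category_probs, dtype=float)
        if len(p) != len(self.categories):
            raise ValueError(f"{self.name}: need one probability per category")
        if (p < 0).any() or (p > 1).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"{self.name}: category_probs must lie in [0,1] and sum to 1")
        if len(self.betas) != len(self.categories) - 1:
            raise ValueError(f"{self.name}: need one beta per non-reference category")

    def beta_map(self) -> dict:
        """Category -> true log-OR (0 for the reference)."""
        return {c: b for c, b in zip(self.categories, (0.0, *self.betas))}

    def with_betas(self, betas) -> "RiskFactorSpec":
        return replace(self, betas=tuple(betas))


def default_risk_factors() -> list[RiskFactorSpec]:
    """Default factor set: reproductive/anthropometric non-modifiable factors
    with moderate effects and lifestyle modifiable factors with small effects,
    plus a binary family history (true OR 2) that is roughly twice as
    prevalent among cases as controls."""
    return [
        RiskFactorSpec("famhist", (0, 1), (0.92, 0.08), (LN2,), modifiable=False),
        RiskFactorSpec(
            "menarche_age", ("<12", "12-13", ">13"), (0.20, 0.50, 0.30), (-0.15, -0.25)
        ),
        RiskFactorSpec(
            "parity", ("nulliparous", "1-2", "3+"), (0.20, 0.55, 0.25), (-0.15, -0.30)
        ),
        RiskFactorSpec(
            "age_first_birth", ("<25", "25-29", "30+"), (0.40, 0.35, 0.25), (0.10, 0.25)
        ),
        RiskFactorSpec("height", ("<160", "160-169", "170+"), (0.35, 0.45, 0.20), (0.08, 0.15)),
        RiskFactorSpec(
            "menopause",
            ("premenopausal", "<45", "45-54", "55+"),
            (0.35, 0.15, 0.40, 0.10),
            (-0.10, 0.10, 0.30),
        ),
        RiskFactorSpec("bmi", ("<25", "25-29.9", "30+"), (0.40, 0.35, 0.25), (0.05, 0.10), True),
        RiskFactorSpec("mht", (0, 1), (0.92, 0.08), (0.15,), modifiable=True),
        RiskFactorSpec("alcohol", ("none", "moderate", "high"), (0.40, 0.40, 0.20), (0.05, 0.10), True),
        RiskFactorSpec("smoking", ("never", "former", "current"), (0.50, 0.25, 0.25), (0.03, 0.06), True),
    ]


@dataclass
class CohortConfig:
    """Study-design parameters for cohort simulation."""

    n_cases: int = 1732
    n_controls: int = 1910
    age_range: tuple = (20, 85)
    matching_bin: float = 5.0
    #: scalar, or (case, control) pair; the default reproduces 1,138/1,732
    #: genotyped cases and 1,239/1,910 genotyped controls.
    genotyped_fraction: object = (1138 / 1732, 1239 / 1910)
    intercept: float = -3.0
    population_factor: int = 20
    seed: int = 0

    def __post_init__(self):
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("n_cases and n_controls must be positive")
        lo, hi = self.age_range
        if not lo < hi:
            raise ValueError("age_range must be increasing")
        if self.matching_bin <= 0:
            raise ValueError("matching_bin must be positive")
        if self.population_factor < 2:
            raise ValueError("population_factor must be at least 2")


def generate_genotypes(panel: GrsPanel, n: int, rng: np.random.Generator) -> pd.DataFrame:
    """HWE risk-allele dosages: column ``g_<rsid>`` ~ i.i.d. Binomial(2, f_k),
    independent across SNPs (linkage equilibrium)."""
    if len(panel) == 0:
        raise ValueError("panel must be non-empty")
    if n <= 0:
        raise ValueError(f"n must be positive, got {n}")
    mat = rng.binomial(2, panel.freqs, size=(n, len(panel))).astype(np.int8)
    return pd.DataFrame(mat, columns=[f"g_{r}" for r in panel.rsids])


def generate_risk_factors(
    specs: list[RiskFactorSpec], n: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Sample each factor independently from its category probabilities.

    Binary numeric factors (categories 0/1) are emitted as integer columns,
    the rest as ordered categoricals with the reference category first.
    """
    if n <= 0:
        raise ValueError(f"n must be positive, got {n}")
    out = pd.DataFrame(index=pd.RangeIndex(n))
    for spec in specs:
        idx = rng.choice(len(spec.categories), size=n, p=np.asarray(spec.category_probs, float))
        if all(isinstance(c, (int, np.integer)) for c in spec.categories):
            out[spec.name] = np.asarray(spec.categories, dtype=np.int64)[idx]
        else:
            out[spec.name] = pd.Categorical.from_codes(
                idx, categories=list(spec.categories), ordered=True
            )
    return out


def _linear_predictor(pop: pd.DataFrame, true_betas: dict) -> np.ndarray:
    lp = np.zeros(len(pop))
    for col, spec in true_betas.items():
        if col not in pop.columns:
            raise KeyError(f"true_betas references missing column {col!r}")
        if isinstance(spec, dict):
            lp += pop[col].map(spec).fillna(0.0).to_numpy(dtype=float)
        else:
            lp += float(spec) * pop[col].to_numpy(dtype=float)
    return lp


def _age_bins(ages: np.ndarray, lo: float, width: float) -> np.ndarray:
    return np.floor((ages - lo) / width).astype(int)


def assign_status(
    pop: pd.DataFrame,
    true_betas: dict,
    config: CohortConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, dict]:
    """Assign disease status by the logistic model and draw the study sample.

    ``P(d=1) = expit(intercept + sum(true_betas * covariates))`` in the source
    population; exactly ``n_cases`` cases are sampled, then controls are drawn
    so their 5-year age-bin distribution matches the cases' (largest-remainder
    apportionment of ``n_controls`` over the case bins).

    Returns the sampled cohort (column ``status``) and an info dict with the
    source-population case fraction and the per-bin matching table.
    """
    need = config.n_cases + config.n_controls
    if len(pop) <= need:
        raise ValueError(f"source population ({len(pop)}) must exceed n_cases+n_controls ({need})")
    lp = config.intercept + _linear_predictor(pop, true_betas)
    p = expit(lp)
    d = rng.random(len(pop)) < p
    case_pool = np.flatnonzero(d)
    ctrl_pool = np.flatnonzero(~d)
    if len(case_pool) < config.n_cases:
        raise ValueError(
            f"only {len(case_pool)} cases arose in the source population; "
            f"{config.n_cases} requested (raise intercept or population_factor)"
        )
    cases = rng.choice(case_pool, size=config.n_cases, replace=False)

    lo = float(config.age_range[0])
    width = float(config.matching_bin)
    ages = pop["age"].to_numpy(dtype=float)
    case_bins = _age_bins(ages[cases], lo, width)
    bins, case_counts = np.unique(case_bins, return_counts=True)
    # largest-remainder apportionment of n_controls over the case bins
    quota = case_counts / config.n_cases * config.n_controls
    target = np.floor(quota).astype(int)
    short = config.n_controls - target.sum()
    order = np.argsort(-(quota - np.floor(quota)), kind="stable")
    target[order[:short]] += 1

    ctrl_bins = _age_bins(ages[ctrl_pool], lo, width)
    chosen_ctrl = []
    matching = []
    for b, n_case_b, n_ctrl_b in zip(bins, case_counts, target):
        avail = ctrl_pool[ctrl_bins == b]
        if len(avail) < n_ctrl_b:
            a0, a1 = lo + b * width, lo + (b + 1) * width
            raise ValueError(
                f"infeasible frequency matching in age bin [{a0:g}, {a1:g}): "
                f"need {n_ctrl_b} controls, only {len(avail)} available"
            )
        chosen_ctrl.append(rng.choice(avail, size=n_ctrl_b, replace=False))
        matching.append((lo + b * width, lo + (b + 1) * width, int(n_case_b), int(n_ctrl_b)))
    controls = np.concatenate(chosen_ctrl) if chosen_ctrl else np.array([], dtype=int)

    idx = np.concatenate([cases, controls])
    cohort = pop.iloc[idx].copy()
    cohort.insert(0, "status", np.repeat([1, 0], [len(cases), len(controls)]).astype(np.int64))
    cohort = cohort.reset_index(drop=True)
    info = {
        "population_case_fraction": float(d.mean()),
        "matching": pd.DataFrame(
            matching, columns=["age_lo", "age_hi", "n_cases", "n_controls"]
        ),
        "n_cases": int(config.n_cases),
        "n_controls": int(config.n_controls),
    }
    return cohort, info


def mask_genotypes(
    cohort: pd.DataFrame, genotyped_fraction, rng: np.random.Generator
) -> pd.DataFrame:
    """Blank out *all* genotype columns for a random subset of each arm
    (chip-level availability): ``round((1 - fraction) * n_arm)`` subjects per
    arm lose their genotypes.  ``genotyped_fraction`` may be a scalar or a
    ``(case, control)`` pair."""
    gcols = [c for c in cohort.columns if c.startswith("g_")]
    if not gcols:
        raise ValueError("cohort has no genotype columns")
    if np.isscalar(genotyped_fraction):
        fracs = (float(genotyped_fraction), float(genotyped_fraction))
    else:
        fracs = tuple(float(f) for f in genotyped_fraction)
    for f in fracs:
        if not (0.0 <= f <= 1.0):
            raise ValueError(f"genotyped_fraction must lie in [0, 1], got {f}")
    out = cohort.copy()
    for c in gcols:
        out[c] = out[c].astype("Int8")
    for arm, frac in zip((1, 0), fracs):
        rows = np.flatnonzero((cohort["status"] == arm).to_numpy())
        n_mask = int(round((1.0 - frac) * len(rows)))
        if n_mask:
            masked = rng.choice(rows, size=n_mask, replace=False)
            out.iloc[masked, [out.columns.get_loc(c) for c in gcols]] = pd.NA
    return out


def simulate_cohort(
    config: CohortConfig,
    chip_panel: GrsPanel | None = None,
    latent_panel: GrsPanel | None = None,
    factor_specs: list[RiskFactorSpec] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """End-to-end cohort simulation under the logistic disease model.

    ``chip_panel`` SNPs are genotyped (emitted as ``g_<rsid>`` columns and
    subject to chip masking); ``latent_panel`` SNPs contribute to disease risk
    but are never genotyped, the situation the conditional score simulation is
    designed for.  Per-allele log-ORs of both panels and the factor-spec betas
    form the true disease model.

    Returns ``(cohort, info)`` where the cohort has columns ``id``, ``status``,
    ``age``, the factor columns and any genotype columns.
    """
    if factor_specs is None:
        factor_specs = default_risk_factors()
    rngs = child_rngs(config.seed)
    n_pop = config.population_factor * (config.n_cases + config.n_controls)

    lo, hi = (float(a) for a in config.age_range)
    pop = pd.DataFrame({"age": rngs["factors"].uniform(lo, hi, n_pop)})
    pop = pd.concat([pop, generate_risk_factors(factor_specs, n_pop, rngs["factors"])], axis=1)

    true_betas: dict = {}
    for spec in factor_specs:
        bm = spec.beta_map()
        if all(isinstance(c, (int, np.integer)) for c in spec.categories):
            true_betas[spec.name] = dict(bm)
        else:
            true_betas[spec.name] = bm
    if chip_panel is not None and len(chip_panel):
        pop = pd.concat([pop, generate_genotypes(chip_panel, n_pop, rngs["genotypes"])], axis=1)
        for s in chip_panel.snps:
            true_betas[f"g_{s.rsid}"] = s.beta
    latent_cols: list[str] = []
    if latent_panel is not None and len(latent_panel):
        lat = generate_genotypes(latent_panel, n_pop, rngs["latent_genotypes"])
        lat.columns = [c.replace("g_", "latent_", 1) for c in lat.columns]
        latent_cols = list(lat.columns)
        pop = pd.concat([pop, lat], axis=1)
        for s in latent_panel.snps:
            true_betas[f"latent_{s.rsid}"] = s.beta

    # config.intercept is the baseline log-odds at the *average* covariate
    # profile: subtract the analytic mean contribution of every covariate so
    # the source-population prevalence is expit(intercept) regardless of the
    # panels and factor sets in force.
    offset = 0.0
    for spec in factor_specs:
        offset += sum(p * b for p, b in zip(spec.category_probs, (0.0, *spec.betas)))
    for panel in (chip_panel, latent_panel):
        if panel is not None and len(panel):
            offset += panel.mean_score
    shifted = replace(config, intercept=config.intercept - offset)
    cohort, info = assign_status(pop, true_betas, shifted, rngs["status"])
    cohort = cohort.drop(columns=latent_cols)
    if chip_panel is not None and len(chip_panel):
        cohort = mask_genotypes(cohort, config.genotyped_fraction, rngs["masking"])
    cohort.insert(0, "id", [f"S{i:06d}" for i in range(len(cohort))])
    cohort = cohort.set_index("id", drop=False)
    cohort.index.name = None
    info["seed"] = config.seed
    return cohort, info
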