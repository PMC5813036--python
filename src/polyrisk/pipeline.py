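"""End-to-end pipeline: simulate -> genetic scores -> factor scores ->
evaluation -> incidence projection, with a provenance manifest."""
from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._rng import child_rngs
from .cohort import CohortConfig, RiskFactorSpec, default_risk_factors, simulate_cohort
from .datasets import SURROGATE_PAIRS, load_default_incidence, load_default_panels
from .evaluation import compare_scores, decile_assign, decile_or, score_summary
from .factors import build_factor_scores, full_model
from .genetic import (
    GrsPanel,
    ScoreVector,
    combine_scores,
    compute_grs_observed,
    ld_exclude,
    simulate_grs_conditional,
)
from .io import read_baseline, read_ld, read_panel, write_csv
from .projection import IncidenceProjector

__all__ = ["PipelineConfig", "run_pipeline", "build_genetic_scores", "config_from_yaml"]


@dataclass
class PipelineConfig:
    """Everything a reproducible pipeline run needs."""

    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    panel24_path: str | None = None  # None -> bundled synthetic panel
    panel68_path: str | None = None
    ld_path: str | None = None
    baseline_path: str | None = None
    factor_specs: list[RiskFactorSpec] | None = None
    surrogates: list[tuple[str, str]] = field(default_factory=lambda: list(SURROGATE_PAIRS))
    r2_threshold: float = 0.3
    auroc_mode: str = "decile-model"
    refit: bool = False
    combined_adjustment: bool = False
    project_scores: tuple = ("GRS92", "NMRFS", "MRFS", "FM")
    out_dir: str | None = None

    def __post_init__(self):
        self.cohort.seed = self.seed

    def digest(self) -> str:
        payload = {
            "seed": self.seed,
            "cohort": asdict(self.cohort),
            "paths": [self.panel24_path, self.panel68_path, self.ld_path, self.baseline_path],
            "factors": None
            if self.factor_specs is None
            else [asdict(s) for s in self.factor_specs],
            "surrogates": [list(p) for p in self.surrogates],
            "r2_threshold": self.r2_threshold,
            "auroc_mode": self.auroc_mode,
            "refit": self.refit,
            "combined_adjustment": self.combined_adjustment,
            "project_scores": list(self.project_scores),
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:16]


def config_from_yaml(path) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML file (see README schema)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cohort = CohortConfig(**{
        k: tuple(v) if isinstance(v, list) else v for k, v in (raw.get("cohort") or {}).items()
    })
    specs = None
    if raw.get("factors"):
        specs = [
            RiskFactorSpec(
                f["name"],
                tuple(f["categories"]),
                tuple(f["probs"]),
                tuple(f["betas"]),
                bool(f.get("modifiable", False)),
            )
            for f in raw["factors"]
        ]
    kwargs = {
        k: raw[k]
        for k in (
            "seed", "panel24_path", "panel68_path", "ld_path", "baseline_path",
            "r2_threshold", "auroc_mode", "refit", "combined_adjustment", "out_dir",
        )
        if k in raw
    }
    if "surrogates" in raw:
        kwargs["surrogates"] = [tuple(p) for p in raw["surrogates"]]
    if "project_scores" in raw:
        kwargs["project_scores"] = tuple(raw["project_scores"])
    return PipelineConfig(cohort=cohort, factor_specs=specs, **kwargs)


def build_genetic_scores(
    cohort: pd.DataFrame,
    panel24: GrsPanel,
    panel68: GrsPanel,
    seed: int,
) -> dict[str, ScoreVector]:
    """GRS24 (observed where genotyped, conditionally simulated elsewhere),
    GRS68 (conditionally simulated throughout) and GRS92 = GRS24 + GRS68.

    The conditional simulation uses each panel's own score variance; for
    GRS24 that is the variance of the retained (post-LD-exclusion) panel.
    """
    rngs = child_rngs(seed)
    d, h = cohort["status"], cohort["famhist"]
    gcols = [f"g_{r}" for r in panel24.rsids if f"g_{r}" in cohort.columns]
    if gcols:
        observed = compute_grs_observed(cohort, panel24.subset([c[2:] for c in gcols]), "GRS24")
        masked = cohort.index.difference(observed.index)
    else:
        observed = None
        masked = cohort.index
    if len(masked):
        # anchor simulated draws at the panel's HWE mean so they share the
        # observed weighted-dosage scale (mixed provenance within GRS24)
        simulated = simulate_grs_conditional(
            d.loc[masked], h.loc[masked], panel24.sigma2, rngs["grs24_sim"], "GRS24",
            mu0=panel24.mean_score if observed is not None else 0.0,
        )
        if observed is not None and len(observed):
            vals = pd.concat([observed.values, simulated.values]).reindex(cohort.index)
            prov = pd.concat([observed.provenance, simulated.provenance]).reindex(cohort.index)
            grs24 = ScoreVector("GRS24", vals, prov)
        else:
            grs24 = ScoreVector("GRS24", simulated.values.reindex(cohort.index),
                                simulated.provenance.reindex(cohort.index))
    else:
        grs24 = observed
    grs68 = simulate_grs_conditional(d, h, panel68.sigma2, rngs["grs68_sim"], "GRS68")
    grs92 = combine_scores(grs24, grs68)
    return {"GRS24": grs24, "GRS68": grs68, "GRS92": grs92}


_TABLE2_PAIRS = [
    ("GRS24", ("GRS24", "GRS68")),
    ("GRS92", ("GRS92", "NMRFS")),
    ("GRS92", ("GRS92", "MRFS")),
    ("NMRFS", ("NMRFS", "MRFS")),
]


class PipelineStageError(RuntimeError):
    """Raised when a pipeline stage fails; carries the stage name."""

    def __init__(self, stage: str, err: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {err}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis and (optionally) write the output bundle.

    Returns a dict with the cohort, all score vectors, the decile table
    (``table1``), the score-comparison table (``table2``), descriptive
    summaries, projection curves and the provenance manifest.  If
    ``config.out_dir`` is set, every table is written as CSV with a
    seed/config-hash header plus ``manifest.json``.
    """
    out: dict = {}
    meta = {"seed": config.seed, "config_hash": config.digest(), "polyrisk_version": __version__}
    out_dir = Path(config.out_dir) if config.out_dir else None

    def _write(name, df, index=False):
        if out_dir is not None:
            write_csv(df, out_dir / name, meta, index=index)

    stage = "inputs"
    try:
        panel24 = read_panel(config.panel24_path) if config.panel24_path else None
        panel68 = read_panel(config.panel68_path) if config.panel68_path else None
        ld = read_ld(config.ld_path) if config.ld_path else None
        if panel24 is None or panel68 is None:
            d24, d68, dld = load_default_panels()
            panel24 = panel24 or d24
            panel68 = panel68 or d68
            ld = ld if ld is not None else dld
        baseline = (
            read_baseline(config.baseline_path) if config.baseline_path else load_default_incidence()
        )
        specs = config.factor_specs or default_risk_factors()
        surrogates = [p for p in config.surrogates if p[0] in panel24.rsids or p[1] in panel24.rsids]
        panel24r, report24 = ld_exclude(panel24, ld, config.r2_threshold, surrogates)
        _, report68 = ld_exclude(panel68, ld, config.r2_threshold, [])
        reports = [r for r in (report24, report68) if len(r)]
        out["ld_report"] = pd.concat(reports, ignore_index=True) if reports else report24

        stage = "simulate"
        cohort, info = simulate_cohort(config.cohort, panel24r, panel68, specs)
        out["cohort"], out["cohort_info"] = cohort, info
        _write("cohort.csv", cohort)

        stage = "scores"
        scores = build_genetic_scores(cohort, panel24r, panel68, config.seed)

        stage = "factor-scores"
        mrfs, nmrfs, weights = build_factor_scores(
            cohort, specs, combined=config.combined_adjustment
        )
        scores["MRFS"], scores["NMRFS"] = mrfs, nmrfs
        scores["FM"] = full_model(scores["GRS92"], mrfs, nmrfs)
        out["scores"] = scores
        out["weights"] = weights
        for nm, w in weights.items():
            _write(f"weights_{nm.lower()}.csv", w)
        score_df = pd.DataFrame(
            {
                "id": cohort["id"],
                "status": cohort["status"],
                "grs24": scores["GRS24"].values,
                "grs24_provenance": scores["GRS24"].provenance,
                "grs68": scores["GRS68"].values,
                "grs92": scores["GRS92"].values,
                "mrfs": mrfs.values.reindex(cohort.index),
                "nmrfs": nmrfs.values.reindex(cohort.index),
                "fm": scores["FM"].values.reindex(cohort.index),
            }
        )
        out["score_table"] = score_df
        _write("scores.csv", score_df)

        stage = "evaluate"
        status = cohort["status"]
        table1_rows = []
        for name in ("GRS92", "NMRFS", "MRFS", "FM"):
            sv = scores[name]
            try:
                labels, cuts = decile_assign(sv.values)
            except ValueError as err:
                warnings.warn(f"{name}: {err}; decile table skipped", stacklevel=2)
                continue
            tab = decile_or(labels, status.reindex(sv.index))
            tab.insert(0, "score", name)
            table1_rows.append(tab)
        table1 = (
            pd.concat(table1_rows, ignore_index=True)
            if table1_rows
            else pd.DataFrame(
                columns=["score", "decile", "n_cases", "n_controls", "odds_ratio", "ci_low", "ci_high", "flagged"]
            )
        )
        out["table1"] = table1
        _write("table1.csv", table1)
        if len(table1):
            wide = table1.assign(
                cell=lambda t: np.where(
                    t.decile == 1,
                    "1 (ref.)",
                    t.odds_ratio.map("{:.2f}".format)
                    + " ("
                    + t.ci_low.map("{:.2f}".format)
                    + "-"
                    + t.ci_high.map("{:.2f}".format)
                    + ")",
                )
            ).pivot(index="decile", columns="score", values="cell")
            _write("table1_formatted.csv", wide, index=True)

        table2_rows = []
        comparisons = []
        for base_name, parts in _TABLE2_PAIRS:
            a, b, base = scores[parts[0]], scores[parts[1]], scores[base_name]
            common = base.index.intersection(a.index).intersection(b.index)
            enhanced = combine_scores(
                ScoreVector(a.name, a.values.loc[common]),
                ScoreVector(b.name, b.values.loc[common]),
            )
            cmp_res = compare_scores(
                ScoreVector(base.name, base.values.loc[common]),
                enhanced,
                status.loc[common],
                auroc_mode=config.auroc_mode,
                refit=config.refit,
            )
            comparisons.append(cmp_res)
            table2_rows.append(
                (
                    cmp_res.base_name,
                    cmp_res.enhanced_name,
                    cmp_res.nri,
                    cmp_res.idi,
                    cmp_res.auroc_base,
                    cmp_res.auroc_enhanced,
                    cmp_res.delta_auroc,
                    cmp_res.p_value,
                )
            )
        table2 = pd.DataFrame(
            table2_rows,
            columns=["base", "enhanced", "nri", "idi", "auroc_base", "auroc_enhanced", "delta_auroc", "p_value"],
        )
        out["table2"] = table2
        out["comparisons"] = comparisons
        _write("table2.csv", table2)

        summary = score_summary(
            [scores[n] for n in ("GRS24", "GRS68", "GRS92", "MRFS", "NMRFS", "FM")], status
        )
        out["summary"] = summary
        _write("summary.csv", summary["summary"])
        _write("correlations.csv", summary["correlations"], index=True)
        for name, dens in summary["densities"].items():
            _write(f"density_{name.lower()}.csv", dens)

        stage = "project"
        curves = {}
        for name in config.project_scores:
            sv = scores[name]
            proj = IncidenceProjector().fit(sv, status.reindex(sv.index))
            cv = proj.percentile_curves(sv, baseline)
            cv.insert(0, "score", name)
            curves[name] = {"beta": proj.beta_, "mean_score": proj.mean_score_, "curves": cv}
            _write(f"curves_{name.lower()}.csv", cv)
        out["projection"] = curves

        stage = "manifest"
        manifest = {
            "seed": config.seed,
            "config_hash": config.digest(),
            "polyrisk_version": __version__,
            "n_cases": int(info["n_cases"]),
            "n_controls": int(info["n_controls"]),
            "panel_sizes": {"GRS24_retained": len(panel24r), "GRS68": len(panel68)},
            "sigma2": {"GRS24": panel24r.sigma2, "GRS68": panel68.sigma2},
            "auroc_mode": config.auroc_mode,
            "decile_rule": "pooled-sample linear-interpolation quantiles; ties to lower decile",
            "mean_anchor": "pooled case+control mean score",
        }
        out["manifest"] = manifest
        if out_dir is not None:
            out_dir.mkdir(parents=True, exist_ok=True)
            with open(out_dir / "manifest.json", "w") as fh:
                json.dump(manifest, fh, indent=2, sort_keys=True)
    except PipelineStageError:
        raise
    except Exception as err:
        raise PipelineStageError(stage, err) from err
    return out
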