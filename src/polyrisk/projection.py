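"""Absolute-risk projection: scale baseline age-specific incidence by score.

A univariate logistic regression of case status on a continuous score gives a
log odds ratio ``beta`` per score unit.  Each subject's expected age-specific
incidence curve is then the baseline rate table multiplied by
``exp(beta * (s_i - s_bar))``, where ``s_bar`` is the pooled mean score — a
rate-proportional model that treats the log-OR as a log rate ratio (a
standard approximation, adequate for a rare disease; see the methods note).
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator

from .genetic import ScoreVector

__all__ = [
    "validate_incidence_table",
    "fit_projection_beta",
    "project_incidence",
    "percentile_curves",
    "IncidenceProjector",
    "DEFAULT_PERCENTILES",
]

DEFAULT_PERCENTILES = (1, 5, 10, 25, 50, 75, 90, 95, 99)


def validate_incidence_table(baseline: pd.DataFrame) -> pd.DataFrame:
    """Check an age-specific incidence table: columns ``age_lo``, ``age_hi``,
    ``rate_per_100k``; contiguous non-overlapping intervals; rates >= 0."""
    required = {"age_lo", "age_hi", "rate_per_100k"}
    missing = required - set(baseline.columns)
    if missing:
        raise ValueError(f"incidence table missing columns: {sorted(missing)}")
    if len(baseline) == 0:
        raise ValueError("incidence table is empty")
    tab = baseline.sort_values("age_lo").reset_index(drop=True)
    if (tab["rate_per_100k"] < 0).any():
        raise ValueError("incidence rates must be nonnegative")
    if (tab["age_hi"] <= tab["age_lo"]).any():
        raise ValueError("age intervals must have age_hi > age_lo")
    gaps = tab["age_lo"].to_numpy()[1:] != tab["age_hi"].to_numpy()[:-1]
    if gaps.any():
        raise ValueError("age intervals must be contiguous and non-overlapping")
    return tab


def fit_projection_beta(score: ScoreVector, status) -> float:
    """Slope of the univariate logistic model of status on the score."""
    status = np.asarray(pd.Series(status).reindex(score.index) if hasattr(status, "reindex") else status, dtype=int)
    if not ((status == 1).any() and (status == 0).any()):
        raise ValueError("both cases and controls are required")
    x = sm.add_constant(score.values.to_numpy())
    res = sm.Logit(status, x).fit(method="newton", maxiter=100, tol=1e-10, disp=0)
    if not res.mle_retvals.get("converged", False):
        raise ValueError("projection logistic fit did not converge")
    return float(res.params[1])


def project_incidence(
    score: ScoreVector, beta: float, baseline: pd.DataFrame, mean_score: float | None = None
) -> pd.DataFrame:
    """Per-subject projected rates: ``baseline * exp(beta * (s_i - s_bar))``.

    Returns a frame indexed by subject with one column per age group
    (``"lo-hi"``), in the baseline table's units (per 100,000 woman-years).
    A subject at the mean score reproduces the baseline row exactly.
    """
    tab = validate_incidence_table(baseline)
    s = score.values
    s_bar = float(s.mean()) if mean_score is None else float(mean_score)
    mult = np.exp(beta * (s.to_numpy() - s_bar))
    rates = tab["rate_per_100k"].to_numpy()
    out = pd.DataFrame(
        np.outer(mult, rates),
        index=s.index,
        columns=[f"{int(lo)}-{int(hi)}" for lo, hi in zip(tab["age_lo"], tab["age_hi"])],
    )
    # bit-exact baseline at the mean: exp(0) == 1.0 multiplies losslessly
    return out


def percentile_curves(
    score: ScoreVector,
    beta: float,
    baseline: pd.DataFrame,
    percentiles=DEFAULT_PERCENTILES,
    mean_score: float | None = None,
) -> pd.DataFrame:
    """Projected incidence curves at the score's empirical percentiles.

    Returns a long frame (percentile, age_lo, age_hi, projected_rate); with a
    positive ``beta`` the curves are ordered bottom-to-top in percentile at
    every age group.
    """
    tab = validate_incidence_table(baseline)
    vals = score.values.to_numpy()
    if len(vals) < 100:
        warnings.warn(
            "fewer than 100 subjects: extreme percentiles clamp to the observed min/max",
            stacklevel=2,
        )
    s_bar = float(vals.mean()) if mean_score is None else float(mean_score)
    qs = np.percentile(vals, percentiles)  # linear interpolation, clamps at min/max
    rows = []
    for p, q in zip(percentiles, qs):
        mult = float(np.exp(beta * (q - s_bar)))
        for lo, hi, rate in zip(tab["age_lo"], tab["age_hi"], tab["rate_per_100k"]):
            rows.append((p, lo, hi, rate * mult))
    return pd.DataFrame(rows, columns=["percentile", "age_lo", "age_hi", "projected_rate"])


class IncidenceProjector(BaseEstimator):
    """Sklearn-style wrapper: fit the projection slope, predict rate curves.

    Parameters
    ----------
    percentiles : sequence of int
        Percentiles at which :meth:`percentile_curves` evaluates the score.

    Attributes
    ----------
    beta_ : fitted log-OR per score unit.
    mean_score_ : pooled mean score used as the baseline anchor.
    """

    def __init__(self, percentiles=DEFAULT_PERCENTILES):
        self.percentiles = percentiles

    def fit(self, score: ScoreVector, status):
        self.beta_ = fit_projection_beta(score, status)
        self.mean_score_ = float(score.values.mean())
        return self

    def predict(self, score: ScoreVector, baseline: pd.DataFrame) -> pd.DataFrame:
        return project_incidence(score, self.beta_, baseline, self.mean_score_)

    def percentile_curves(self, score: ScoreVector, baseline: pd.DataFrame) -> pd.DataFrame:
        return percentile_curves(score, self.beta_, baseline, self.percentiles, self.mean_score_)
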