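"""Discrimination and reclassification metrics for competing risk scores.

The workhorse quantities are:

* decile odds ratios — pooled-sample decile categorisation of a score, then
  the odds of disease in each decile relative to decile 1;
* AUROC — Mann-Whitney estimator (ties count 1/2), either on the raw score
  (``continuous``) or on the fitted probabilities of the decile logistic
  model (``decile-model``);
* the continuous net reclassification improvement (NRI),
  ``[P(up|case) - P(down|case)] + [P(down|control) - P(up|control)]``;
* the integrated discrimination improvement (IDI), the change in the
  case-control difference of mean predicted probability;
* DeLong's test for the difference of two correlated AUROCs.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
from sklearn.metrics import roc_auc_score

from .genetic import ScoreVector

__all__ = [
    "decile_assign",
    "decile_or",
    "auroc",
    "delong_compare",
    "continuous_nri",
    "idi",
    "logistic_probs",
    "compare_scores",
    "score_summary",
    "ComparisonResult",
    "DelongResult",
]


# ---------------------------------------------------------------- deciles

def decile_assign(values) -> tuple[pd.Series, np.ndarray]:
    """Pooled-sample decile labels (1..10) and the 9 interior cutpoints.

    Cutpoints are the 10%..90% linear-interpolation quantiles of the pooled
    (cases + controls) sample; a score tied with a cutpoint falls in the
    *lower* decile, so decile sizes can be unequal under heavy ties.
    """
    values = pd.Series(values, dtype=float)
    if values.nunique() < 10:
        raise ValueError(
            f"only {values.nunique()} distinct score values; decile categorisation "
            "needs at least 10 (use fewer bins)"
        )
    cuts = np.quantile(values.to_numpy(), np.arange(1, 10) / 10.0)
    labels = np.searchsorted(cuts, values.to_numpy(), side="left") + 1
    return pd.Series(labels, index=values.index, name="decile"), cuts


def _pair_logit_or(n_case_j, n_ctrl_j, n_case_1, n_ctrl_1):
    """OR of decile j vs decile 1 from a 2x2 logistic fit (saturated, so the
    MLE equals the cross-product ratio); returns (or, lo, hi)."""
    y = np.repeat([1, 0, 1, 0], [n_case_j, n_ctrl_j, n_case_1, n_ctrl_1])
    x = np.repeat([1.0, 1.0, 0.0, 0.0], [n_case_j, n_ctrl_j, n_case_1, n_ctrl_1])
    res = sm.Logit(y, sm.add_constant(x)).fit(method="newton", maxiter=100, tol=1e-12, disp=0)
    b, se = res.params[1], res.bse[1]
    return float(np.exp(b)), float(np.exp(b - 1.959963984540054 * se)), float(
        np.exp(b + 1.959963984540054 * se)
    )


def decile_or(deciles, status) -> pd.DataFrame:
    """Per-decile odds ratios vs decile 1 with Wald 95% CIs.

    A decile with a zero cell gets the raw cross-product ratio (possibly 0 or
    inf) with an undefined CI and ``flagged=True``; no continuity correction
    is applied.
    """
    deciles = pd.Series(deciles).astype(int)
    status = np.asarray(status, dtype=int)
    tab = pd.crosstab(deciles, pd.Series(status, index=deciles.index)).reindex(
        index=range(1, deciles.max() + 1), columns=[0, 1], fill_value=0
    )
    a1, b1 = int(tab.loc[1, 1]), int(tab.loc[1, 0])  # cases, controls in decile 1
    if a1 == 0 or b1 == 0:
        raise ValueError("reference decile 1 must contain both cases and controls")
    rows = []
    for j in tab.index:
        aj, bj = int(tab.loc[j, 1]), int(tab.loc[j, 0])
        if j == 1:
            rows.append((j, aj, bj, 1.0, np.nan, np.nan, False))
            continue
        if aj == 0 or bj == 0:
            with np.errstate(divide="ignore"):
                cross = (aj * b1) / (bj * a1) if bj else np.inf
            rows.append((j, aj, bj, float(cross), np.nan, np.nan, True))
            continue
        or_, lo, hi = _pair_logit_or(aj, bj, a1, b1)
        rows.append((j, aj, bj, or_, lo, hi, False))
    return pd.DataFrame(
        rows, columns=["decile", "n_cases", "n_controls", "odds_ratio", "ci_low", "ci_high", "flagged"]
    )


# ---------------------------------------------------------------- AUROC

def _check_arms(status):
    status = np.asarray(status, dtype=int)
    if not ((status == 1).any() and (status == 0).any()):
        raise ValueError("both cases and controls are required")
    return status


def decile_model_probs(values, status) -> np.ndarray:
    """Fitted probabilities of the decile logistic model.

    The model on 9 decile indicators is saturated, so its MLE fitted value in
    each decile is that decile's observed case fraction.
    """
    status = _check_arms(status)
    labels, _ = decile_assign(values)
    frac = pd.Series(status, index=labels.index).groupby(labels).mean()
    return labels.map(frac).to_numpy(dtype=float)


def auroc(scores, status, mode: str = "continuous") -> float:
    """Mann-Whitney AUROC (ties count 1/2).

    ``mode="decile-model"`` first collapses subjects to their decile-model
    fitted probability; ``mode="continuous"`` ranks the raw score.  A constant
    predictor yields 0.5 with a warning.
    """
    status = _check_arms(status)
    scores = np.asarray(pd.Series(scores, dtype=float))
    if np.ptp(scores) == 0.0:
        warnings.warn("constant predictor: AUROC is 0.5 by convention", stacklevel=2)
        return 0.5
    if mode == "decile-model":
        scores = decile_model_probs(scores, status)
        if np.ptp(scores) == 0.0:
            warnings.warn("constant decile-model probabilities: AUROC is 0.5", stacklevel=2)
            return 0.5
    elif mode != "continuous":
        raise ValueError(f"unknown mode {mode!r}")
    return float(roc_auc_score(status, scores))


# ---------------------------------------------------------------- DeLong

class DelongResult(NamedTuple):
    delta: float
    p_value: float
    variance: float


def _midrank(x: np.ndarray) -> np.ndarray:
    order = np.argsort(x, kind="mergesort")
    z = x[order]
    n = len(x)
    t = np.zeros(n)
    i = 0
    while i < n:
        j = i
        while j < n and z[j] == z[i]:
            j += 1
        t[i:j] = 0.5 * (i + j - 1) + 1.0
        i = j
    out = np.empty(n)
    out[order] = t
    return out


def delong_compare(probs_a, probs_b, status) -> DelongResult:
    """DeLong's paired test for the difference of two correlated AUROCs.

    Returns ``delta = AUROC(b) - AUROC(a)``, the two-sided p-value, and the
    variance estimate of ``delta``.  Identical predictors short-circuit to
    ``(0, 1, 0)``; otherwise a zero variance of the placement values is an
    error.
    """
    status = _check_arms(status)
    pa = np.asarray(pd.Series(probs_a, dtype=float))
    pb = np.asarray(pd.Series(probs_b, dtype=float))
    if pa.shape != pb.shape or pa.shape != status.shape:
        raise ValueError("probs_a, probs_b and status must have equal length")
    if np.array_equal(pa, pb):
        return DelongResult(0.0, 1.0, 0.0)
    preds = np.vstack([pa, pb])
    pos, neg = preds[:, status == 1], preds[:, status == 0]
    m, n = pos.shape[1], neg.shape[1]
    v01 = np.empty((2, m))
    v10 = np.empty((2, n))
    aucs = np.empty(2)
    for r in range(2):
        tx = _midrank(pos[r])
        ty = _midrank(neg[r])
        tz = _midrank(np.concatenate([pos[r], neg[r]]))
        aucs[r] = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
        v01[r] = (tz[:m] - tx) / n
        v10[r] = 1.0 - (tz[m:] - ty) / m
    s01 = np.cov(v01)
    s10 = np.cov(v10)
    cov = s01 / m + s10 / n
    var = float(cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1])
    delta = float(aucs[1] - aucs[0])
    if var <= 0.0:
        raise ValueError("degenerate placement values: zero variance in DeLong test")
    z = delta / np.sqrt(var)
    return DelongResult(delta, float(2.0 * st.norm.sf(abs(z))), var)


# ------------------------------------------------------- reclassification

def continuous_nri(p_base, p_new, status) -> float:
    """Continuous NRI: any upward move counts for cases, any downward move
    for controls; ties contribute to neither direction."""
    status = _check_arms(status)
    pb = np.asarray(pd.Series(p_base, dtype=float))
    pn = np.asarray(pd.Series(p_new, dtype=float))
    if pb.shape != pn.shape or pb.shape != status.shape:
        raise ValueError("p_base, p_new and status must have equal length")
    up = pn > pb
    down = pn < pb
    case = status == 1
    nri_case = up[case].mean() - down[case].mean()
    nri_ctrl = down[~case].mean() - up[~case].mean()
    return float(nri_case + nri_ctrl)


def idi(p_base, p_new, status) -> float:
    """IDI: gain in mean predicted probability among cases plus drop among
    controls, base -> new.  Inputs must be fitted probabilities in [0, 1]."""
    status = _check_arms(status)
    pb = np.asarray(pd.Series(p_base, dtype=float))
    pn = np.asarray(pd.Series(p_new, dtype=float))
    if pb.shape != pn.shape or pb.shape != status.shape:
        raise ValueError("p_base, p_new and status must have equal length")
    for name, p in (("p_base", pb), ("p_new", pn)):
        if (p < 0).any() or (p > 1).any():
            raise ValueError(f"{name} must lie in [0, 1]")
    case = status == 1
    return float((pn[case].mean() - pb[case].mean()) + (pb[~case].mean() - pn[~case].mean()))


# ----------------------------------------------------------- comparisons

def logistic_probs(values, status) -> np.ndarray:
    """Fitted probabilities of the univariate logistic model of status on a
    continuous score (the inputs NRI and IDI are computed on)."""
    status = _check_arms(status)
    x = sm.add_constant(np.asarray(pd.Series(values, dtype=float)))
    res = sm.Logit(status, x).fit(method="newton", maxiter=100, tol=1e-10, disp=0)
    if not res.mle_retvals.get("converged", False):
        raise ValueError("univariate logistic fit did not converge")
    return np.asarray(res.predict(x))


@dataclass(frozen=True)
class ComparisonResult:
    """Base vs enhanced score comparison: NRI, IDI, AUROCs and DeLong p."""

    base_name: str
    enhanced_name: str
    nri: float
    idi: float
    auroc_base: float
    auroc_enhanced: float
    delta_auroc: float
    p_value: float

    def __post_init__(self):
        if abs(self.delta_auroc - (self.auroc_enhanced - self.auroc_base)) > 1e-12:
            raise ValueError("delta_auroc must equal auroc_enhanced - auroc_base")
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value must lie in [0, 1]")


def compare_scores(
    base: ScoreVector,
    enhanced: ScoreVector,
    status,
    auroc_mode: str = "decile-model",
    refit: bool = False,
) -> ComparisonResult:
    """Quantify the gain of an enhanced (nested) score over a base score.

    Nesting is asserted by the caller: the enhanced composite is expected to
    be the base score plus an added component.  NRI and IDI are computed on
    fitted probabilities from univariate logistic models of status on each
    composite score (``refit=True`` instead refits the enhanced model on the
    base score and the added component jointly).  AUROCs follow
    ``auroc_mode``; too few distinct values for deciles falls back to the
    continuous mode with a warning.  The p-value is DeLong's test on the same
    predictors as the reported AUROCs.
    """
    if not base.index.equals(enhanced.index):
        if set(base.index) != set(enhanced.index):
            raise ValueError("base and enhanced scores must cover the same subjects")
        enhanced = ScoreVector(enhanced.name, enhanced.values.reindex(base.index))
    status = _check_arms(status)
    vb = base.values.to_numpy()
    ve = enhanced.values.to_numpy()

    p_base = logistic_probs(vb, status)
    if refit:
        x = sm.add_constant(np.column_stack([vb, ve - vb]))
        res = sm.Logit(status, x).fit(method="newton", maxiter=100, tol=1e-10, disp=0)
        p_new = np.asarray(res.predict(x))
    else:
        p_new = logistic_probs(ve, status)
    nri_val = continuous_nri(p_base, p_new, status)
    idi_val = idi(p_base, p_new, status)

    def _mode_pred(v):
        if auroc_mode == "decile-model":
            try:
                return decile_model_probs(v, status)
            except ValueError:
                warnings.warn("too few distinct values for deciles; continuous AUROC used", stacklevel=2)
                return v
        return v

    qb, qe = _mode_pred(vb), _mode_pred(ve)
    auc_b = auroc(qb, status, mode="continuous") if np.ptp(qb) else 0.5
    auc_e = auroc(qe, status, mode="continuous") if np.ptp(qe) else 0.5
    if np.ptp(qb) == 0 and np.ptp(qe) == 0:
        p_val = 1.0
    else:
        p_val = delong_compare(qb, qe, status).p_value
    return ComparisonResult(
        base.name, enhanced.name, nri_val, idi_val, auc_b, auc_e, auc_e - auc_b, p_val
    )


# -------------------------------------------------------------- summaries

def score_summary(scores: list[ScoreVector], status, kde_points: int = 128) -> dict:
    """Descriptive comparison of scores: case/control means with Student-t
    tests, the pairwise Pearson correlation matrix, and per-arm kernel
    density grids for plotting."""
    if len(scores) < 2:
        raise ValueError("need at least two scores to summarise")
    status = pd.Series(status)
    rows = []
    densities = {}
    frame = {}
    for sv in scores:
        v = sv.values
        st_al = status.reindex(v.index) if len(status) != len(v) or not status.index.equals(v.index) else status
        case = v[st_al.to_numpy() == 1].to_numpy()
        ctrl = v[st_al.to_numpy() == 0].to_numpy()
        constant = np.ptp(v.to_numpy()) == 0.0
        if constant:
            t, p = 0.0, 1.0
            warnings.warn(f"score {sv.name!r} is constant: correlation undefined", stacklevel=2)
        else:
            t, p = st.ttest_ind(case, ctrl, equal_var=True)
        rows.append(
            (sv.name, len(case), len(ctrl), case.mean(), ctrl.mean(), float(t), float(p), constant)
        )
        frame[sv.name] = v
        if not constant:
            grid = np.linspace(v.min(), v.max(), kde_points)
            dens = {"grid": grid}
            for label, arm in (("cases", case), ("controls", ctrl)):
                dens[label] = st.gaussian_kde(arm)(grid) if np.ptp(arm) else np.full(kde_points, np.nan)
            densities[sv.name] = pd.DataFrame(dens)
    summary = pd.DataFrame(
        rows,
        columns=["score", "n_cases", "n_controls", "mean_cases", "mean_controls", "t", "p_value", "constant"],
    )
    corr = pd.DataFrame(frame).corr(method="pearson")
    return {"summary": summary, "correlations": corr, "densities": densities}
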