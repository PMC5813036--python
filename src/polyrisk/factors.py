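"""Risk-factor scores from mutually adjusted logistic log-odds weights.

A factor score is built by fitting one multivariate logistic regression of
case status on a set of dummy-coded categorical risk factors (reference =
first category) and then summing, for each subject, the fitted beta of the
category she occupies in every factor.  Subjects in all reference categories
score 0.  The modifiable score (MRFS) and non-modifiable score (NMRFS) are
fitted in two separate models by default — each beta adjusted only for the
other factors in its own set — with a combined-adjustment mode available.
"""
from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, TransformerMixin
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

from .cohort import RiskFactorSpec
from .genetic import ScoreVector

__all__ = [
    "FactorScoreModel",
    "fit_score_weights",
    "apply_score",
    "full_model",
    "build_factor_scores",
]

logger = logging.getLogger(__name__)


def _factor_categories(col: pd.Series):
    if isinstance(col.dtype, pd.CategoricalDtype):
        return [c for c in col.cat.categories if (col == c).any()]
    return sorted(col.dropna().unique().tolist())


class FactorScoreModel(TransformerMixin, BaseEstimator):
    """Sklearn-style estimator: fit adjusted log-OR weights, transform to scores.

    Parameters
    ----------
    factors : list of str
        Cohort columns to include.  Categorical columns use their declared
        category order (first = reference); other columns use sorted unique
        values.
    name : str
        Name given to the resulting score vector (e.g. ``"MRFS"``).

    Attributes
    ----------
    weights_ : DataFrame with columns factor, category, beta, se, reference.
    n_used_ : number of complete-case subjects in the fit.
    converged_ : bool.
    dropped_factors_ : factors excluded for having a single observed category.
    """

    def __init__(self, factors=None, name: str = "RFS"):
        self.factors = factors
        self.name = name

    def fit(self, X: pd.DataFrame, y=None):
        if self.factors is None:
            raise ValueError("factors must be specified")
        if y is None:
            y = X["status"]
        y = pd.Series(y).astype(float)
        if y.nunique() != 2 or not set(y.unique()) <= {0.0, 1.0}:
            raise ValueError("status must be a 0/1 vector with both arms present")
        missing = [f for f in self.factors if f not in X.columns]
        if missing:
            raise KeyError(f"factor columns not in cohort: {missing}")

        complete = X[list(self.factors)].notna().all(axis=1)
        n_dropped = int((~complete).sum())
        if n_dropped:
            logger.info("%s fit: excluded %d subjects with missing factor values", self.name, n_dropped)
        Xc = X.loc[complete]
        yc = pd.Series(np.asarray(y, dtype=float)[complete.to_numpy()])

        design = {}
        records = []
        self.dropped_factors_ = []
        self.categories_ = {}
        for f in self.factors:
            cats = _factor_categories(Xc[f])
            if len(cats) < 2:
                warnings.warn(f"factor {f!r} has a single observed category; dropped", stacklevel=2)
                self.dropped_factors_.append(f)
                continue
            self.categories_[f] = cats
            records.append((f, cats[0], 0.0, np.nan, True))
            for c in cats[1:]:
                design[(f, c)] = (Xc[f] == c).to_numpy(dtype=float)
                records.append((f, c, np.nan, np.nan, False))
        if not design:
            raise ValueError("no factor with at least two categories to fit")

        exog = sm.add_constant(pd.DataFrame(design, index=Xc.index).to_numpy())
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            try:
                res = sm.Logit(yc.to_numpy(), exog).fit(method="newton", maxiter=100, tol=1e-10, disp=0)
            except (PerfectSeparationError, PerfectSeparationWarning) as err:
                raise ValueError(
                    f"complete separation while fitting {self.name} on factors {list(design)}"
                ) from err
        if not res.mle_retvals.get("converged", False) or not np.all(np.isfinite(res.params)):
            raise ValueError(f"logistic fit for {self.name} did not converge")

        wt = pd.DataFrame(records, columns=["factor", "category", "beta", "se", "reference"])
        betas = dict(zip(design.keys(), res.params[1:]))
        ses = dict(zip(design.keys(), res.bse[1:]))
        for i, row in wt.iterrows():
            if not row.reference:
                wt.at[i, "beta"] = betas[(row.factor, row.category)]
                wt.at[i, "se"] = ses[(row.factor, row.category)]
        self.weights_ = wt
        self.intercept_ = float(res.params[0])
        self.n_used_ = int(complete.sum())
        self.converged_ = bool(res.mle_retvals.get("converged", False))
        return self

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        return self.score_vector(X).values.to_numpy().reshape(-1, 1)

    def score_vector(self, X: pd.DataFrame) -> ScoreVector:
        """Per-subject sum of the fitted betas; complete-case on the factors."""
        if not hasattr(self, "weights_"):
            raise ValueError("model is not fitted")
        return apply_score(X, self.weights_, self.name)


def fit_score_weights(cohort: pd.DataFrame, factors: list[str], status=None) -> pd.DataFrame:
    """Adjusted log-OR weight table from one multivariate logistic fit."""
    return FactorScoreModel(factors=factors).fit(cohort, status).weights_


def apply_score(cohort: pd.DataFrame, weights: pd.DataFrame, name: str = "RFS") -> ScoreVector:
    """``score_i = sum_f beta(f, category_i(f))`` over the weight table's factors.

    Subjects with a missing value in any scored factor are excluded
    (complete-case) and their count logged; an unseen non-missing category is
    an error.
    """
    factors = weights["factor"].unique().tolist()
    complete = cohort[factors].notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("%s: excluded %d subjects with missing factor values", name, n_dropped)
    sub = cohort.loc[complete]
    total = np.zeros(len(sub))
    for f in factors:
        bmap = dict(
            zip(weights.loc[weights.factor == f, "category"], weights.loc[weights.factor == f, "beta"])
        )
        col = sub[f]
        if isinstance(col.dtype, pd.CategoricalDtype):
            col = col.astype(object)
        unseen = set(col.unique()) - set(bmap)
        if unseen:
            raise ValueError(f"factor {f!r} has categories absent from the weight table: {sorted(unseen)}")
        total += col.map(bmap).to_numpy(dtype=float)
    return ScoreVector(name, pd.Series(total, index=sub.index), pd.Series("observed", index=sub.index))


def full_model(grs92: ScoreVector, mrfs: ScoreVector, nmrfs: ScoreVector) -> ScoreVector:
    """Full-model score FM = GRS92 + MRFS + NMRFS on the complete-case
    intersection of the three subject sets."""
    common = grs92.index.intersection(mrfs.index).intersection(nmrfs.index)
    if len(common) == 0:
        raise ValueError("no common subjects across GRS92, MRFS and NMRFS")
    vals = (
        grs92.values.loc[common] + mrfs.values.loc[common] + nmrfs.values.loc[common]
    )
    prov = np.where(grs92.provenance.loc[common].to_numpy() == "observed", "observed", "mixed")
    return ScoreVector("FM", vals, pd.Series(prov, index=common))


def build_factor_scores(
    cohort: pd.DataFrame,
    specs: list[RiskFactorSpec],
    status=None,
    combined: bool = False,
) -> tuple[ScoreVector, ScoreVector, dict[str, pd.DataFrame]]:
    """Fit MRFS and NMRFS for a cohort generated from ``specs``.

    ``combined=False`` (default) fits two separate multivariate models, one
    per factor set; ``combined=True`` adjusts every factor for all others in a
    single model and splits the resulting weights by set.
    """
    mod = [s.name for s in specs if s.modifiable]
    nonmod = [s.name for s in specs if not s.modifiable]
    if combined:
        w = fit_score_weights(cohort, mod + nonmod, status)
        w_m, w_n = w[w.factor.isin(mod)], w[w.factor.isin(nonmod)]
    else:
        w_m = fit_score_weights(cohort, mod, status)
        w_n = fit_score_weights(cohort, nonmod, status)
    mrfs = apply_score(cohort, w_m, "MRFS")
    nmrfs = apply_score(cohort, w_n, "NMRFS")
    return mrfs, nmrfs, {"MRFS": w_m.reset_index(drop=True), "NMRFS": w_n.reset_index(drop=True)}
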