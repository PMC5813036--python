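"""Discrimination/reclassification metrics against independent oracles."""
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from polyrisk.evaluation import (
    auroc,
    compare_scores,
    continuous_nri,
    decile_assign,
    decile_or,
    delong_compare,
    idi,
    logistic_probs,
    score_summary,
)
from polyrisk.genetic import ScoreVector


def _auroc_all_pairs(scores, status):
    """Brute-force Mann-Whitney: every (case, control) pair, ties count 1/2."""
    scores = np.asarray(scores, float)
    cases = scores[np.asarray(status) == 1]
    ctrls = scores[np.asarray(status) == 0]
    total = 0.0
    for c in cases:
        for u in ctrls:
            total += 1.0 if c > u else (0.5 if c == u else 0.0)
    return total / (len(cases) * len(ctrls))


class TestDecileAssign:
    def test_uniform_distinct_ten_per_decile(self):
        labels, cuts = decile_assign(pd.Series(np.arange(1, 101, dtype=float)))
        assert labels.value_counts().eq(10).all()
        assert len(cuts) == 9 and (np.diff(cuts) >= 0).all()

    def test_ties_go_to_lower_decile(self):
        # 50 copies of one value straddle a cutpoint: all land below it
        vals = pd.Series(np.r_[np.arange(50, dtype=float), np.full(50, 50.0)])
        labels, cuts = decile_assign(vals)
        tied = labels[vals == 50.0]
        assert tied.nunique() == 1
        # enumeration under the tie rule: v == cutpoint -> lower decile
        v = 50.0
        expected = int(np.searchsorted(cuts, v, side="left")) + 1
        assert (tied == expected).all()

    def test_monotone_transform_invariance(self, rng):
        vals = pd.Series(rng.normal(size=500))
        a, _ = decile_assign(vals)
        b, _ = decile_assign(np.exp(vals) + 3.0)
        assert a.equals(b)

    def test_too_few_distinct_values(self):
        with pytest.raises(ValueError, match="distinct"):
            decile_assign(pd.Series([1.0] * 30 + [2.0] * 30))


class TestDecileOr:
    @staticmethod
    def _make(counts):
        """counts: {decile: (n_cases, n_controls)} -> (labels, status)."""
        labels, status = [], []
        for dec, (nc, nu) in counts.items():
            labels += [dec] * (nc + nu)
            status += [1] * nc + [0] * nu
        return pd.Series(labels), np.array(status)

    def test_cross_product_oracle(self):
        labels, status = self._make({1: (10, 20), 10: (20, 10)})
        tab = decile_or(labels, status)
        got = tab.loc[tab.decile == 10, "odds_ratio"].item()
        assert got == pytest.approx((20 * 20) / (10 * 10), abs=1e-6)  # = 4.0

    def test_reference_or_is_one(self):
        labels, status = self._make({1: (10, 20), 2: (5, 10)})
        tab = decile_or(labels, status)
        assert tab.loc[tab.decile == 1, "odds_ratio"].item() == 1.0

    def test_equal_ratio_gives_unit_or(self):
        labels, status = self._make({1: (10, 20), 5: (30, 60)})
        tab = decile_or(labels, status)
        assert tab.loc[tab.decile == 5, "odds_ratio"].item() == pytest.approx(1.0, abs=1e-6)

    def test_zero_cell_flagged_without_correction(self):
        labels, status = self._make({1: (10, 20), 2: (5, 0)})
        tab = decile_or(labels, status)
        row = tab.loc[tab.decile == 2].iloc[0]
        assert row.flagged and np.isinf(row.odds_ratio) and np.isnan(row.ci_low)

    def test_empty_reference_decile_error(self):
        labels, status = self._make({1: (10, 0), 2: (5, 5)})
        with pytest.raises(ValueError, match="decile 1"):
            decile_or(labels, status)


class TestAuroc:
    def test_perfect_separation(self):
        s = np.r_[np.ones(5), np.zeros(5)]
        d = np.r_[np.ones(5, int), np.zeros(5, int)]
        assert auroc(s, d) == 1.0

    def test_identical_distributions(self):
        s = np.r_[np.arange(6.0), np.arange(6.0)]
        d = np.r_[np.ones(6, int), np.zeros(6, int)]
        assert auroc(s, d) == 0.5

    def test_interleaved_matches_all_pairs(self):
        s = np.array([1, 3, 5, 7, 9, 11, 2, 4, 6, 8, 10, 12], float)
        d = np.r_[np.ones(6, int), np.zeros(6, int)]
        assert auroc(s, d) == pytest.approx(_auroc_all_pairs(s, d), abs=1e-12)

    def test_constant_predictor_warns_half(self):
        d = np.r_[np.ones(5, int), np.zeros(5, int)]
        with pytest.warns(UserWarning, match="constant"):
            assert auroc(np.ones(10), d) == 0.5

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(hst.integers(0, 10_000))
    def test_negation_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        s = rng.normal(size=30).round(1)  # rounding forces ties
        d = rng.integers(0, 2, 30)
        if d.sum() in (0, 30):
            return
        assert auroc(-s, d) == pytest.approx(1.0 - auroc(s, d), abs=1e-12)

    def test_decile_model_mode_uses_decile_case_fractions(self, rng):
        s = rng.normal(size=400)
        d = rng.integers(0, 2, 400)
        got = auroc(s, d, mode="decile-model")
        labels, _ = decile_assign(pd.Series(s))
        frac = pd.Series(d).groupby(labels.to_numpy()).mean()
        assert got == pytest.approx(_auroc_all_pairs(labels.map(frac), d), abs=1e-12)


class TestDelong:
    def test_self_comparison(self, rng):
        p = rng.random(40)
        d = rng.integers(0, 2, 40)
        d[:2] = [0, 1]
        res = delong_compare(p, p, d)
        assert res.delta == 0.0 and res.p_value == 1.0

    def test_antisymmetry(self, rng):
        a, b = rng.random(60), rng.random(60)
        d = rng.integers(0, 2, 60)
        d[:2] = [0, 1]
        r1 = delong_compare(a, b, d)
        r2 = delong_compare(b, a, d)
        assert r1.delta == pytest.approx(-r2.delta, abs=1e-12)
        assert r1.p_value == pytest.approx(r2.p_value, abs=1e-12)

    def test_variance_close_to_bootstrap(self):
        rng = np.random.default_rng(5)
        n = 200
        d = np.r_[np.ones(n // 2, int), np.zeros(n // 2, int)]
        latent = rng.normal(size=n) + 0.8 * d
        a = latent + rng.normal(scale=1.0, size=n)
        b = latent + rng.normal(scale=0.7, size=n)
        res = delong_compare(a, b, d)
        boots = []
        for _ in range(2000):
            idx = rng.integers(0, n, n)
            if d[idx].sum() in (0, n):
                continue
            boots.append(
                auroc(b[idx], d[idx]) - auroc(a[idx], d[idx])
            )
        boot_var = np.var(boots, ddof=1)
        assert res.variance == pytest.approx(boot_var, rel=0.15)


class TestReclassification:
    def test_nri_directional_enumeration(self):
        # one case moves up, one case moves down -> case term 0;
        # both controls move down -> control term 1; NRI = 1.0
        d = np.array([1, 1, 0, 0])
        p_base = np.array([0.5, 0.5, 0.5, 0.5])
        p_new = np.array([0.6, 0.4, 0.4, 0.3])
        assert continuous_nri(p_base, p_new, d) == pytest.approx(1.0)

    def test_nri_bounds_and_identity(self):
        d = np.array([1, 1, 0, 0])
        p = np.array([0.5, 0.6, 0.4, 0.3])
        assert continuous_nri(p, p, d) == 0.0
        assert continuous_nri(p, p + np.where(d == 1, 0.1, -0.1), d) == pytest.approx(2.0)

    def test_nri_ties_count_neither_direction(self):
        d = np.array([1, 1, 0, 0])
        p_base = np.array([0.5, 0.5, 0.5, 0.5])
        p_new = np.array([0.6, 0.5, 0.5, 0.5])  # one case up, everything else tied
        assert continuous_nri(p_base, p_new, d) == pytest.approx(0.5)

    def test_idi_term_arithmetic(self):
        # case means 0.5 -> 0.6, control means 0.5 -> 0.45: IDI = 0.1 + 0.05
        d = np.array([1, 1, 0, 0])
        p_base = np.array([0.4, 0.6, 0.5, 0.5])
        p_new = np.array([0.55, 0.65, 0.5, 0.4])
        assert idi(p_base, p_new, d) == pytest.approx(0.15)

    def test_idi_range_validation(self):
        d = np.array([1, 0])
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            idi(np.array([0.5, 1.2]), np.array([0.5, 0.5]), d)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(hst.integers(0, 10_000))
    def test_antisymmetry(self, seed):
        rng = np.random.default_rng(seed)
        n = 24
        d = rng.integers(0, 2, n)
        if d.sum() in (0, n):
            return
        pa, pb = rng.random(n), rng.random(n)
        assert continuous_nri(pa, pb, d) == pytest.approx(-continuous_nri(pb, pa, d), abs=1e-12)
        assert idi(pa, pb, d) == pytest.approx(-idi(pb, pa, d), abs=1e-12)


class TestCompareScores:
    def test_nested_comparison_consistency(self, rng):
        n = 600
        d = np.r_[np.ones(n // 2, int), np.zeros(n // 2, int)]
        base_vals = rng.normal(size=n) + 0.3 * d
        add_vals = rng.normal(size=n) + 0.3 * d
        idx = [f"s{i}" for i in range(n)]
        base = ScoreVector("GRS24", pd.Series(base_vals, index=idx))
        enh = ScoreVector("GRS92", pd.Series(base_vals + add_vals, index=idx))
        res = compare_scores(base, enh, pd.Series(d, index=idx), auroc_mode="continuous")
        assert res.delta_auroc == pytest.approx(res.auroc_enhanced - res.auroc_base, abs=1e-12)
        pb = logistic_probs(base_vals, d)
        pn = logistic_probs(base_vals + add_vals, d)
        assert res.nri == pytest.approx(continuous_nri(pb, pn, d), abs=1e-12)
        assert res.idi == pytest.approx(idi(pb, pn, d), abs=1e-12)
        assert 0.0 < res.p_value < 1.0


class TestScoreSummary:
    def _svs(self, rng, n=300):
        idx = [f"s{i}" for i in range(n)]
        return [
            ScoreVector("A", pd.Series(rng.normal(size=n), index=idx)),
            ScoreVector("B", pd.Series(rng.normal(size=n), index=idx)),
        ], pd.Series(rng.integers(0, 2, n), index=idx)

    def test_identical_arms_t_zero(self):
        idx = [f"s{i}" for i in range(8)]
        vals = pd.Series([1, 2, 3, 4, 1, 2, 3, 4], index=idx, dtype=float)
        status = pd.Series([1, 1, 1, 1, 0, 0, 0, 0], index=idx)
        out = score_summary(
            [ScoreVector("A", vals), ScoreVector("B", vals + 1)], status
        )
        assert out["summary"]["t"].abs().max() == pytest.approx(0.0, abs=1e-12)

    def test_self_correlation_one(self, rng):
        svs, status = self._svs(rng)
        out = score_summary(svs, status)
        assert np.allclose(np.diag(out["correlations"]), 1.0)

    def test_constant_score_flagged(self, rng):
        svs, status = self._svs(rng)
        svs.append(ScoreVector("C", pd.Series(np.ones(300), index=svs[0].index)))
        with pytest.warns(UserWarning, match="constant"):
            out = score_summary(svs, status)
        assert out["summary"].set_index("score").loc["C", "constant"]

    def test_independent_scores_near_zero_correlation(self):
        hits = 0
        reps = 20
        n = 3642
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            a, b = rng.normal(size=n), rng.normal(size=n)
            if abs(np.corrcoef(a, b)[0, 1]) < 0.06:
                hits += 1
        assert hits >= int(0.95 * reps)
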