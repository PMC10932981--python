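import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from binovision.stats import (
    fisher_compare,
    mann_whitney,
    spearman,
    two_way_anova,
    two_way_anova_from_summary,
    wmw_power,
)


def exact_mw_p(x, y):
    """Two-sided p by exhaustive enumeration of all rank assignments."""
    x, y = list(x), list(y)
    n1 = len(x)
    pooled = x + y
    obs_u = mann_whitney(x, y).statistic
    n = len(pooled)
    us = []
    for idx in itertools.combinations(range(n), n1):
        ranks = sps.rankdata(pooled)
        r1 = sum(ranks[i] for i in idx)
        us.append(r1 - n1 * (n1 + 1) / 2)
    us = np.array(us)
    mu = n1 * (n - n1) / 2
    return float(np.mean(np.abs(us - mu) >= abs(obs_u - mu) - 1e-12))


class TestMannWhitney:
    def test_identical_samples_null(self):
        r = mann_whitney([1, 2, 3, 4], [1, 2, 3, 4])
        assert r.z == pytest.approx(0.0)
        assert r.p == pytest.approx(1.0)

    def test_extreme_separation(self):
        r = mann_whitney([1, 2, 3, 4], [10, 11, 12, 13])
        assert r.statistic == 0.0
        assert r.z < 0

    def test_matches_exact_enumeration_small(self):
        rng = np.random.default_rng(0)
        for n1, n2 in [(3, 3), (4, 4), (3, 5), (2, 6)]:
            x = rng.normal(0, 1, n1).round(1)
            y = rng.normal(0.8, 1, n2).round(1)
            p_exact = exact_mw_p(x, y)
            # the enumeration oracle itself agrees with scipy's exact method
            if len(np.unique(np.r_[x, y])) == n1 + n2:  # no ties
                ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
                assert p_exact == pytest.approx(ref.pvalue, rel=1e-9)
            # and the normal approximation tracks it at small n
            p_normal = mann_whitney(x, y).p
            assert p_normal == pytest.approx(p_exact, abs=0.2)

    def test_matches_scipy_asymptotic(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 28)
        y = rng.normal(1, 1, 28)
        r = mann_whitney(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided",
                               method="asymptotic", use_continuity=False)
        assert r.p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_tie_correction_against_scipy(self):
        x = [1, 1, 2, 2, 3, 3, 3]
        y = [2, 2, 3, 4, 4, 5, 5]
        r = mann_whitney(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided",
                               method="asymptotic", use_continuity=False)
        assert r.p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestSpearman:
    def test_perfect_monotone(self):
        assert spearman([1, 2, 3, 4], [10, 20, 25, 90]).rho == pytest.approx(1.0)
        assert spearman([1, 2, 3, 4], [4, 3, 2, 1]).rho == pytest.approx(-1.0)

    def test_six_point_rank_formula(self):
        # hand computation: rho = 1 - 6*sum(d^2)/(n(n^2-1)) without ties
        x = [3, 1, 4, 1.5, 5, 9]
        y = [2, 7, 1, 8, 2.5, 9.5]
        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        d2 = float(np.sum((rx - ry) ** 2))
        expected = 1 - 6 * d2 / (6 * 35)
        assert spearman(x, y).rho == pytest.approx(expected)

    def test_constant_input_flagged(self):
        r = spearman([1, 1, 1, 1], [1, 2, 3, 4])
        assert not r.defined


class TestFisherCompare:
    def test_equal_rhos_zero(self):
        z, p = fisher_compare(0.5, 30, 0.5, 25)
        assert z == 0.0
        assert p == pytest.approx(1.0)

    def test_antisymmetry(self):
        z1, _ = fisher_compare(0.7, 28, 0.3, 28)
        z2, _ = fisher_compare(0.3, 28, 0.7, 28)
        assert z1 == pytest.approx(-z2)

    def test_printed_correlation_contrast(self):
        # 0.77 vs 0.40 with 28 per group: direct evaluation gives ~2.11
        z, p = fisher_compare(0.77, 28, 0.40, 28)
        assert z == pytest.approx(2.1096, abs=1e-3)
        assert p < 0.05

    def test_degenerate_rho_rejected(self):
        with pytest.raises(ValueError):
            fisher_compare(1.0, 28, 0.4, 28)


class TestTwoWayAnova:
    def test_constant_data_zero_f(self):
        vals = [5.0] * 12
        g = ["a"] * 6 + ["b"] * 6
        t = (["x"] * 2 + ["y"] * 2 + ["z"] * 2) * 2
        tab = two_way_anova(vals, g, t)
        assert tab.effects["group"]["F"] == pytest.approx(0.0, abs=1e-20)
        assert tab.effects["test"]["F"] == pytest.approx(0.0, abs=1e-20)

    def test_hand_computed_fixture(self):
        # balanced 2x3 with n=2 per cell; classical SS decomposition by hand
        data = {
            ("a", "x"): [1.0, 2.0], ("a", "y"): [2.0, 4.0], ("a", "z"): [5.0, 5.0],
            ("b", "x"): [2.0, 3.0], ("b", "y"): [4.0, 6.0], ("b", "z"): [7.0, 9.0],
        }
        vals, gs, ts = [], [], []
        for (g, t), vv in data.items():
            vals += vv
            gs += [g, g]
            ts += [t, t]
        vals = np.array(vals)
        grand = vals.mean()
        cell_means = {k: np.mean(v) for k, v in data.items()}
        gm = {g: np.mean([cell_means[(g, t)] for t in "xyz"]) for g in "ab"}
        tm = {t: np.mean([cell_means[(g, t)] for g in "ab"]) for t in "xyz"}
        ss_a = 6 * sum((m - grand) ** 2 for m in gm.values())
        ss_b = 4 * sum((m - grand) ** 2 for m in tm.values())
        ss_ab = 2 * sum(
            (cell_means[(g, t)] - gm[g] - tm[t] + grand) ** 2
            for g in "ab" for t in "xyz"
        )
        ss_err = sum(
            (v - cell_means[k]) ** 2 for k, vv in data.items() for v in vv
        )
        tab = two_way_anova(vals, gs, ts)
        assert tab.effects["group"]["sum_sq"] == pytest.approx(ss_a)
        assert tab.effects["test"]["sum_sq"] == pytest.approx(ss_b)
        assert tab.effects["interaction"]["sum_sq"] == pytest.approx(ss_ab)
        assert tab.effects["error"]["sum_sq"] == pytest.approx(ss_err)
        # SS decomposition adds to total in the balanced case
        total = np.sum((vals - grand) ** 2)
        parts = sum(tab.effects[k]["sum_sq"] for k in ("group", "test", "interaction", "error"))
        assert parts == pytest.approx(total, rel=1e-9)

    def test_degrees_of_freedom_2x3(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(size=168)
        g = np.repeat(["a", "b"], 84)
        t = np.tile(np.repeat(["x", "y", "z"], 28), 2)
        tab = two_way_anova(vals, g, t)
        assert tab.effects["group"]["df"] == 1
        assert tab.effects["test"]["df"] == 2
        assert tab.effects["interaction"]["df"] == 2
        assert tab.effects["error"]["df"] == 162
        assert len(tab.posthoc) == 3

    def test_single_level_rejected(self):
        with pytest.raises(ValueError):
            two_way_anova([1, 2, 3], ["a", "a", "a"], ["x", "y", "z"])

    def test_summary_variant_equals_data_variant(self):
        rng = np.random.default_rng(8)
        cells = {}
        vals, gs, ts = [], [], []
        for g in ("a", "b"):
            for t in ("x", "y", "z"):
                v = rng.normal(loc=rng.uniform(-1, 1), size=10)
                cells[(g, t)] = (float(v.mean()), float(v.std(ddof=1)), 10)
                vals += list(v)
                gs += [g] * 10
                ts += [t] * 10
        a = two_way_anova(vals, gs, ts)
        b = two_way_anova_from_summary(cells)
        for k in ("group", "test", "interaction"):
            assert b.effects[k]["F"] == pytest.approx(a.effects[k]["F"], rel=1e-9)


class TestWmwPower:
    def test_null_equals_alpha(self):
        assert wmw_power(0.0, 1.0, 0.0, 1.0, 28) == pytest.approx(0.05, abs=1e-12)

    def test_monotone_in_effect_and_n(self):
        p1 = wmw_power(0.0, 1.0, 0.5, 1.0, 20)
        p2 = wmw_power(0.0, 1.0, 1.0, 1.0, 20)
        p3 = wmw_power(0.0, 1.0, 1.0, 1.0, 40)
        assert p1 < p2 < p3

    def test_stereo_4c_power(self):
        # printed group summaries: 6.3 +- 1.0 vs 5.5 +- 0.7, n = 28/group
        assert 100 * wmw_power(6.3, 1.0, 5.5, 0.7, 28) == pytest.approx(91.4, abs=0.05)

    def test_masking_weight_power(self):
        assert 100 * wmw_power(-7.9, 3.6, -11.8, 2.3, 28) == pytest.approx(99.6, abs=0.05)
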