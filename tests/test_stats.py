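"""Unit tests for the statistical procedures."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from optosilence import stats
from oracles import (fisher_exact_enum, holm_stepdown, mannwhitney_exact_enum,
                     srh_oracle)


class TestChi2:
    @pytest.mark.parametrize("table,expected", [
        ((14, 59, 2, 68), 9.58),
        ((21, 79, 51, 47), 20.61),
        ((29, 71, 60, 38), 20.77),
        ((43, 57, 60, 38), 6.59),
        ((35, 65, 55, 43), 8.91),
    ])
    def test_published_unit_count_comparisons(self, table, expected):
        """Pearson chi-square without continuity correction on the unit
        count tables reproduces the published statistics to 2 decimals."""
        res = stats.chi2_2x2(*table)
        assert res.statistic == pytest.approx(expected, abs=0.005)
        assert res.df == 1

    def test_independence_gives_zero(self):
        assert stats.chi2_2x2(10, 10, 10, 10).statistic == pytest.approx(0.0)

    def test_matches_closed_form(self, rng):
        for _ in range(20):
            a, b, c, d = rng.integers(1, 50, size=4)
            n = a + b + c + d
            expect = n * (a * d - b * c) ** 2 / \
                ((a + b) * (c + d) * (a + c) * (b + d))
            assert stats.chi2_2x2(a, b, c, d).statistic == \
                pytest.approx(expect)

    def test_zero_cell_rejected(self):
        with pytest.raises(ValueError, match="fisher"):
            stats.chi2_2x2(0, 10, 5, 5)


class TestFisher:
    def test_identical_margins(self):
        assert stats.fisher_exact_2x2(0, 10, 0, 10).p_value == pytest.approx(1.0)

    def test_diagonal_table(self):
        # only the two extreme tables are as improbable as the observed one
        assert stats.fisher_exact_2x2(5, 0, 0, 5).p_value == \
            pytest.approx(2 / 252)

    def test_matches_enumeration(self, rng):
        for _ in range(30):
            a, b, c, d = rng.integers(0, 12, size=4)
            if (a + b == 0) or (c + d == 0):
                continue
            assert stats.fisher_exact_2x2(a, b, c, d).p_value == \
                pytest.approx(fisher_exact_enum(a, b, c, d), rel=1e-9)


class TestMannWhitney:
    def test_exact_matches_enumeration(self, rng):
        for n1, n2 in [(4, 4), (5, 7), (8, 8), (3, 8)]:
            for _ in range(3):
                x = rng.permutation(100)[:n1 + n2]
                res = stats.mann_whitney_u(x[:n1], x[n1:], mode="exact")
                u, p = mannwhitney_exact_enum(x[:n1], x[n1:])
                assert res.statistic == u
                assert res.p_value == pytest.approx(p, rel=1e-12)

    def test_u19_one_sided_normal_cc(self):
        """U = 19 with n1 = n2 = 8 under the one-sided continuity-corrected
        normal approximation gives p ~ 0.09."""
        x = [85, 86, 15, 16, 17, 1, 2, 3]
        y = [10, 20, 30, 40, 50, 60, 70, 80]
        res = stats.mann_whitney_u(x, y, sidedness="less", mode="normal_cc")
        assert res.statistic == 19
        assert res.p_value == pytest.approx(0.0947, abs=0.005)

    def test_balanced_u_is_symmetric(self):
        x = [1, 4, 5, 8]
        y = [2, 3, 6, 7]
        res = stats.mann_whitney_u(x, y, mode="exact")
        assert res.statistic == 8  # n1*n2/2
        assert res.p_value == pytest.approx(1.0, abs=0.05)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            stats.mann_whitney_u([], [1, 2])


class TestKruskal:
    def test_identical_groups_degenerate(self):
        res = stats.kruskal_wallis([3, 3, 3], [3, 3, 3])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_two_groups_is_squared_rank_z(self, rng):
        """For k = 2 without ties, H equals the squared (non-cc) normal
        z-score of the Mann-Whitney U statistic."""
        perm = rng.permutation(50).astype(float)
        x, y = perm[:8], perm[8:20]
        h = stats.kruskal_wallis(x, y).statistic
        n1, n2 = len(x), len(y)
        u1 = sum(1 for a in x for b in y if a > b)
        z = (u1 - n1 * n2 / 2) / np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12)
        assert h == pytest.approx(z ** 2, rel=1e-9)

    def test_matches_rank_formula(self, rng):
        groups = [rng.normal(size=n) for n in (5, 8, 6)]
        pooled = np.concatenate(groups)
        from scipy.stats import rankdata
        ranks = rankdata(pooled)
        n = pooled.size
        idx = np.cumsum([0] + [len(g) for g in groups])
        h = 12 / (n * (n + 1)) * sum(
            ranks[a:b].sum() ** 2 / (b - a)
            for a, b in zip(idx[:-1], idx[1:])) - 3 * (n + 1)
        assert stats.kruskal_wallis(*groups).statistic == \
            pytest.approx(h, rel=1e-9)


class TestScheirerRayHare:
    def test_matches_rank_anova_oracle(self, rng):
        """H for both main effects and the interaction agrees with an
        independent OLS rank-ANOVA computation to 1e-9."""
        for _ in range(5):
            n_per = 6
            fa = np.repeat(["a1", "a2"], 2 * n_per)
            fb = np.tile(np.repeat(["b1", "b2"], n_per), 2)
            v = rng.normal(size=fa.size)
            ours = stats.scheirer_ray_hare(v, fa, fb)
            ref = srh_oracle(v, fa, fb)
            for key in ("A", "B", "interaction"):
                assert ours[key].statistic == pytest.approx(ref[key], abs=1e-9)

    def test_strong_effect_detected(self, rng):
        fa = np.repeat(["x", "y"], 20)
        fb = np.tile(np.repeat(["u", "v"], 10), 2)
        v = rng.normal(size=40) + np.where(fb == "v", 50.0, 0.0)
        out = stats.scheirer_ray_hare(v, fa, fb)
        assert out["B"].p_value < 1e-4
        assert out["A"].p_value > 0.05

    def test_empty_cell_rejected(self, rng):
        fa = ["a", "a", "b", "b"]
        fb = ["u", "u", "u", "u"]
        fb[-1] = "v"  # cell (a, v) empty
        with pytest.raises(ValueError, match="empty cell"):
            stats.scheirer_ray_hare(rng.normal(size=4), fa, fb)


class TestPairedT:
    def test_identical_gives_p1(self):
        res = stats.paired_t([1, 2, 3], [1, 2, 3])
        assert res.p_value == 1.0

    def test_zero_variance_nonzero_mean(self):
        res = stats.paired_t([2, 3, 4], [1, 2, 3])
        assert res.p_value == 0.0
        assert "degenerate" in res.notes

    def test_matches_textbook_formula(self, rng):
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        d = x - y
        t = d.mean() / (d.std(ddof=1) / np.sqrt(12))
        from scipy.stats import t as tdist
        p = 2 * tdist.sf(abs(t), 11)
        res = stats.paired_t(x, y)
        assert res.statistic == pytest.approx(t, rel=1e-12)
        assert res.p_value == pytest.approx(p, rel=1e-12)

    def test_sign_antisymmetry(self, rng):
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        assert stats.paired_t(x, y).statistic == \
            pytest.approx(-stats.paired_t(y, x).statistic)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            stats.paired_t([1, 2], [1, 2, 3])


class TestRmAnova:
    def test_identical_conditions(self, rng):
        base = rng.normal(size=(8, 1))
        m = np.tile(base, (1, 4)) + rng.normal(scale=1.0, size=(8, 4))
        m_same = np.tile(m[:, :1], (1, 4))
        res = stats.rm_anova_oneway(m_same)
        assert res.statistic == pytest.approx(0.0, abs=1e-20)

    def test_subject_offset_invariance(self, rng):
        m = rng.normal(size=(10, 3))
        offsets = rng.normal(scale=100, size=(10, 1))
        f1 = stats.rm_anova_oneway(m).statistic
        f2 = stats.rm_anova_oneway(m + offsets).statistic
        assert f1 == pytest.approx(f2, rel=1e-9)

    def test_matches_anovarm(self, rng):
        """Cross-check against statsmodels AnovaRM on long-format data."""
        import pandas as pd
        from statsmodels.stats.anova import AnovaRM

        m = rng.normal(size=(9, 4)) + np.arange(4)
        long = pd.DataFrame(
            [{"subject": i, "cond": j, "value": m[i, j]}
             for i in range(9) for j in range(4)])
        ref = AnovaRM(long, "value", "subject", within=["cond"]).fit()
        res = stats.rm_anova_oneway(m)
        assert res.statistic == pytest.approx(
            float(ref.anova_table["F Value"].iloc[0]), rel=1e-9)
        assert res.df == (3, 24)

    def test_missing_cells_rejected(self):
        m = np.array([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(ValueError):
            stats.rm_anova_oneway(m)


class TestHolm:
    def test_published_adjusted_pair(self):
        """The two published corrected p-values are consistent with the
        Holm step-down factors (x4 for the smallest of four raw p, x3 for
        the second smallest) applied to the recomputed raw chi-square p."""
        from scipy.stats import chi2 as chi2_dist
        raw = sorted(chi2_dist.sf(s, 1) for s in (20.608885, 20.770496,
                                                  6.586295, 8.906633))
        assert 4 * raw[0] == pytest.approx(2.07e-5, rel=0.02)
        assert 3 * raw[1] == pytest.approx(1.69e-5, rel=0.02)
        # the full (monotonicity-enforced) adjustment never undercuts the
        # step factors
        adj, _ = stats.holm_bonferroni(raw)
        assert np.all(np.sort(adj) >= [4 * raw[0], 3 * raw[1],
                                       2 * raw[2], 1 * raw[3]])

    def test_single_p_unchanged(self):
        adj, rej = stats.holm_bonferroni([0.03])
        assert adj[0] == pytest.approx(0.03)
        assert rej[0]

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=12))
    def test_matches_stepdown_oracle(self, ps):
        adj, _ = stats.holm_bonferroni(ps)
        assert np.allclose(adj, holm_stepdown(ps), atol=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=12))
    def test_never_below_raw(self, ps):
        adj, _ = stats.holm_bonferroni(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-15)
        assert np.all(adj <= 1.0)
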