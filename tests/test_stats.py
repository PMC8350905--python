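import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from organoid_ephys.stats import (GroupSample, anova_tukey, auto_compare,
                                  holm_sidak_adjust, kinetic_compare,
                                  kruskal_dunn, mann_whitney, rout_outliers,
                                  star_code, welch_t)

# ---------------------------------------------------------------------------
# independent oracles (closed-form / alternative-library recomputation)
# ---------------------------------------------------------------------------


def oracle_welch(a, b):
    na, nb = len(a), len(b)
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    se2 = va / na + vb / nb
    t = (np.mean(a) - np.mean(b)) / math.sqrt(se2)
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * sps.t.sf(abs(t), df)
    return t, df, p


def oracle_mannwhitney(a, b):
    """Asymptotic two-sided U with tie correction and continuity correction."""
    pooled = np.concatenate([a, b])
    ranks = pd.Series(pooled).rank().to_numpy()
    na, nb = len(a), len(b)
    u1 = ranks[:na].sum() - na * (na + 1) / 2
    mu = na * nb / 2
    counts = pd.Series(pooled).value_counts().to_numpy()
    tie = (counts ** 3 - counts).sum() / ((na + nb) * (na + nb - 1))
    sd = math.sqrt(na * nb / 12 * (na + nb + 1 - tie))
    z = (abs(u1 - mu) - 0.5) / sd
    p = math.erfc(z / math.sqrt(2))
    return u1, min(p, 1.0)


def oracle_anova_f(groups):
    all_v = np.concatenate(groups)
    grand = all_v.mean()
    ssb = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ssw = sum(((g - np.mean(g)) ** 2).sum() for g in groups)
    dfb, dfw = len(groups) - 1, all_v.size - len(groups)
    f = (ssb / dfb) / (ssw / dfw)
    return f, sps.f.sf(f, dfb, dfw)


def oracle_kruskal_h(groups):
    pooled = np.concatenate(groups)
    ranks = pd.Series(pooled).rank().to_numpy()
    n = pooled.size
    start, h = 0, 0.0
    for g in groups:
        r = ranks[start:start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12 / (n * (n + 1)) * h - 3 * (n + 1)
    counts = pd.Series(pooled).value_counts().to_numpy()
    h /= 1 - (counts ** 3 - counts).sum() / (n ** 3 - n)
    return h, sps.chi2.sf(h, len(groups) - 1)


def oracle_dunn_p(groups):
    """Dunn z via pandas ranks + erfc, Bonferroni-adjusted."""
    pooled = np.concatenate(groups)
    ranks = pd.Series(pooled).rank().to_numpy()
    n = pooled.size
    counts = pd.Series(pooled).value_counts().to_numpy()
    tie = (counts ** 3 - counts).sum() / (12 * (n - 1))
    var = n * (n + 1) / 12 - tie
    means, start = [], 0
    for g in groups:
        means.append(ranks[start:start + len(g)].mean())
        start += len(g)
    m = len(groups) * (len(groups) - 1) // 2
    out = {}
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            z = (means[i] - means[j]) / math.sqrt(
                var * (1 / len(groups[i]) + 1 / len(groups[j])))
            p_raw = math.erfc(abs(z) / math.sqrt(2))
            out[(i, j)] = (z, min(1.0, p_raw * m))
    return out


def fixture_bank(n_cases=20, seed=123):
    """Random 2- and 3-group fixtures with assorted sizes and scales."""
    rng = np.random.default_rng(seed)
    cases = []
    for i in range(n_cases):
        k = 2 if i % 2 == 0 else 3
        groups = [rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3),
                             rng.integers(5, 20)) for _ in range(k)]
        cases.append(groups)
    return cases


# ---------------------------------------------------------------------------
# oracle-equivalence tests
# ---------------------------------------------------------------------------


class TestOracleEquivalence:
    @pytest.mark.parametrize("case", fixture_bank(), ids=range(20))
    def test_all_tests_match_reference(self, case):
        if len(case) == 2:
            a, b = case
            t, df, p = welch_t(a, b)
            to, dfo, po = oracle_welch(a, b)
            assert abs(t - to) < 1e-8 and abs(df - dfo) < 1e-8 and abs(p - po) < 1e-8
            u, p = mann_whitney(a, b)
            uo, po = oracle_mannwhitney(a, b)
            assert abs(u - uo) < 1e-8 and abs(p - po) < 1e-8
        else:
            rep = anova_tukey([GroupSample(f"g{i}", g)
                               for i, g in enumerate(case)])
            f_o, p_o = oracle_anova_f(case)
            assert abs(rep.omnibus["F"] - f_o) < 1e-8
            assert abs(rep.omnibus["p"] - p_o) < 1e-8
            # Tukey p-values against statsmodels
            sm = pytest.importorskip("statsmodels.stats.multicomp")
            values = np.concatenate(case)
            labels = np.concatenate([[f"g{i}"] * len(g)
                                     for i, g in enumerate(case)])
            ref = sm.pairwise_tukeyhsd(values, labels)
            pairs = [(str(r[0]), str(r[1])) for r in ref.summary().data[1:]]
            ref_p = dict(zip(pairs, np.asarray(ref.pvalues, float)))
            for _, row in rep.comparisons.iterrows():
                key = (row.group_a, row.group_b)
                ref_val = ref_p.get(key, ref_p.get(key[::-1]))
                assert abs(row.p_adj - ref_val) < 1e-8

            rep_k = kruskal_dunn([GroupSample(f"g{i}", g)
                                  for i, g in enumerate(case)])
            h_o, hp_o = oracle_kruskal_h(case)
            assert abs(rep_k.omnibus["H"] - h_o) < 1e-8
            assert abs(rep_k.omnibus["p"] - hp_o) < 1e-8
            dunn = oracle_dunn_p(case)
            for idx, (_, row) in enumerate(rep_k.comparisons.iterrows()):
                pairs = list(dunn.values())
                z_o, p_o = pairs[idx]
                assert abs(row.statistic - z_o) < 1e-8
                assert abs(row.p_adj - p_o) < 1e-8

    def test_holm_sidak_matches_statsmodels(self):
        mt = pytest.importorskip("statsmodels.stats.multitest")
        rng = np.random.default_rng(5)
        for _ in range(10):
            p = rng.uniform(0, 1, rng.integers(1, 12))
            ours = holm_sidak_adjust(p)
            ref = mt.multipletests(p, method="holm-sidak")[1]
            assert np.allclose(ours, ref, atol=1e-12)


class TestElementaryBehavior:
    def test_identical_groups_null_result(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        t, df, p = welch_t(a, a.copy())
        assert t == 0.0 and p == 1.0

    def test_three_equal_groups_anova_null(self):
        g = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        rep = anova_tukey([GroupSample("a", g), GroupSample("b", g.copy()),
                           GroupSample("c", g.copy())])
        assert rep.omnibus["F"] == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(rep.comparisons["p_adj"], 1.0, atol=1e-9)

    def test_welch_antisymmetric_under_swap(self, rng):
        a, b = rng.normal(0, 1, 10), rng.normal(1, 2, 12)
        t1, _, p1 = welch_t(a, b)
        t2, _, p2 = welch_t(b, a)
        assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="nonparametric"):
            welch_t(np.ones(5), np.ones(5))


class TestHolmSidak:
    def test_degenerate_families(self):
        assert np.allclose(holm_sidak_adjust([1.0, 1.0, 1.0]), 1.0)
        assert holm_sidak_adjust([0.2])[0] == pytest.approx(0.2)

    def test_brute_force_stepdown(self):
        p = [0.01, 0.02, 0.2]
        expected = [1 - (1 - 0.01) ** 3,
                    max(1 - (1 - 0.01) ** 3, 1 - (1 - 0.02) ** 2),
                    max(1 - (1 - 0.01) ** 3, 1 - (1 - 0.02) ** 2, 0.2)]
        assert np.allclose(holm_sidak_adjust(p), expected)

    def test_adjusted_never_below_raw(self, rng):
        p = rng.uniform(0, 1, 15)
        assert np.all(holm_sidak_adjust(p) >= p)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            holm_sidak_adjust([0.5, 1.2])


class TestRout:
    def test_gross_outlier_removed(self):
        values = np.array([1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 100.0])
        kept, removed = rout_outliers(values)
        assert removed.tolist() == [100.0]
        assert len(kept) == 10

    def test_clean_gaussian_rarely_flagged(self):
        flags = 0
        for seed in range(50):
            x = np.random.default_rng(seed).normal(0, 1, 20)
            _, removed = rout_outliers(x)
            flags += removed.size > 0
        assert flags / 50 <= 0.05

    def test_minimum_n(self):
        with pytest.raises(ValueError, match="n >= 3"):
            rout_outliers(np.array([1.0, 2.0]))


class TestDecisionTree:
    def test_gaussian_two_groups_routes_to_welch(self, rng):
        a = GroupSample("wt", rng.normal(0, 1, 14))
        b = GroupSample("ko", rng.normal(1, 1, 14))
        rep = auto_compare([a, b])
        assert rep.test_name == "welch_t"
        assert all(p > 0.05 for p in rep.normality_p.values())

    def test_heavy_tailed_three_groups_routes_to_kruskal(self, rng):
        groups = [GroupSample(f"g{i}", rng.standard_cauchy(20) ** 3)
                  for i in range(3)]
        rep = auto_compare(groups)
        assert rep.test_name == "kruskal_dunn"

    def test_two_groups_nonnormal_routes_to_mannwhitney(self, rng):
        a = GroupSample("a", np.exp(rng.normal(0, 2, 25)))
        b = GroupSample("b", np.exp(rng.normal(0.5, 2, 25)))
        rep = auto_compare([a, b])
        assert rep.test_name == "mann_whitney"

    def test_degenerate_inputs_rejected(self, rng):
        one = [GroupSample("only", rng.normal(0, 1, 5))]
        with pytest.raises(ValueError, match="two groups"):
            auto_compare(one)
        small = [GroupSample("a", np.array([1.0, 2.0])),
                 GroupSample("b", rng.normal(0, 1, 5))]
        with pytest.raises(ValueError, match="n="):
            auto_compare(small)

    def test_rout_screen_reports_removed_points(self, rng):
        a = GroupSample("a", np.append(rng.normal(0, 1, 15), 40.0))
        b = GroupSample("b", rng.normal(0.5, 1, 15))
        rep = auto_compare([a, b], rout_q=0.01)
        assert rep.outliers_removed == {"a": [40.0]}

    def test_welch_branch_level_under_null(self):
        """Type-I error of the tree at alpha=0.05 on Gaussian nulls."""
        hits = 0
        reps = 400
        for seed in range(reps):
            rng = np.random.default_rng(10_000 + seed)
            rep = auto_compare([GroupSample("a", rng.normal(0, 1, 14)),
                                GroupSample("b", rng.normal(0, 1, 14))])
            hits += rep.comparisons["p_adj"].iloc[0] <= 0.05
        assert 0.02 <= hits / reps <= 0.08

    def test_kinetic_family_adjusted(self, rng):
        pairs = [(GroupSample("wt", rng.normal(0, 1, 6)),
                  GroupSample("ko", rng.normal(3, 1, 6))) for _ in range(4)]
        rep = kinetic_compare(pairs, labels=["w6", "w10", "w15", "w24"])
        assert rep.test_name == "multiple_t_holm_sidak"
        assert len(rep.comparisons) == 4
        assert np.all(rep.comparisons["p_adj"] >= rep.comparisons["p_raw"] - 1e-15)


class TestStarCodes:
    @pytest.mark.parametrize("p,stars", [
        (0.2, "n.s."), (0.05, "*"), (0.02, "*"), (0.01, "**"),
        (0.0005, "***"), (0.00005, "****"),
    ])
    def test_cutoffs(self, p, stars):
        assert star_code(p) == stars
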