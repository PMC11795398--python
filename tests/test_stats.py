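"""Nonparametric group tests, BH adjustment, Welch's t, proportions."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate
from scipy.stats import rankdata

from flowpheno.exceptions import ConfigError
from flowpheno.stats import (bh_adjust, cell_proportions, compare_groups,
                             ks_two_sample, welch_t, welch_t_values,
                             wilcoxon_rank_sum)
from flowpheno.synthetic import _three_population_config, simulate_proportion_table

# --------------------------------------------------------------------------
# independent oracles


def wrs_enumeration_p(x, y):
    """Exact two-sided WRS p by enumerating all group assignments."""
    pooled = np.concatenate([x, y])
    n1, n = len(x), len(pooled)
    ranks = rankdata(pooled)
    obs_u = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    us = []
    for comb in itertools.combinations(range(n), n1):
        r1 = ranks[list(comb)].sum()
        us.append(r1 - n1 * (n1 + 1) / 2)
    us = np.asarray(us)
    lo = np.mean(us <= obs_u)
    hi = np.mean(us >= obs_u)
    return min(1.0, 2.0 * min(lo, hi))


def ks_enumeration_p(x, y):
    """Exact two-sided KS p by enumerating all group assignments."""
    pooled = np.sort(np.concatenate([x, y]))
    n1, n = len(x), len(x) + len(y)

    def ks_d(a, b):
        a, b = np.sort(a), np.sort(b)
        fa = np.searchsorted(a, pooled, side="right") / len(a)
        fb = np.searchsorted(b, pooled, side="right") / len(b)
        return np.max(np.abs(fa - fb))

    obs = ks_d(np.asarray(x), np.asarray(y))
    ds = []
    for comb in itertools.combinations(range(n), n1):
        a = pooled[list(comb)]
        b = np.delete(pooled, list(comb))
        ds.append(ks_d(a, b))
    return float(np.mean(np.asarray(ds) >= obs - 1e-12))


def bh_stepup_oracle(p):
    """Direct implementation of the BH step-up definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    running = np.inf
    for i in range(m - 1, -1, -1):
        running = min(running, m * p[order[i]] / (i + 1))
        q_sorted[i] = min(running, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def t_tail_quadrature(t, df):
    """Two-sided t-distribution tail by numerical integration of the pdf."""
    const = math.gamma((df + 1) / 2) / (math.sqrt(df * math.pi)
                                        * math.gamma(df / 2))

    def pdf(u):
        return const * (1 + u * u / df) ** (-(df + 1) / 2)

    tail, _ = integrate.quad(pdf, abs(t), np.inf)
    return min(1.0, 2.0 * tail)


# --------------------------------------------------------------------------


class TestWilcoxonRankSum:
    def test_textbook_example(self):
        res = wilcoxon_rank_sum([1, 2], [3, 4])
        assert res.p_value == pytest.approx(2 / 6, abs=1e-12)
        assert res.statistic_name == "WRS U"

    def test_identical_groups_null(self):
        res = wilcoxon_rank_sum([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert res.statistic == pytest.approx(8.0)   # n1*n2/2
        assert res.p_value >= 0.99

    def test_agrees_with_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            pooled = rng.permutation(rng.uniform(0, 1, 8))
            x, y = pooled[:4], pooled[4:]
            res = wilcoxon_rank_sum(x, y)
            assert res.p_value == pytest.approx(wrs_enumeration_p(x, y),
                                                abs=1e-10)

    def test_empty_group_errors(self):
        with pytest.raises(ConfigError):
            wilcoxon_rank_sum([], [1.0])


class TestKolmogorovSmirnov:
    def test_identical_samples(self):
        res = ks_two_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_hand_computed_d(self):
        res = ks_two_sample([0.0, 1.0], [0.5, 1.5])
        assert res.statistic == pytest.approx(0.5)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(0, 1, 30), rng.normal(0.5, 1.2, 40)
        r1 = ks_two_sample(x, y)
        r2 = ks_two_sample(np.exp(x), np.exp(y))
        assert r1.statistic == pytest.approx(r2.statistic)
        assert r1.p_value == pytest.approx(r2.p_value)

    @pytest.mark.parametrize("n", [2, 3, 4])
    def test_agrees_with_enumeration_oracle(self, n):
        rng = np.random.default_rng(2)
        for _ in range(30):
            pooled = rng.permutation(rng.uniform(0, 1, 2 * n))
            x, y = pooled[:n], pooled[n:]
            res = ks_two_sample(x, y)
            assert res.p_value == pytest.approx(ks_enumeration_p(x, y),
                                                abs=1e-9)


class TestBenjaminiHochberg:
    def test_worked_example(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.123])[0] == pytest.approx(0.123)

    def test_agrees_with_stepup_definition_on_random_vectors(self):
        rng = np.random.default_rng(3)
        for _ in range(1000):
            p = rng.uniform(0, 1, rng.integers(1, 30))
            np.testing.assert_allclose(bh_adjust(p), bh_stepup_oracle(p),
                                       atol=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1,
                    max_size=40))
    def test_stepup_property(self, p):
        q = bh_adjust(p)
        assert np.all((q >= 0) & (q <= 1))
        np.testing.assert_allclose(q, bh_stepup_oracle(p), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ConfigError):
            bh_adjust([0.5, 1.2])


class TestWelch:
    def test_summary_statistics_blood_count_example(self):
        # printed summary statistics: mean 8.17 sd 1.30 n 25 vs 7.07 / 1.46 / 42
        res = welch_t(8.17, 1.30, 25, 7.07, 1.46, 42)
        assert res.p_value == pytest.approx(0.0023, abs=2e-4)
        assert res.direction == 1

    def test_identical_summaries(self):
        res = welch_t(5.0, 1.0, 10, 5.0, 1.0, 10)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_degenerate_zero_variance(self):
        assert welch_t(3.0, 0.0, 5, 3.0, 0.0, 5).p_value == 1.0
        with pytest.warns(UserWarning):
            assert welch_t(3.0, 0.0, 5, 4.0, 0.0, 5).p_value == 0.0

    def test_agrees_with_quadrature_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(25):
            m1, m2 = rng.normal(0, 2, 2)
            s1, s2 = rng.uniform(0.5, 3, 2)
            n1, n2 = rng.integers(3, 50, 2)
            res = welch_t(m1, s1, int(n1), m2, s2, int(n2))
            se2 = s1 ** 2 / n1 + s2 ** 2 / n2
            df = se2 ** 2 / ((s1 ** 2 / n1) ** 2 / (n1 - 1)
                             + (s2 ** 2 / n2) ** 2 / (n2 - 1))
            assert res.p_value == pytest.approx(
                t_tail_quadrature(res.statistic, df), abs=1e-8)

    def test_raw_value_overload_matches_summaries(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(0, 1, 20), rng.normal(0.7, 1.5, 25)
        a = welch_t_values(x, y)
        b = welch_t(x.mean(), x.std(ddof=1), 20, y.mean(), y.std(ddof=1), 25)
        assert a.p_value == pytest.approx(b.p_value)


class TestCellProportions:
    def _meta(self, sample_ids, groups=None):
        groups = groups or ["A"] * len(sample_ids)
        return pd.DataFrame({"sample_id": sample_ids,
                             "batch_id": ["b"] * len(sample_ids),
                             "group": groups})

    def test_simple_fraction(self):
        labels = ["CD4 T cell"] * 10 + ["other"] * 90
        meta = self._meta(["s1"] * 100)
        table = cell_proportions(labels, meta)
        row = table.set_index("cell_type").loc["CD4 T cell"]
        assert row["proportion"] == pytest.approx(0.10)

    def test_exhaustive_children_sum_to_one(self):
        rng = np.random.default_rng(6)
        labels = rng.choice(["a", "b", "c"], 300)
        meta = self._meta(list(np.repeat(["s1", "s2", "s3"], 100)))
        table = cell_proportions(labels, meta)
        sums = table.groupby("sample_id")["proportion"].sum()
        np.testing.assert_allclose(sums, 1.0, atol=1e-12)

    def test_nested_parent_denominator(self):
        # 40 CD4 T cells of which 10 CD62L-high, plus 60 others
        labels = (["CD62Lhi CD4"] * 10 + ["CD4 T cell"] * 30 + ["other"] * 60)
        meta = self._meta(["s1"] * 100)
        table = cell_proportions(labels, meta,
                                 parent_spec={"CD62Lhi CD4": "CD4 T cell"})
        row = table.set_index("cell_type").loc["CD62Lhi CD4"]
        assert row["parent_count"] == 40
        assert row["proportion"] == pytest.approx(10 / 40)
        # not relative to all 100 events
        assert row["proportion"] != pytest.approx(0.10)


class TestCompareGroups:
    def test_planted_shift_has_smallest_wrs_q(self):
        config = _three_population_config(
            99, samples_per_group={"A": 20, "B": 20},
            group_effects={"B": {"CD8_T": 1.5}})
        proportions = simulate_proportion_table(config)
        table = compare_groups(proportions, ("A", "B"))
        wrs = table[table["test"] == "wrs"].set_index("cell_type")
        assert wrs["q_value"].idxmin() == "CD8_T"
        assert wrs.loc["CD8_T", "q_value"] < 0.05

    def test_invariant_to_row_and_sample_order(self):
        config = _three_population_config(
            55, samples_per_group={"A": 8, "B": 8},
            group_effects={"B": {"CD4_T": 1.3}})
        proportions = simulate_proportion_table(config)
        shuffled = proportions.sample(frac=1.0, random_state=1)
        a = compare_groups(proportions, ("A", "B"))
        b = compare_groups(shuffled, ("A", "B"))
        pd.testing.assert_frame_equal(a, b)

    def test_insufficient_samples_flagged_and_excluded(self):
        proportions = pd.DataFrame({
            "sample_id": ["s1", "s2", "s3"],
            "group": ["A", "B", "B"],
            "parent": ["all"] * 3,
            "cell_type": ["t"] * 3,
            "count": [1, 2, 3],
            "parent_count": [10, 10, 10],
            "proportion": [0.1, 0.2, 0.3],
        })
        table = compare_groups(proportions, ("A", "B"))
        assert not table["tested"].any()
        assert table["q_value"].isna().all()

    def test_permuted_labels_give_uniform_p(self):
        # permuting group labels under the null must give uniform p-values
        config = _three_population_config(
            123, samples_per_group={"A": 20, "B": 20})
        proportions = simulate_proportion_table(config)
        base = proportions.drop_duplicates("sample_id")[
            ["sample_id", "group"]].reset_index(drop=True)
        rng = np.random.default_rng(7)
        pvals = []
        for _ in range(500):
            perm = dict(zip(base["sample_id"],
                            rng.permutation(base["group"].to_numpy())))
            shuffled = proportions.assign(
                group=proportions["sample_id"].map(perm))
            sub = shuffled[shuffled["cell_type"] == "CD4_T"]
            x = sub.loc[sub["group"] == "A", "proportion"]
            y = sub.loc[sub["group"] == "B", "proportion"]
            pvals.append(wilcoxon_rank_sum(x, y).p_value)
        from scipy.stats import kstest
        assert kstest(pvals, "uniform").pvalue > 0.01
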