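"""Nonparametric battery vs brute-force enumeration oracles."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from drg_t2map import (
    build_cohort_tables,
    categorical_test,
    ks_normality,
    mann_whitney_u,
    percent_difference,
    spearman_rho,
    wilcoxon_signed_rank,
)


# ---------------------------------------------------------------------------
# Enumeration oracles (independent of scipy)
# ---------------------------------------------------------------------------

def mw_exact_oracle(a, b):
    """Two-sided exact Mann-Whitney p by enumeration of group assignments."""
    a, b = list(a), list(b)
    pooled = a + b
    na = len(a)

    def u_stat(group_a, group_b):
        return sum(1 for x in group_a for y in group_b if x > y)

    u_obs = u_stat(a, b)
    mean_u = na * len(b) / 2.0
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), na):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        u = u_stat(ga, gb)
        total += 1
        if abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-12:
            count += 1
    return count / total


def wilcoxon_exact_oracle(d):
    """Two-sided exact signed-rank p by enumeration of sign patterns."""
    d = np.asarray([x for x in d if x != 0], dtype=float)
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    mean_w = ranks.sum() / 2.0
    n = len(d)
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = ranks[np.array(signs, dtype=bool)].sum()
        if abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-12:
            count += 1
    return count / 2**n


def fisher_exact_oracle(table):
    """Two-sided Fisher p: sum of hypergeometric probabilities <= observed."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x):
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    p_obs = prob(a)
    return sum(prob(x) for x in range(max(0, c1 - r2), min(r1, c1) + 1)
               if prob(x) <= p_obs * (1 + 1e-12))


# ---------------------------------------------------------------------------


class TestMannWhitney:
    def test_separated_groups_exact(self):
        r = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert r.statistic == 0.0 and r.p_value == pytest.approx(0.1, abs=1e-12)
        assert "exact" in r.method_detail

    def test_all_ties_asymptotic_p_one(self):
        r = mann_whitney_u([5, 5, 5], [5, 5, 5])
        assert r.p_value == 1.0 and "tie" in r.method_detail

    @pytest.mark.parametrize("seed", range(10))
    def test_exact_path_equals_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, rng.integers(3, 7))
        b = rng.normal(0.5, 1, rng.integers(3, 6))
        r = mann_whitney_u(a, b)
        assert r.p_value == pytest.approx(mw_exact_oracle(a, b), abs=1e-12)

    def test_asymptotic_close_to_exact(self):
        """Continuity-corrected normal approximation within 0.02 of exact at n=6+6."""
        rng = np.random.default_rng(1)
        for _ in range(100):
            a, b = rng.normal(0, 1, 6), rng.normal(0.3, 1, 6)
            exact = mann_whitney_u(a, b).p_value
            asym = sps.mannwhitneyu(a, b, method="asymptotic", use_continuity=True).pvalue
            assert abs(asym - exact) <= 0.02

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    def test_type_one_error_calibration(self):
        """Two-sided alpha 0.05 rejects 4-6% of null data at n = 20 vs 20."""
        rng = np.random.default_rng(2024)
        rejections = 0
        n_sim = 2000
        for _ in range(n_sim):
            a = rng.normal(0, 1, 20)
            b = rng.normal(0, 1, 20)
            rejections += mann_whitney_u(a, b).p_value <= 0.05
        assert 0.04 <= rejections / n_sim <= 0.06


class TestWilcoxon:
    def test_uniform_shift_extreme(self):
        a = np.arange(8.0)
        r = wilcoxon_signed_rank(a + 1, a)
        assert r.p_value == pytest.approx(2.0 / 2**8, abs=1e-12)

    def test_all_zero_degenerate(self):
        a = np.arange(6.0)
        r = wilcoxon_signed_rank(a, a)
        assert r.p_value == 1.0 and "degenerate" in r.flags

    @pytest.mark.parametrize("seed", range(8))
    def test_exact_path_equals_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 12))
        a = rng.normal(0, 1, n)
        b = a + rng.normal(0.3, 1, n)
        r = wilcoxon_signed_rank(a, b)
        assert r.p_value == pytest.approx(wilcoxon_exact_oracle(a - b), abs=1e-12)

    def test_asymptotic_close_to_exact_at_n12(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            d = rng.normal(0.2, 1, 12)
            exact = wilcoxon_signed_rank(d, np.zeros(12)).p_value
            asym = sps.wilcoxon(d, method="approx", correction=True).pvalue
            assert abs(asym - exact) <= 0.02

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1.0, 2.0], [1.0])


class TestCategorical:
    def test_balanced_table_chi2_zero(self):
        r = categorical_test([[10, 10], [10, 10]])
        assert r.statistic == 0.0 and r.p_value == 1.0
        assert r.test_name == "chi-squared"

    def test_diagonal_table_fisher(self):
        r = categorical_test([[5, 0], [0, 5]])
        assert r.test_name == "Fisher exact"
        assert r.p_value == pytest.approx(2.0 / 252.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_fisher_equals_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        t = rng.integers(0, 5, (2, 2))
        t[0, 0] += 1  # avoid fully empty margins
        r = categorical_test(t)
        if r.test_name == "Fisher exact":
            assert r.p_value == pytest.approx(fisher_exact_oracle(t), abs=1e-9)

    def test_large_table_uses_chi2_without_yates(self):
        t = [[30, 20], [25, 25]]
        r = categorical_test(t)
        chi2 = sps.chi2_contingency(np.array(t), correction=False)[0]
        assert r.test_name == "chi-squared" and r.statistic == pytest.approx(chi2)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            categorical_test([[1.5, 2.0], [3.0, 4.0]])
        with pytest.raises(ValueError):
            categorical_test([[-1, 2], [3, 4]])


class TestSpearman:
    def test_perfect_monotone(self):
        assert spearman_rho([1, 2, 3, 4], [10, 20, 30, 40]).statistic == pytest.approx(1.0)
        assert spearman_rho([1, 2, 3, 4], [40, 30, 20, 10]).statistic == pytest.approx(-1.0)

    def test_equals_rank_then_pearson_oracle_with_ties(self):
        rng = np.random.default_rng(3)
        x = rng.integers(0, 5, 30).astype(float)  # plenty of ties
        y = x + rng.integers(0, 3, 30)
        r = spearman_rho(x, y)
        rx, ry = sps.rankdata(x), sps.rankdata(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert r.statistic == pytest.approx(oracle, abs=1e-12)

    def test_zero_rank_variance_rejected(self):
        with pytest.raises(ValueError):
            spearman_rho([1, 1, 1, 1], [1, 2, 3, 4])


class TestKSNormality:
    def test_calibration_on_normal_and_lognormal(self):
        rng = np.random.default_rng(10)
        p_norm = [ks_normality(rng.normal(0, 1, 1000)).p_value for _ in range(100)]
        assert np.mean(np.array(p_norm) > 0.05) >= 0.90
        p_logn = [ks_normality(rng.lognormal(0, 1, 1000)).p_value for _ in range(20)]
        assert np.mean(np.array(p_logn) < 0.05) >= 0.99

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            ks_normality(np.full(10, 3.0))


class TestPercentDifference:
    @pytest.mark.parametrize(
        "a,b,expected",
        [(102.4, 93.6, 9.4), (96.8, 92.9, 4.2), (1323.9, 905.4, 46.2),
         (1342.1, 987.8, 35.9), (50.0, 50.0, 0.0)],
    )
    def test_signed_one_decimal(self, a, b, expected):
        assert percent_difference(a, b) == expected

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            percent_difference(1.0, 0.0)


@pytest.fixture(scope="module")
def subjects():
    from drg_t2map import CohortSpec, generate_cohort, average_readers, summarise_subjects

    subs, samples, _ = generate_cohort(CohortSpec(seed=4))
    summ = summarise_subjects(average_readers(samples))
    return summ.merge(subs, on="subject_id")


class TestCohortTables:
    def test_mutation_contrast_counts(self, subjects):
        table = build_cohort_tables(subjects, "mutation_class")
        row = table[table.variable == "drg_t2_ms"].iloc[0]
        assert "(" in row["classical"] and row["p_value"] <= 1.0
        # 18 vs 54: VUS excluded
        n = subjects.mutation_class.value_counts()
        assert n["classical"] == 18 and n["nonclassical"] == 54

    def test_medians_match_percentile_oracle(self, subjects):
        table = build_cohort_tables(subjects, "sex")
        males = subjects[subjects.sex == "male"]["drg_t2_ms"].to_numpy()
        med = float(np.percentile(np.sort(males), 50))
        row = table[table.variable == "drg_t2_ms"].iloc[0]
        assert row["male"].startswith(f"{med:.1f}")

    def test_constant_variable_p_one(self, subjects):
        df = subjects.copy()
        df["constant_var"] = 1.0
        table = build_cohort_tables(df, "sex", continuous=["constant_var"], categorical=[])
        assert table.iloc[0]["p_value"] == 1.0

    def test_empty_group_rejected(self, subjects):
        with pytest.raises(ValueError, match="empty"):
            build_cohort_tables(subjects[subjects.sex == "male"], "sex")
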