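"""Enrichment, dN/dS, G scores, and the statistical test wrappers."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from coreflex.stats import (
    CompartmentCounts,
    bootstrap_median_ci,
    dnds_ratio,
    enrichment_test,
    fisher_exact_one_tailed,
    gscores,
    mann_whitney,
    spearman_correlation,
    welch_t,
    wilcoxon_signed_rank,
)

L_CORE, L_FLEX = 1_944_921, 2_066_263


def binomial_two_sided_oracle(k: int, n: int, p0: float) -> float:
    """Minimum-likelihood two-sided p by full outcome enumeration."""
    probs = [math.comb(n, i) * p0**i * (1 - p0) ** (n - i) for i in range(n + 1)]
    pk = probs[k]
    return min(1.0, sum(p for p in probs if p <= pk * (1 + 1e-12)))


class TestEnrichment:
    @pytest.mark.parametrize(
        "core_n,flex_n,expected_or",
        [(123, 51, 2.41), (10, 10, 1.00), (2265, 2510, 0.90), (838, 860, 0.97)],
    )
    def test_count_ratio_reproduces_reference_rows(self, core_n, flex_n, expected_or):
        res = enrichment_test(CompartmentCounts(core_n, flex_n, L_CORE, L_FLEX))
        assert round(res.odds_ratio, 2) == expected_or

    def test_strong_core_excess_is_significant(self):
        res = enrichment_test(CompartmentCounts(123, 51, L_CORE, L_FLEX))
        assert res.p_value < 1e-8

    def test_equal_counts_at_even_lengths_give_p_one(self):
        res = enrichment_test(CompartmentCounts(7, 7, 1000, 1000))
        assert res.p0 == 0.5
        assert res.p_value == pytest.approx(1.0)

    def test_zero_flexible_count_flags_undefined_ratio(self):
        res = enrichment_test(CompartmentCounts(5, 0, 1000, 1000))
        assert not res.odds_ratio_defined
        assert math.isnan(res.odds_ratio)
        assert 0 <= res.p_value <= 1

    def test_p_matches_enumeration_oracle_for_small_tables(self):
        for core_n, flex_n in itertools.product(range(0, 7), range(0, 7)):
            if core_n + flex_n == 0:
                continue
            res = enrichment_test(CompartmentCounts(core_n, flex_n, L_CORE, L_FLEX))
            oracle = binomial_two_sided_oracle(core_n, core_n + flex_n, res.p0)
            assert res.p_value == pytest.approx(oracle, rel=1e-9)

    def test_rate_ratio_normalises_by_length(self):
        res = enrichment_test(CompartmentCounts(100, 100, 1000, 2000))
        assert res.rate_ratio == pytest.approx(2.0)


class TestDnDs:
    @pytest.mark.parametrize(
        "nonsyn,syn,expected",
        [(51, 10, 1.58), (2265, 838, 0.84), (2510, 860, 0.91)],
    )
    def test_reference_worked_examples(self, nonsyn, syn, expected):
        assert round(dnds_ratio(nonsyn, syn, 3.22).dnds, 2) == expected

    def test_core_nonmutator_value_within_rounding(self):
        assert dnds_ratio(123, 10, 3.22).dnds == pytest.approx(3.81, abs=0.02)

    def test_zero_nonsynonymous_gives_zero(self):
        assert dnds_ratio(0, 5, 3.22).dnds == 0.0

    def test_undefined_for_zero_synonymous(self):
        with pytest.raises(ValueError):
            dnds_ratio(10, 0, 3.22)

    def test_scale_invariance(self):
        assert dnds_ratio(30, 12, 3.22).dnds == pytest.approx(
            dnds_ratio(300, 120, 3.22).dnds
        )


class TestGScores:
    def test_zero_and_equal_conventions(self):
        out = {g.gene_id: g for g in gscores([("a", 100, 0), ("b", 100, 2)])}
        assert out["a"].G == 0.0
        # O == E gives G == 0
        even = gscores([("a", 100, 1), ("b", 100, 1)])
        assert all(g.G == pytest.approx(0.0) for g in even)

    def test_worked_value(self):
        """O=4, E=1 -> G = 8 ln 4."""
        out = gscores([("a", 100, 4), ("b", 300, 0)])
        g = next(x for x in out if x.gene_id == "a")
        assert g.E == pytest.approx(1.0)
        assert g.G == pytest.approx(8 * math.log(4))

    def test_expectations_sum_to_total(self):
        rng = np.random.default_rng(0)
        genes = [(f"g{i}", int(rng.integers(50, 5000)), int(rng.integers(0, 6)))
                 for i in range(200)]
        out = gscores(genes)
        T = sum(o for _, _, o in genes)
        assert sum(g.E for g in out) == pytest.approx(T, abs=1e-9)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            gscores([("a", 100, -1)])


class TestSpearman:
    def test_monotone_extremes(self):
        x = [1, 2, 3, 4, 5]
        assert spearman_correlation(x, [2, 4, 6, 8, 10]).statistic == pytest.approx(1.0)
        assert spearman_correlation(x, [10, 8, 6, 4, 2]).statistic == pytest.approx(-1.0)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            spearman_correlation([1, 1, 1], [1, 2, 3])

    def test_exact_p_matches_permutation_oracle_with_tie(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        y = [2.0, 1.0, 4.0, 4.0, 6.0, 5.0]
        res = spearman_correlation(x, y)
        r_obs = sps.spearmanr(x, y).statistic
        assert res.statistic == pytest.approx(r_obs)
        count = total = 0
        for perm in itertools.permutations(x):
            r = sps.spearmanr(perm, y).statistic
            total += 1
            if abs(r) >= abs(r_obs) - 1e-12:
                count += 1
        assert res.p_value == pytest.approx(count / total, abs=1e-9)


class TestMannWhitney:
    def test_identical_single_values_give_half(self):
        res = mann_whitney([5.0, 5.0], [5.0, 5.0, 5.0])
        assert res.statistic == pytest.approx(2 * 3 / 2)

    def test_fully_separated_groups(self):
        res = mann_whitney([1, 2, 3], [10, 11, 12])
        assert res.statistic == 0.0

    def test_u_matches_pair_counting_oracle(self):
        a = [3.1, 5.0, 1.2, 5.0, 9.9]
        b = [2.0, 5.0, 7.3, 0.4]
        res = mann_whitney(a, b)
        u = sum(
            1.0 if x > y else 0.5 if x == y else 0.0 for x in a for y in b
        )
        assert res.statistic == pytest.approx(u)
        assert res.extra["U_a"] + res.extra["U_b"] == pytest.approx(len(a) * len(b))

    def test_u_sum_identity_random_inputs(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            a = rng.integers(0, 5, size=rng.integers(1, 8)).astype(float)
            b = rng.integers(0, 5, size=rng.integers(1, 8)).astype(float)
            res = mann_whitney(a, b)
            assert res.extra["U_a"] + res.extra["U_b"] == pytest.approx(len(a) * len(b))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestWilcoxon:
    def test_mirrored_pairs_give_p_one(self):
        a = [1.0, -1.0, 2.0, -2.0]
        b = [0.0, 0.0, 0.0, 0.0]
        res = wilcoxon_signed_rank(a, b)
        assert res.p_value == pytest.approx(1.0)

    def test_exact_p_matches_sign_enumeration(self):
        a = np.array([2.0, 3.5, 1.0, 4.0, 6.0, 0.5])
        b = np.array([1.0, 3.0, 2.0, 1.5, 2.0, 1.0])
        res = wilcoxon_signed_rank(a, b)
        d = a - b
        ranks = sps.rankdata(np.abs(d))
        w_obs = min(ranks[d > 0].sum(), ranks[d < 0].sum())
        assert res.statistic == pytest.approx(w_obs)
        count = 0
        n = len(d)
        for mask in range(1 << n):
            plus = sum(ranks[i] for i in range(n) if mask >> i & 1)
            if min(plus, ranks.sum() - plus) <= w_obs + 1e-12:
                count += 1
        assert res.p_value == pytest.approx(count / (1 << n), abs=1e-9)

    def test_one_sided_extreme(self):
        a = list(range(1, 16))
        b = [0.0] * 15
        res = wilcoxon_signed_rank(a, b)
        assert res.statistic == 0.0  # all differences positive

    def test_all_zero_differences_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])


class TestWelch:
    def test_identical_groups(self):
        res = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_hand_computed_formula(self):
        a = np.array([1.0, 2.0, 3.0])
        b = a + 1.0
        res = welch_t(a, b)
        se = math.sqrt(a.var(ddof=1) / 3 + b.var(ddof=1) / 3)
        assert res.statistic == pytest.approx((a.mean() - b.mean()) / se)
        va, vb = a.var(ddof=1) / 3, b.var(ddof=1) / 3
        df = (va + vb) ** 2 / (va**2 / 2 + vb**2 / 2)
        assert res.extra["df"] == pytest.approx(df)

    def test_swap_antisymmetry(self):
        a, b = [1.0, 4.0, 2.0], [3.0, 8.0, 5.0, 6.0]
        r1, r2 = welch_t(a, b), welch_t(b, a)
        assert r1.statistic == pytest.approx(-r2.statistic)
        assert r1.p_value == pytest.approx(r2.p_value)


class TestFisher:
    def test_matches_hypergeometric_enumeration_family(self):
        for x in range(0, 41):
            table = [[2, 14], [x, 40 - x]]
            res = fisher_exact_one_tailed(table, alternative="less")
            # oracle: hypergeometric tail for the [0][0] cell
            M = 2 + 14 + x + (40 - x)
            n_row = 16
            K = 2 + x
            oracle = sum(
                sps.hypergeom.pmf(k, M, K, n_row) for k in range(0, 3)
            )
            assert res.p_value == pytest.approx(oracle, rel=1e-8)

    def test_proportional_rows_show_no_direction(self):
        res = fisher_exact_one_tailed([[10, 20], [20, 40]], alternative="greater")
        assert res.p_value >= 0.5

    def test_zero_margin_degenerates_to_one(self):
        res = fisher_exact_one_tailed([[0, 0], [3, 5]])
        assert res.p_value == 1.0
        assert res.extra["degenerate"]


class TestBootstrapMedianCI:
    def test_constant_vector_collapses(self):
        ci = bootstrap_median_ci([4.0] * 10, n_boot=500, seed=1)
        assert ci.ci_low == ci.median == ci.ci_high == 4.0

    def test_deterministic_per_seed(self):
        vals = np.random.default_rng(3).normal(size=50)
        c1 = bootstrap_median_ci(vals, n_boot=2000, seed=9)
        c2 = bootstrap_median_ci(vals, n_boot=2000, seed=9)
        assert (c1.ci_low, c1.median, c1.ci_high) == (c2.ci_low, c2.median, c2.ci_high)

    def test_coverage_of_true_median(self):
        """95% CI covers the true median in at least ~95% of replicates."""
        rng = np.random.default_rng(17)
        hits = 0
        n_rep = 200
        for i in range(n_rep):
            sample = rng.normal(loc=1.0, size=100)
            ci = bootstrap_median_ci(sample, n_boot=500, seed=i)
            hits += ci.ci_low <= 1.0 <= ci.ci_high
        assert hits / n_rep >= 0.88  # binomial slack below the nominal level

    def test_small_n_boot_warns(self):
        with pytest.warns(UserWarning):
            bootstrap_median_ci([1.0, 2.0, 3.0], n_boot=50, seed=0)
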