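"""Association functions against enumeration oracles and hand-computed values."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

import motifenrich as me
from motifenrich import association as A
from motifenrich.affinity import AffinityKind, SignalKind
from motifenrich.errors import (
    DegenerateDataError,
    EmptyPositiveSetError,
    InputError,
    PartitionError,
)

from conftest import make_mapped


def fisher_oracle(n, K, n1, k):
    """Brute-force hypergeometric upper tail over the whole support."""
    total = math.comb(n, n1)
    acc = 0
    for i in range(k, min(K, n1) + 1):
        acc += math.comb(K, i) * math.comb(n - K, n1 - i)
    return acc / total


class TestFisher:
    def test_closed_form_example(self):
        # n=10, K=4, n1=4, k=4: single table, p = 1/C(10,4)
        x = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0], float)
        d = make_mapped(x, x, AffinityKind.MC)
        res = A.fisher_association(d, t_x=1, t_y=1)
        assert res.p_value == pytest.approx(1 / 210, rel=1e-10)
        assert res.f_value == pytest.approx(210, rel=1e-10)

    def test_degenerate_table_p_one(self):
        d = make_mapped([0, 0, 0, 0], [1, 1, 0, 0], AffinityKind.MC)
        res = A.fisher_association(d, t_x=1, t_y=1)
        assert res.p_value == pytest.approx(1.0)
        assert res.f_value == pytest.approx(1.0)

    def test_matches_enumeration_on_sampled_tables(self):
        rng = np.random.default_rng(8)
        for _ in range(150):
            n = int(rng.integers(2, 16))
            K = int(rng.integers(0, n + 1))
            n1 = int(rng.integers(1, n + 1))
            x = np.zeros(n)
            x[:K] = 1
            rng.shuffle(x)
            y = np.zeros(n)
            y[rng.choice(n, size=n1, replace=False)] = 1
            k = int(np.sum(x[y == 1]))
            d = make_mapped(x, y, AffinityKind.MC)
            res = A.fisher_association(d, t_x=1, t_y=1)
            assert res.p_value == pytest.approx(fisher_oracle(n, K, n1, k), abs=1e-12)

    def test_p_nonincreasing_in_overlap(self):
        ps = [math.exp(A.hypergeom_logsf(k, 20, 8, 10)) for k in range(0, 9)]
        assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))

    def test_empty_positive_set_raises(self):
        d = make_mapped([1, 0], [0, 0], AffinityKind.MC)
        with pytest.raises(EmptyPositiveSetError):
            A.fisher_association(d, t_x=1, t_y=1)


def mhg_oracle(xc, n1, observed):
    """Enumerate all positive-set choices of size n1; tail on total count."""
    n = len(xc)
    hits = sum(
        1 for sub in itertools.combinations(range(n), n1)
        if sum(xc[i] for i in sub) >= observed
    )
    return hits / math.comb(n, n1)


class TestMhg:
    def test_c1_bit_identical_to_fisher(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            n = int(rng.integers(3, 14))
            x = rng.integers(0, 3, size=n).astype(float)
            y = (rng.random(n) < 0.4).astype(float)
            if y.sum() == 0:
                y[0] = 1
            d = make_mapped(np.minimum(x, 1), y, AffinityKind.MC)
            f = A.fisher_association(d, t_x=1, t_y=1)
            m = A.mhg_association(d, t_y=1, c=1)
            assert m.p_value == f.p_value  # bitwise identical
            assert m.f_value == f.f_value

    def test_matches_subset_enumeration(self):
        rng = np.random.default_rng(21)
        for _ in range(60):
            n = int(rng.integers(4, 13))
            xc = rng.integers(0, 4, size=n)
            n1 = int(rng.integers(1, n))
            y = np.zeros(n)
            y[rng.choice(n, size=n1, replace=False)] = 1
            d = make_mapped(xc.astype(float), y, AffinityKind.MC)
            res = A.mhg_association(d, t_y=1, c=2)
            capped = np.minimum(xc, 2)
            observed = int(capped[y == 1].sum())
            assert res.p_value == pytest.approx(
                mhg_oracle(capped, n1, observed), abs=1e-10
            )

    def test_unique_maximal_vector_single_table(self):
        # positives hold all the 2s: tail is that single category-count vector
        xc = np.array([2, 2, 1, 0, 0, 0], float)
        y = np.array([1, 1, 0, 0, 0, 0], float)
        d = make_mapped(xc, y, AffinityKind.MC)
        res = A.mhg_association(d, t_y=1, c=2)
        assert res.p_value == pytest.approx(1 / math.comb(6, 2), rel=1e-10)

    def test_non_integral_affinities_rejected(self):
        d = make_mapped([0.5, 1.2, 0.0], [1, 0, 0], AffinityKind.AMA)
        with pytest.raises(InputError):
            A.mhg_association(d, t_y=1, c=2)

    def test_general_c_grid_agrees_with_enumeration(self):
        rng = np.random.default_rng(31)
        for _ in range(15):
            n = int(rng.integers(5, 11))
            xc = rng.integers(0, 4, size=n)
            n1 = int(rng.integers(1, n))
            N = np.bincount(np.minimum(xc, 3), minlength=4)
            observed = int(np.minimum(xc, 3)[:n1].sum())
            p = math.exp(A.mhg_logsf(N, n1, observed))
            assert p == pytest.approx(mhg_oracle(np.minimum(xc, 3), n1, observed), abs=1e-10)


def ranksum_oracle(ranks, n1, W):
    """Enumerate all positive-set placements; lower tail on the rank-sum."""
    n = len(ranks)
    hits = sum(
        1 for sub in itertools.combinations(range(n), n1)
        if sum(ranks[i] for i in sub) <= W + 1e-9
    )
    return hits / math.comb(n, n1)


class TestRanksum:
    def test_top_two_positives_minimal_ranksum(self):
        d = make_mapped([4, 3, 2, 1], [1, 1, 0, 0])
        res = A.ranksum_association(d, t_y=1)
        assert res.details["W"] == pytest.approx(3.0)
        assert res.p_value == pytest.approx(1 / 6, rel=1e-12)

    def test_bottom_positives_p_one(self):
        d = make_mapped([4, 3, 2, 1], [0, 0, 1, 1])
        res = A.ranksum_association(d, t_y=1)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_enumeration_with_and_without_ties(self):
        rng = np.random.default_rng(17)
        for _ in range(80):
            n = int(rng.integers(3, 11))
            # half the trials use tied affinities
            x = (rng.integers(0, 4, size=n) if rng.random() < 0.5
                 else rng.random(n) * 10).astype(float)
            n1 = int(rng.integers(1, n))
            y = np.zeros(n)
            y[rng.choice(n, size=n1, replace=False)] = 1
            d = make_mapped(x, y)
            res = A.ranksum_association(d, t_y=1)
            ranks = stats.rankdata(-x, method="average")
            W = float(ranks[y == 1].sum())
            assert res.p_value == pytest.approx(ranksum_oracle(ranks, n1, W), abs=1e-10)

    def test_normal_approximation_close_at_n20(self):
        # random partitions at the exact/approximate switch point
        rng = np.random.default_rng(23)
        rels = []
        for _ in range(60):
            x = rng.random(20)
            n1 = int(rng.integers(3, 18))
            ranks = stats.rankdata(-x, method="average")
            pos = rng.choice(20, size=n1, replace=False)
            W = float(ranks[pos].sum())
            p_exact = math.exp(A.ranksum_logcdf_exact(2 * ranks, n1, 2 * W))
            p_norm = math.exp(A.ranksum_logcdf_normal(20, n1, W, 0.0))
            if p_exact >= 0.02:  # central regime; normal tails diverge as always
                rels.append(abs(p_norm - p_exact) / p_exact)
        assert rels and max(rels) < 0.10

    def test_one_sided_partition_rejected(self):
        d = make_mapped([1, 2, 3], [1, 1, 1])
        with pytest.raises(PartitionError):
            A.ranksum_association(d, t_y=1)


def clover_oracle(a):
    """Mean over subset sizes of the mean subset product."""
    P = len(a)
    by_size = []
    for j in range(1, P + 1):
        prods = [np.prod([a[i] for i in sub]) for sub in itertools.combinations(range(P), j)]
        by_size.append(np.mean(prods))
    return float(np.mean(by_size))


class TestClover:
    def test_all_ones_scores_one(self):
        d = make_mapped([1.0, 1.0, 1.0], [1, 1, 1])
        assert A.clover_association(d, t_y=1).f_value == pytest.approx(1.0)

    def test_two_point_hand_example(self):
        # a = (2, 4): size-1 mean 3, size-2 product 8 -> (3 + 8) / 2
        d = make_mapped([2.0, 4.0], [1, 1])
        assert A.clover_association(d, t_y=1).f_value == pytest.approx(5.5, rel=1e-12)

    def test_matches_subset_enumeration(self):
        rng = np.random.default_rng(3)
        for _ in range(40):
            P = int(rng.integers(1, 13))
            a = np.exp(rng.normal(0, 1.5, size=P))
            d = make_mapped(a, np.ones(P))
            res = A.clover_association(d, t_y=1)
            assert res.f_value == pytest.approx(clover_oracle(a), rel=1e-9)

    def test_symmetric_in_affinities(self):
        a = np.array([0.5, 2.0, 7.0, 1.3])
        d1 = make_mapped(a, np.ones(4))
        d2 = make_mapped(a[::-1], np.ones(4))
        assert A.clover_association(d1, t_y=1).log10_f == pytest.approx(
            A.clover_association(d2, t_y=1).log10_f, rel=1e-12
        )

    def test_log_domain_survives_huge_sets(self):
        # subset products overflow double range; log score must stay finite
        rng = np.random.default_rng(6)
        a = np.exp(rng.normal(2.0, 1.0, size=400))
        d = make_mapped(a, np.ones(400))
        res = A.clover_association(d, t_y=1)
        assert np.isfinite(res.log10_f)
        assert res.log10_f > 100  # far beyond double overflow as plain F

    def test_mc_affinity_rejected(self):
        d = make_mapped([1, 0, 2], [1, 1, 0], AffinityKind.MC)
        with pytest.raises(InputError):
            A.clover_association(d, t_y=1)


class TestLinearRegression:
    def test_exact_positive_fit_capped(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        d = make_mapped(x, 2 * x + 1)
        res = A.lr_association(d)
        assert res.f_value == pytest.approx(1e12)
        assert res.details["exact_fit"]

    def test_exact_negative_fit_sign(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        d = make_mapped(x, -2 * x + 1)
        res = A.lr_association(d)
        assert res.f_value == pytest.approx(-1e12)

    def test_hand_example_zero_slope(self):
        d = make_mapped([0.0, 1.0, 0.0, 1.0], [0.0, 0.0, 1.0, 1.0])
        res = A.lr_association(d)
        assert res.details["slope"] == pytest.approx(0.0)
        assert res.f_value == pytest.approx(4.0)

    def test_sign_flips_when_y_negated(self):
        rng = np.random.default_rng(10)
        x = rng.random(30)
        y = 3 * x + rng.normal(0, 0.3, 30)
        d = make_mapped(x, y)
        dn = make_mapped(x, -y)
        assert A.lr_association(d).f_value == pytest.approx(-A.lr_association(dn).f_value)

    def test_invariant_under_x_shift(self):
        rng = np.random.default_rng(11)
        x = rng.random(25)
        y = x + rng.normal(0, 0.2, 25)
        f1 = A.lr_association(make_mapped(x, y)).f_value
        f2 = A.lr_association(make_mapped(x + 5.0, y)).f_value
        assert f1 == pytest.approx(f2, rel=1e-9)

    def test_constant_x_rejected(self):
        d = make_mapped([1.0, 1.0, 1.0], [0.0, 1.0, 2.0])
        with pytest.raises(DegenerateDataError):
            A.lr_association(d)


class TestSpearman:
    def test_monotone_extremes(self):
        x = np.arange(10, dtype=float)
        assert A.spearman_association(make_mapped(x, x**3)).f_value == pytest.approx(1.0)
        assert A.spearman_association(make_mapped(x, -x)).f_value == pytest.approx(-1.0)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(14)
        x = rng.random(40)
        y = rng.random(40)
        base = A.spearman_association(make_mapped(x, y)).f_value
        assert A.spearman_association(make_mapped(np.exp(5 * x), y)).f_value == pytest.approx(base)
        assert A.spearman_association(make_mapped(x, np.log(y + 1))).f_value == pytest.approx(base)

    def test_constant_variable_rejected(self):
        with pytest.raises(DegenerateDataError):
            A.spearman_association(make_mapped([1, 1, 1], [1, 2, 3]))


class TestPValueContract:
    def test_reciprocal_pvalue_methods(self):
        rng = np.random.default_rng(30)
        for _ in range(30):
            n = int(rng.integers(4, 25))
            x = rng.integers(0, 3, size=n).astype(float)
            y = rng.random(n)
            t_y = float(np.quantile(y, 0.6))
            d = make_mapped(x, y, AffinityKind.MC)
            for res in (
                A.fisher_association(d, t_x=1, t_y=t_y),
                A.mhg_association(d, t_y=t_y, c=2),
            ):
                assert 0 < res.p_value <= 1
                assert res.f_value >= 1 - 1e-12
                assert res.log10_f == pytest.approx(-math.log10(res.p_value), abs=1e-9)


class TestPermutation:
    def test_observed_below_all_permutations_gives_p_one(self):
        # Y perfectly anti-correlated with X: every permutation scores >= observed
        x = np.arange(10, dtype=float)
        d = make_mapped(x, -x)
        p = A.permutation_pvalue(d, "lr", n_perm=99, seed=0)
        assert p == pytest.approx(1.0)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(44)
        d = make_mapped(rng.random(20), rng.random(20))
        p1 = A.permutation_pvalue(d, "spearman", n_perm=200, seed=9)
        p2 = A.permutation_pvalue(d, "spearman", n_perm=200, seed=9)
        assert p1 == p2

    def test_strong_association_detected(self):
        x = np.arange(50, dtype=float)
        d = make_mapped(x, 2 * x + np.sin(x))
        p = A.permutation_pvalue(d, "lr", n_perm=199, seed=1)
        assert p == pytest.approx(1 / 200)


class TestNegativeDirection:
    def test_fisher_negative_matches_depletion_enumeration(self):
        rng = np.random.default_rng(55)
        for _ in range(60):
            n = int(rng.integers(4, 14))
            x = rng.integers(0, 3, size=n).astype(float)
            n1 = int(rng.integers(1, n))
            y = np.zeros(n)
            y[rng.choice(n, size=n1, replace=False)] = 1
            d = make_mapped(x, y, AffinityKind.MC)
            res = A.compute_association(d, "fisher", t_x=1, t_y=1, direction="negative")
            K = int(np.sum(x >= 1))
            k = int(np.sum(x[y == 1] >= 1))
            # depletion: P(overlap <= k) enumerated over the support
            oracle = sum(
                math.comb(K, i) * math.comb(n - K, n1 - i)
                for i in range(max(0, K + n1 - n), k + 1)
            ) / math.comb(n, n1)
            assert res.p_value == pytest.approx(oracle, abs=1e-10)

    def test_ranksum_negative_matches_upper_tail_enumeration(self):
        rng = np.random.default_rng(56)
        for _ in range(40):
            n = int(rng.integers(4, 10))
            x = rng.random(n) * 5
            n1 = int(rng.integers(1, n))
            y = np.zeros(n)
            y[rng.choice(n, size=n1, replace=False)] = 1
            d = make_mapped(x, y)
            res = A.compute_association(d, "ranksum", t_y=1, direction="negative")
            ranks = stats.rankdata(-x, method="average")
            W = float(ranks[y == 1].sum())
            oracle = sum(
                1 for c in itertools.combinations(range(n), n1)
                if ranks[list(c)].sum() >= W - 1e-9
            ) / math.comb(n, n1)
            assert res.p_value == pytest.approx(oracle, abs=1e-10)

    def test_lr_and_spearman_negative_negate_f(self):
        rng = np.random.default_rng(57)
        x = rng.random(30)
        y = 2 * x + rng.normal(0, 0.2, 30)
        d = make_mapped(x, y)
        for method in ("lr", "spearman"):
            pos = A.compute_association(d, method).f_value
            neg = A.compute_association(d, method, direction="negative").f_value
            assert neg == pytest.approx(-pos)

    def test_clover_negative_rewards_depleted_positives(self):
        y = np.array([1, 1, 0, 0], float)
        depleted = make_mapped([0.1, 0.2, 3.0, 4.0], y)
        enriched = make_mapped([3.0, 4.0, 0.1, 0.2], y)
        f_dep = A.compute_association(depleted, "clover", t_y=1, direction="negative")
        f_enr = A.compute_association(enriched, "clover", t_y=1, direction="negative")
        assert f_dep.log10_f > f_enr.log10_f
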