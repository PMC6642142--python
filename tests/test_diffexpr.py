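"""Normalization, t-test / NB exact DE, filtering and clustering."""

import math

import numpy as np
import pytest
import scipy.stats as st

from spongenet.diffexpr import (
    DEFilter,
    DERecord,
    apply_de_filter,
    hierarchical_cluster,
    nb_exact_de,
    quantile_normalize,
    ttest_de,
)
from conftest import two_group_matrix


class TestQuantileNormalize:
    def test_identical_columns_are_fixed_point(self):
        m = two_group_matrix(np.tile([[5.0], [1.0], [9.0]], 6))
        out = quantile_normalize(m)
        np.testing.assert_allclose(out.values, m.values)

    def test_two_column_hand_case(self):
        """Columns [1,3] and [2,4] both become [1.5, 3.5]: the means of
        the cross-sample sorted rows, assigned back by rank."""
        from spongenet.io_formats import ExpressionMatrix
        m = ExpressionMatrix(
            ["g1", "g2"], ["s1", "s2"], [[1.0, 4.0], [3.0, 2.0]],
            {"s1": "control", "s2": "C+T"},
        )
        out = quantile_normalize(m)
        np.testing.assert_allclose(out.values, [[1.5, 3.5], [3.5, 1.5]])

    @pytest.mark.parametrize("seed", [0, 1])
    def test_columns_share_one_distribution_afterwards(self, seed):
        rng = np.random.default_rng(seed)
        m = two_group_matrix(rng.lognormal(5, 1, (200, 6)))
        out = quantile_normalize(m)
        ref = np.sort(out.values[:, 0])
        for j in range(1, 6):
            np.testing.assert_allclose(np.sort(out.values[:, j]), ref)

    def test_empty_matrix_rejected(self):
        from spongenet.io_formats import ExpressionMatrix
        m = ExpressionMatrix([], ["s1"], np.empty((0, 1)), {"s1": "control"})
        with pytest.raises(ValueError):
            quantile_normalize(m)


class TestTtestDe:
    def test_null_identity(self):
        m = two_group_matrix(np.full((3, 6), 7.0))
        for r in ttest_de(m):
            assert r.p == 1.0
            assert r.signed_fc == 1.0
            assert r.direction == "flat"

    def test_signed_fc_definition(self):
        m = two_group_matrix([[20.0] * 3 + [40.0] * 3,
                              [40.0] * 3 + [20.0] * 3])
        r_up, r_down = ttest_de(m)
        assert r_up.signed_fc == pytest.approx(2.0)
        assert r_down.signed_fc == pytest.approx(-2.0)
        assert r_up.raw_intensity == pytest.approx(40.0)

    def test_matches_textbook_equal_variance_t(self):
        """Fixed 3-vs-3 vectors: t and p equal the pooled-variance
        two-sample formula computed by hand on the log2 data."""
        a = np.array([100.0, 140.0, 120.0])  # control
        b = np.array([260.0, 300.0, 240.0])  # treated
        m = two_group_matrix([np.r_[a, b]])
        (rec,) = ttest_de(m)
        la, lb = np.log2(a + 1), np.log2(b + 1)
        sp2 = ((la.var(ddof=1) + lb.var(ddof=1)) / 2)
        t = (lb.mean() - la.mean()) / math.sqrt(sp2 * (2 / 3))
        p = 2 * st.t.sf(abs(t), df=4)
        assert rec.p == pytest.approx(p, rel=1e-12)
        assert rec.signed_fc == pytest.approx(b.mean() / a.mean())

    def test_group_smaller_than_two_rejected(self):
        from spongenet.io_formats import ExpressionMatrix
        m = ExpressionMatrix(
            ["g"], ["c1", "t1", "t2"], [[1.0, 2.0, 3.0]],
            {"c1": "control", "t1": "C+T", "t2": "C+T"},
        )
        with pytest.raises(ValueError, match=">= 2 samples"):
            ttest_de(m)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_group_swap_antisymmetry(self, seed):
        """Swapping group labels negates every signed FC and leaves the
        p-values untouched."""
        rng = np.random.default_rng(seed)
        m = two_group_matrix(rng.lognormal(6, 0.5, (50, 6)))
        swapped = two_group_matrix(m.values)
        swapped.sample_groups = {
            s: ("C+T" if g == "control" else "control")
            for s, g in m.sample_groups.items()
        }
        fwd = ttest_de(m)
        rev = ttest_de(swapped)
        for f, r in zip(fwd, rev):
            assert f.signed_fc == pytest.approx(-r.signed_fc)
            assert f.p == pytest.approx(r.p)

    def test_bh_q_never_below_p_and_order_preserved(self):
        rng = np.random.default_rng(3)
        m = two_group_matrix(rng.lognormal(6, 0.5, (80, 6)))
        recs = ttest_de(m)
        for r in recs:
            assert r.q >= r.p - 1e-15
        ps = [r.p for r in recs]
        qs = [r.q for r in recs]
        order = np.argsort(ps)
        assert np.all(np.diff(np.array(qs)[order]) >= -1e-12)


class TestNbExactDe:
    def test_null_identity(self):
        m = two_group_matrix(np.full((4, 6), 25.0), integral=True)
        for r in nb_exact_de(m):
            assert r.p == 1.0
            assert r.direction == "flat"

    @pytest.mark.parametrize("s_trt,s_ctrl", [(10, 0), (7, 3), (2, 8)])
    def test_poisson_limit_equals_binomial_enumeration(self, s_trt, s_ctrl):
        """Constant filler features drive the moment dispersion to its
        floor, so the exact test reduces to the two-sided binomial
        (minimum-likelihood) test on the group sums at pi = 1/2."""
        filler = np.full((500, 6), 100.0)
        def spread(total):
            base = [total // 3] * 3
            base[0] += total - sum(base)
            return base
        feat = np.array(spread(s_ctrl) + spread(s_trt), dtype=float)
        m = two_group_matrix(np.vstack([feat, filler]), integral=True)
        rec = nb_exact_de(m)[0]
        total = s_trt + s_ctrl
        w = st.binom.pmf(np.arange(total + 1), total, 0.5)
        expected = w[w <= w[s_trt] * (1 + 1e-10)].sum()
        assert rec.p == pytest.approx(expected, rel=1e-6)

    def test_all_zero_feature_is_flat_p1(self):
        vals = np.vstack([np.zeros(6), np.full((3, 6), 50.0)])
        recs = nb_exact_de(two_group_matrix(vals, integral=True))
        assert recs[0].p == 1.0 and recs[0].direction == "flat"

    def test_library_size_normalization_prevents_depth_artifacts(self):
        """Doubling one sample's sequencing depth must not create fake
        differential expression."""
        rng = np.random.default_rng(4)
        base = rng.poisson(200.0, (30, 6)).astype(float)
        base[:, 3:] *= 2  # treated libraries twice as deep
        recs = nb_exact_de(two_group_matrix(base, integral=True))
        assert np.mean([r.p <= 0.05 for r in recs]) < 0.2


class TestApplyDeFilter:
    @pytest.mark.parametrize(
        "fc,p,expected",
        [
            (1.631, 0.037, "up"),        # printed up-regulated lncRNA row
            (-3.855, 0.029, "down"),     # printed down-regulated miRNA row
            (1.0, 0.001, None),          # below the fold gate
            (2.0, 0.06, None),           # above the p gate
            (1.5, 0.05, "up"),           # both boundaries are inclusive
            (-1.5, 0.05, "down"),
        ],
    )
    def test_threshold_semantics(self, fc, p, expected):
        rec = DERecord("x", 1.0, 1.0, fc, p, p, 10.0, "flat")
        up, down = apply_de_filter([rec])
        got = "up" if "x" in up else "down" if "x" in down else None
        assert got == expected

    def test_up_down_disjoint_on_random_records(self):
        rng = np.random.default_rng(5)
        recs = []
        for i in range(200):
            fc = float(rng.choice([-1, 1]) * rng.uniform(1, 5))
            p = float(rng.uniform(0, 0.2))
            recs.append(DERecord(f"g{i}", 1, 1, fc, p, p, 10, "flat"))
        up, down = apply_de_filter(recs)
        assert not up & down

    def test_filter_domain_validation(self):
        with pytest.raises(ValueError):
            DEFilter(fc_min=0.5)
        with pytest.raises(ValueError):
            DEFilter(p_max=1.5)


class TestHierarchicalCluster:
    def test_duplicate_rows_merge_first_at_zero_height(self):
        x = np.array([[1.0, 1.0], [5.0, 5.0], [1.0, 1.0]])
        _order, z = hierarchical_cluster(x)
        assert sorted(z[0, :2].astype(int).tolist()) == [0, 2]
        assert z[0, 2] == 0.0

    def test_one_dimensional_hand_case(self):
        """Points 0, 1, 10, 11: the two tight pairs merge before the
        final join (verified against exhaustive merge enumeration)."""
        x = np.array([[0.0], [1.0], [10.0], [11.0]])
        _order, z = hierarchical_cluster(x)
        first_two = {frozenset(z[0, :2].astype(int).tolist()),
                     frozenset(z[1, :2].astype(int).tolist())}
        assert first_two == {frozenset({0, 1}), frozenset({2, 3})}

    def test_permutation_gives_same_tree_heights(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(12, 4))
        perm = rng.permutation(12)
        _o1, z1 = hierarchical_cluster(x)
        _o2, z2 = hierarchical_cluster(x[perm])
        np.testing.assert_allclose(sorted(z1[:, 2]), sorted(z2[:, 2]))

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            hierarchical_cluster(np.array([[1.0, np.nan], [2.0, 3.0]]))
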