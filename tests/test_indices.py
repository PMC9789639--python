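"""Specificity index components and permutation statistics."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from aromdeg import (
    compare_aromatic_vs_other,
    ec_index,
    pairwise_t_residual,
    permanova_oneway,
    projection_cosine,
    spearman_profile_corr,
    specificity_score,
)


class TestSpearman:
    def test_hand_computed_rank_correlation(self):
        # ranks of (1,2,3) vs (3,1,2): Pearson of (1,2,3),(3,1,2) = -0.5
        rho = spearman_profile_corr(np.array([[1.0, 2.0, 3.0]]), np.array([[3.0, 1.0, 2.0]]))
        assert rho.iloc[0, 0] == pytest.approx(-0.5)

    def test_identical_profiles_are_one(self):
        x = np.array([[2.0, 5.0, 1.0, 9.0]])
        assert spearman_profile_corr(x, x).iloc[0, 0] == pytest.approx(1.0)

    def test_constant_profile_maps_to_zero(self):
        rho = spearman_profile_corr(np.array([[3.0, 3.0, 3.0]]), np.array([[1.0, 2.0, 3.0]]))
        assert rho.iloc[0, 0] == 0.0

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            spearman_profile_corr(np.ones((1, 2)), np.ones((1, 2)))

    def test_matches_scipy_spearmanr(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(size=(15, 8))
        h = rng.uniform(size=(3, 8))
        ours = spearman_profile_corr(a, h)
        for i in range(15):
            for k in range(3):
                expected = stats.spearmanr(a[i], h[k]).statistic
                assert ours.iloc[i, k] == pytest.approx(expected, abs=1e-12)

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(size=(5, 7))
        h = rng.uniform(size=(2, 7))
        base = spearman_profile_corr(a, h)
        warped = spearman_profile_corr(np.exp(3 * a), h)
        pd.testing.assert_frame_equal(base, warped)


class TestCosine:
    def test_collinear_profiles_are_one(self):
        a = np.array([[1.0, 2.0, 3.0]])
        assert projection_cosine(a, 5 * a).iloc[0, 0] == pytest.approx(1.0)

    def test_orthogonal_supports_are_zero(self):
        assert projection_cosine(np.array([[1.0, 0.0]]), np.array([[0.0, 1.0]])).iloc[0, 0] == 0

    def test_hand_computed_cosine(self):
        cos = projection_cosine(np.array([[1.0, 0.0]]), np.array([[1.0, 1.0]]))
        assert cos.iloc[0, 0] == pytest.approx(1 / math.sqrt(2), abs=1e-5)

    def test_zero_profile_maps_to_zero(self):
        assert projection_cosine(np.array([[0.0, 0.0]]), np.array([[1.0, 1.0]])).iloc[0, 0] == 0

    def test_invariant_to_positive_rescaling(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(size=(4, 6))
        h = rng.uniform(size=(2, 6))
        pd.testing.assert_frame_equal(
            projection_cosine(a, h), projection_cosine(7.3 * a, h)
        )


class TestScore:
    @pytest.mark.parametrize(
        "row,expected",
        [
            ([1, 0, 0, 0], 1.0),
            ([0.25, 0.25, 0.25, 0.25], 0.0),
            ([0.5, 0.5, 0, 0], 0.5),
        ],
    )
    def test_worked_examples(self, row, expected):
        assert specificity_score(np.array([row]))[0] == pytest.approx(expected)

    def test_all_zero_row_scores_zero(self):
        assert specificity_score(np.array([[0.0, 0.0, 0.0, 0.0]]))[0] == 0.0

    def test_invariant_to_row_rescaling(self):
        rng = np.random.default_rng(3)
        w = rng.uniform(size=(10, 4))
        s1 = specificity_score(w)
        s2 = specificity_score(w * rng.uniform(0.1, 10, size=(10, 1)))
        assert np.allclose(s1, s2, atol=1e-12)

    def test_score_within_unit_interval(self):
        rng = np.random.default_rng(4)
        s = specificity_score(rng.uniform(size=(200, 5)))
        assert ((s >= 0) & (s <= 1)).all()

    def test_single_component_rejected(self):
        with pytest.raises(ValueError):
            specificity_score(np.ones((3, 1)))


class TestIndex:
    @pytest.mark.parametrize(
        "rho,cos,score,expected",
        [(1.0, 1.0, 1.0, 1.0), (-1.0, 1.0, 1.0, -1.0), (0.5, 0.70711, 0.5, 0.176778)],
    )
    def test_product_rule(self, rho, cos, score, expected):
        out = ec_index(
            pd.DataFrame([[rho]]), pd.DataFrame([[cos]]), pd.Series([score])
        )
        assert out.iloc[0, 0] == pytest.approx(expected, abs=1e-5)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ec_index(pd.DataFrame(np.ones((2, 2))), pd.DataFrame(np.ones((2, 3))),
                     pd.Series([1.0, 1.0]))

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_index_bounded_by_one_on_random_inputs(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.lognormal(0, 1, size=(30, 9))
        h = rng.uniform(size=(4, 9))
        w = rng.uniform(size=(30, 4))
        idx = ec_index(
            spearman_profile_corr(a, h), projection_cosine(a, h), specificity_score(w)
        )
        assert (idx.abs().to_numpy() <= 1 + 1e-12).all()


class TestPermanova:
    def test_worked_f_and_exhaustive_p(self):
        F, p = permanova_oneway([1, 2, 3, 4, 5, 6], ["a"] * 3 + ["b"] * 3)
        assert F == pytest.approx(13.5)
        assert p == pytest.approx(2 / 20)

    def test_identical_values_give_zero_f(self):
        F, _ = permanova_oneway([5.0] * 6, ["a"] * 3 + ["b"] * 3)
        assert F == 0.0

    def test_label_permutation_leaves_statistics(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=9)
        g = np.array(["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        F1, p1 = permanova_oneway(v, g)
        perm = rng.permutation(9)
        F2, p2 = permanova_oneway(v[perm], g[perm])
        assert F1 == pytest.approx(F2)
        assert p1 == pytest.approx(p2)  # both exhaustive: identical

    def test_exhaustive_matches_full_enumeration_oracle(self):
        # brute-force oracle: enumerate label assignments via combinations
        rng = np.random.default_rng(5)
        v = rng.normal(size=7)
        g = ["a"] * 3 + ["b"] * 4

        def f_stat(codes):
            codes = np.asarray(codes)
            grand = v.mean()
            ssb = sum((v[codes == k].mean() - grand) ** 2 * (codes == k).sum()
                      for k in (0, 1))
            ssw = sum(((v[codes == k] - v[codes == k].mean()) ** 2).sum()
                      for k in (0, 1))
            return (ssb / 1) / (ssw / 5)

        obs = f_stat([0] * 3 + [1] * 4)
        ge = 0
        total = 0
        for pos in itertools.combinations(range(7), 3):
            codes = np.ones(7, int)
            codes[list(pos)] = 0
            total += 1
            if f_stat(codes) >= obs - 1e-12:
                ge += 1
        F, p = permanova_oneway(v, g)
        assert F == pytest.approx(obs)
        assert p == pytest.approx(ge / total)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            permanova_oneway([1, 2, 3], ["a", "a", "a"])

    def test_matches_skbio_permanova_f(self):
        # univariate one-way PERMANOVA on Euclidean distances has the same
        # pseudo-F as the classical one-way F; skbio is the oracle
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import permanova as sk_permanova

        rng = np.random.default_rng(9)
        v = rng.normal(size=12)
        g = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        d = np.abs(v[:, None] - v[None, :])
        dm = skbio.DistanceMatrix(d, ids=[str(i) for i in range(12)])
        sk = sk_permanova(dm, grouping=list(g), permutations=99)
        F, _ = permanova_oneway(v, g)
        assert F == pytest.approx(float(sk["test statistic"]), rel=1e-9)


class TestPairwiseT:
    def test_hand_computed_t(self):
        out = pairwise_t_residual([1, 2, 3, 4, 5, 6], ["a"] * 3 + ["b"] * 3)
        assert abs(out["t"].iloc[0]) == pytest.approx(3 / math.sqrt(2 / 3), abs=1e-4)

    def test_equal_means_give_zero_t_p_one(self):
        out = pairwise_t_residual([1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3)
        assert out["t"].iloc[0] == pytest.approx(0.0)
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_location_invariance(self):
        v = np.array([1.0, 2, 3, 7, 8, 10])
        g = ["a"] * 3 + ["b"] * 3
        t1 = pairwise_t_residual(v, g)["t"].iloc[0]
        t2 = pairwise_t_residual(v + 100.0, g)["t"].iloc[0]
        assert t1 == pytest.approx(t2)

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError):
            pairwise_t_residual([1.0, 1.0, 2.0, 2.0], ["a", "a", "b", "b"])


class TestAromaticContrast:
    def _table(self, arom_vals, other_vals):
        anns = [f"A{i}" for i in range(len(arom_vals))] + [
            f"O{i}" for i in range(len(other_vals))
        ]
        return (
            pd.DataFrame(
                {
                    "annotation": anns,
                    "component": "component_1",
                    "index": list(arom_vals) + list(other_vals),
                }
            ),
            {f"A{i}" for i in range(len(arom_vals))},
        )

    def test_planted_difference_detected(self):
        rng = np.random.default_rng(0)
        table, arom = self._table(rng.normal(0.6, 0.1, 20), rng.normal(0.0, 0.1, 60))
        rep = compare_aromatic_vs_other(table, arom, "component_1", seed=1)
        assert rep.mean_aromatic > rep.mean_other
        assert rep.p_t < 0.05 and rep.significant

    def test_identical_sets_give_zero_f(self):
        table, arom = self._table([0.2, 0.2, 0.2], [0.2, 0.2, 0.2, 0.2])
        rep = compare_aromatic_vs_other(table, arom, "component_1", seed=1)
        assert rep.F == 0.0

    def test_empty_partition_rejected(self):
        table, _ = self._table([0.1, 0.2], [0.3])
        with pytest.raises(ValueError):
            compare_aromatic_vs_other(table, set(), "component_1")

    def test_null_type_one_error_calibrated(self):
        """Permutation p-values under the null reject at ~alpha (0.05 +/- 0.02
        over 500 replicates)."""
        rng = np.random.default_rng(123)
        pvals = []
        n_rep = 500
        for _ in range(n_rep):
            v = rng.normal(size=16)
            g = ["x"] * 8 + ["y"] * 8
            _, p = permanova_oneway(v, g, n_perm=199, seed=int(rng.integers(2**31)))
            pvals.append(p)
        pvals = np.asarray(pvals)
        assert abs((pvals <= 0.05).mean() - 0.05) <= 0.02
        # and the p-value distribution is uniform on (0, 1)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01
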