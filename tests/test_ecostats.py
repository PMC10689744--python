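"""Community-comparison statistics against closed forms and oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps
from scipy.spatial.distance import braycurtis as scipy_bc
from skbio import DistanceMatrix
from skbio.stats.distance import anosim as skbio_anosim

from reefspectra import ecostats as es


class TestBrayCurtis:
    def test_identical_rows_zero(self):
        d = es.bray_curtis(np.array([[0.2, 0.8], [0.2, 0.8]]))
        assert d.values[0, 1] == 0.0

    def test_disjoint_support_one(self):
        d = es.bray_curtis(np.array([[1.0, 0.0], [0.0, 1.0]]))
        assert d.values[0, 1] == 1.0

    def test_closed_form_example(self):
        d = es.bray_curtis(np.array([[3.0, 1.0], [1.0, 3.0]]))
        assert d.values[0, 1] == pytest.approx(0.5, abs=1e-12)

    def test_matches_scipy_on_random_data(self):
        rng = np.random.default_rng(0)
        data = rng.uniform(0, 1, (6, 8))
        d = es.bray_curtis(data)
        for i, j in itertools.combinations(range(6), 2):
            assert d.values[i, j] == pytest.approx(
                scipy_bc(data[i], data[j]), abs=1e-12
            )

    def test_all_zero_pair_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            es.bray_curtis(np.array([[0.0, 0.0], [0.0, 0.0]]))

    @given(
        st.lists(
            st.lists(st.floats(0, 10, allow_nan=False), min_size=4, max_size=4),
            min_size=2,
            max_size=6,
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_range_symmetry_properties(self, rows):
        data = np.asarray(rows) + 1e-3  # avoid all-zero pairs
        d = es.bray_curtis(data)
        assert np.all(d.values >= 0) and np.all(d.values <= 1 + 1e-12)
        assert np.allclose(d.values, d.values.T)
        assert np.all(np.diag(d.values) == 0)


class TestSimilarityAndTransforms:
    @pytest.mark.parametrize("bc,expected", [(0.0, 100.0), (1.0, 0.0), (0.25, 75.0)])
    def test_similarity_percent(self, bc, expected):
        assert es.similarity_percent(bc) == pytest.approx(expected)

    def test_similarity_out_of_range(self):
        with pytest.raises(ValueError):
            es.similarity_percent(1.5)

    def test_sqrt_transform_values_and_monotonicity(self):
        m = np.array([[0.0, 1.0, 0.25], [0.49, 0.04, 0.47]])
        out = es.sqrt_transform(m)
        assert out[0, 0] == 0.0 and out[0, 1] == 1.0 and out[0, 2] == 0.5
        flat_in, flat_out = m.ravel(), out.ravel()
        for i, j in itertools.combinations(range(len(flat_in)), 2):
            assert (flat_in[i] < flat_in[j]) == (flat_out[i] < flat_out[j]) or (
                flat_in[i] == flat_in[j]
            )

    def test_sqrt_transform_rejects_negative(self):
        with pytest.raises(ValueError):
            es.sqrt_transform(np.array([[-0.1, 1.0]]))


def _exact_anosim_p(dist: es.DissimilarityMatrix, groups):
    """Brute-force oracle: enumerate group assignments via combinations."""
    groups = np.asarray(groups)
    n = dist.n
    ranks = sps.rankdata(dist.condensed())
    rank_m = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    rank_m[iu] = ranks
    rank_m += rank_m.T
    m_half = n * (n - 1) / 4.0

    def r_stat(g):
        within = g[:, None] == g[None, :]
        w = within[iu]
        rv = rank_m[iu]
        return (rv[~w].mean() - rv[w].mean()) / m_half

    r_obs = r_stat(groups)
    labels = sorted(set(groups))
    n_a = int((groups == labels[0]).sum())
    rs = []
    for combo in itertools.combinations(range(n), n_a):
        g = np.full(n, labels[1], dtype=object)
        g[list(combo)] = labels[0]
        rs.append(r_stat(g))
    rs = np.asarray(rs)
    return r_obs, float(np.mean(rs >= r_obs - 1e-12))


class TestAnosim:
    def _random_dist(self, n, seed):
        rng = np.random.default_rng(seed)
        data = rng.uniform(0, 1, (n, 5))
        return es.bray_curtis(data)

    def test_perfectly_separated_groups_give_r_one(self):
        # all between-group dissimilarities exceed all within-group ones
        d = np.array(
            [
                [0.0, 0.1, 0.9, 0.8],
                [0.1, 0.0, 0.85, 0.95],
                [0.9, 0.85, 0.0, 0.2],
                [0.8, 0.95, 0.2, 0.0],
            ]
        )
        dist = es.DissimilarityMatrix(list("abcd"), d)
        res = es.anosim(dist, ["g1", "g1", "g2", "g2"], n_permutations=99, seed=0)
        assert res.R == pytest.approx(1.0)

    def test_exact_enumeration_matches_bruteforce_oracle(self):
        dist = self._random_dist(8, seed=3)
        groups = ["a"] * 4 + ["b"] * 4
        res = es.anosim(dist, groups, n_permutations=999, seed=1)
        assert res.method == "exact"
        assert res.n_permutations == 70  # C(8,4) distinct relabelings
        r_oracle, p_oracle = _exact_anosim_p(dist, groups)
        assert res.R == pytest.approx(r_oracle, abs=1e-12)
        assert res.significance == pytest.approx(p_oracle, abs=1e-12)

    def test_matches_skbio_r_statistic(self):
        dist = self._random_dist(9, seed=5)
        groups = ["a"] * 4 + ["b"] * 5
        res = es.anosim(dist, groups, n_permutations=999, seed=2)
        sk = skbio_anosim(
            DistanceMatrix(dist.values, ids=[str(i) for i in dist.ids]),
            grouping=list(groups),
            permutations=0,
        )
        assert res.R == pytest.approx(float(sk["test statistic"]), abs=1e-10)

    def test_permutation_significance_reproducible(self):
        dist = self._random_dist(12, seed=7)
        groups = ["a"] * 6 + ["b"] * 6
        # force Monte-Carlo by keeping n_permutations below the 924
        # distinct relabelings of a 6+6 design
        a = es.anosim(dist, groups, n_permutations=500, seed=11)
        b = es.anosim(dist, groups, n_permutations=500, seed=11)
        assert a.method == "permutation"
        assert a.significance == b.significance
        assert np.array_equal(a.permutation_Rs, b.permutation_Rs)

    def test_singleton_group_rejected(self):
        dist = self._random_dist(5, seed=0)
        with pytest.raises(ValueError, match="singleton"):
            es.anosim(dist, ["a", "a", "a", "a", "b"])

    @given(st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_r_bounds_fuzzed(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        data = rng.uniform(0, 1, (n, 4)) + 1e-6
        dist = es.bray_curtis(data)
        half = n // 2
        groups = ["a"] * half + ["b"] * (n - half)
        res = es.anosim(dist, groups, n_permutations=49, seed=seed)
        assert -1.0 - 1e-9 <= res.R <= 1.0 + 1e-9
        assert 0.0 < res.significance <= 1.0


class TestNmds:
    def test_exactly_embeddable_triangle(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.3, 0.8]])
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        dist = es.DissimilarityMatrix([0, 1, 2], d)
        res = es.nmds(dist, k=2, n_restarts=3, seed=0)
        assert res.stress <= 1e-3

    def test_stress_history_non_increasing(self):
        rng = np.random.default_rng(4)
        data = rng.uniform(0, 1, (8, 5))
        dist = es.bray_curtis(data)
        res = es.nmds(dist, k=2, n_restarts=5, seed=1)
        h = np.asarray(res.stress_history)
        assert np.all(np.diff(h) <= 1e-15)

    def test_stress_invariant_under_rigid_motion(self):
        rng = np.random.default_rng(2)
        data = rng.uniform(0, 1, (7, 5))
        dist = es.bray_curtis(data)
        res = es.nmds(dist, k=2, n_restarts=4, seed=3)

        def stress_of(coords):
            # recompute stress-1 with an independent isotonic fit (sklearn)
            from sklearn.isotonic import IsotonicRegression

            iu = np.triu_indices(dist.n, 1)
            delta = dist.values[iu]
            dvec = np.sqrt(
                ((coords[:, None] - coords[None]) ** 2).sum(-1)
            )[iu]
            order = np.argsort(delta, kind="stable")
            iso = IsotonicRegression()
            dhat = np.empty_like(dvec)
            dhat[order] = iso.fit_transform(np.arange(len(dvec)), dvec[order])
            return np.sqrt(((dvec - dhat) ** 2).sum() / (dvec**2).sum())

        theta = 0.7
        rot = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        moved = res.coordinates @ rot.T + np.array([3.0, -2.0])
        assert stress_of(moved) == pytest.approx(stress_of(res.coordinates), abs=1e-10)
        # and the sklearn-isotonic recomputation agrees with the reported stress
        assert stress_of(res.coordinates) == pytest.approx(res.stress, abs=1e-8)

    def test_invalid_k(self):
        dist = es.bray_curtis(np.random.default_rng(0).uniform(0, 1, (4, 3)))
        with pytest.raises(ValueError):
            es.nmds(dist, k=4)


class TestAnovaTukey:
    def test_all_equal_groups(self):
        res = es.anova_tukey([2.0, 2.0, 2.0, 2.0], ["a", "a", "b", "b"])
        assert res.F == 0.0
        assert res.p == 1.0

    def test_closed_form_two_groups(self):
        res = es.anova_tukey([1, 2, 3, 4, 5, 6], ["a"] * 3 + ["b"] * 3)
        assert res.F == pytest.approx(13.5, abs=1e-12)
        assert (res.df_between, res.df_within) == (1, 4)

    def test_two_group_tukey_equals_t_test(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 8)
        y = rng.normal(0.7, 1, 6)
        res = es.anova_tukey(
            np.concatenate([x, y]), ["a"] * 8 + ["b"] * 6
        )
        t = sps.ttest_ind(x, y)  # pooled-variance two-sided t-test
        assert res.tukey[0][2] == pytest.approx(t.pvalue, abs=1e-9)
        assert res.p == pytest.approx(t.pvalue, abs=1e-9)

    def test_tukey_at_least_unadjusted_t(self):
        rng = np.random.default_rng(6)
        vals = rng.normal(0, 1, 15)
        groups = ["a"] * 5 + ["b"] * 5 + ["c"] * 5
        res = es.anova_tukey(vals, groups)
        for (g1, g2), _, adj_p in res.tukey:
            x = vals[np.asarray(groups) == g1]
            y = vals[np.asarray(groups) == g2]
            assert adj_p >= sps.ttest_ind(x, y).pvalue - 1e-12

    def test_matches_statsmodels_f(self):
        rng = np.random.default_rng(7)
        vals = rng.normal(0, 1, 18)
        groups = np.repeat(["a", "b", "c"], 6)
        res = es.anova_tukey(vals, groups)
        f, p = sps.f_oneway(*(vals[groups == g] for g in "abc"))
        assert res.F == pytest.approx(f, abs=1e-10)
        assert res.p == pytest.approx(p, abs=1e-10)

    def test_degenerate_zero_within_variance(self):
        res = es.anova_tukey([1.0, 1.0, 2.0, 2.0], ["a", "a", "b", "b"])
        assert np.isinf(res.F)
        assert res.degenerate
        assert 0 < res.p < 1e-12 or res.p > 0
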