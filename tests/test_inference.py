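"""Distance matrices, PERMANOVA (with oracles), SIMPER identities."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import braycurtis

import raftkit as rk


def _random_community(rng, n, p, integer=True):
    X = rng.uniform(0, 50, size=(n, p))
    if integer:
        X = np.floor(X)
    X[X.sum(axis=1) == 0, 0] = 1.0
    return X


class TestBrayCurtis:
    def test_identical_rows_are_zero(self):
        X = np.array([[3.0, 1.0, 2.0], [3.0, 1.0, 2.0]])
        assert rk.bray_curtis_matrix(X).values[0, 1] == 0.0

    def test_disjoint_rows_are_maximal(self):
        X = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert rk.bray_curtis_matrix(X, scale=100).values[0, 1] == 100.0

    def test_hand_value_from_published_source_vectors(self):
        # Andrin vs Sta. Marina general source percentages:
        # sum|x-y| = 6+0+13+19 = 38, sum(x+y) = 200 -> 100*38/200 = 19
        X = np.array([[0.0, 0.0, 0.0, 100.0], [6.0, 0.0, 13.0, 81.0]])
        assert rk.bray_curtis_matrix(X).values[0, 1] == pytest.approx(19.0)

    def test_matches_scipy_pairwise(self):
        rng = np.random.default_rng(3)
        X = _random_community(rng, 8, 5, integer=False)
        D = rk.bray_curtis_matrix(X, scale=1.0).values
        for i, j in itertools.combinations(range(8), 2):
            assert D[i, j] == pytest.approx(braycurtis(X[i], X[j]), abs=1e-12)

    def test_all_zero_row_rejected_by_name(self):
        X = pd.DataFrame([[1.0, 2.0], [0.0, 0.0]], index=["ok", "empty"])
        with pytest.raises(ValueError, match="empty"):
            rk.bray_curtis_matrix(X)

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            rk.bray_curtis_matrix(np.array([[1.0, -1.0], [1.0, 1.0]]))


class TestEuclidean:
    def test_three_four_five(self):
        D = rk.euclidean_matrix(np.array([[0.0, 0.0], [3.0, 4.0]]))
        assert D.values[0, 1] == pytest.approx(5.0)

    def test_variable_order_irrelevant(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(6, 4))
        perm = rng.permutation(4)
        assert np.allclose(rk.euclidean_matrix(X).values,
                           rk.euclidean_matrix(X[:, perm]).values)


class TestPermanova:
    def test_equals_classical_anova_on_univariate_data(self):
        """Euclidean distances + univariate samples: pseudo-F is the
        one-way ANOVA F statistic (independent scipy oracle)."""
        rng = np.random.default_rng(42)
        for _ in range(20):
            sizes = rng.integers(3, 8, size=rng.integers(2, 4))
            groups = [rng.normal(loc=rng.normal(0, 2), size=s) for s in sizes]
            y = np.concatenate(groups)[:, None]
            labels = np.repeat(np.arange(len(sizes)), sizes)
            res = rk.permanova(rk.euclidean_matrix(y), labels,
                               n_permutations=1, seed=0)
            f_oracle = stats.f_oneway(*groups).statistic
            assert res.pseudo_F == pytest.approx(f_oracle, rel=1e-10)

    def test_exact_enumeration_small_instance(self):
        """Full enumeration over all 20 arrangements of 2 groups of 3
        agrees with an independent brute-force oracle."""
        rng = np.random.default_rng(7)
        X = _random_community(rng, 6, 3)
        labels = ["a", "a", "a", "b", "b", "b"]
        D = rk.bray_curtis_matrix(X)

        # independent oracle: enumerate index subsets, recompute F from
        # scratch using plain sums over pairs
        d2 = D.values ** 2

        def brute_f(idx_a):
            idx_b = [i for i in range(6) if i not in idx_a]
            sst = sum(d2[i, j] for i in range(6) for j in range(i + 1, 6)) / 6
            ssw = 0.0
            for g in (list(idx_a), idx_b):
                ssw += sum(d2[i, j] for i in g for j in g if i < j) / len(g)
            return (sst - ssw) / (ssw / 4)

        f_obs = brute_f((0, 1, 2))
        fs = [brute_f(c) for c in itertools.combinations(range(6), 3)]
        p_oracle = np.mean([f >= f_obs - 1e-12 for f in fs])

        assert rk.permanova_exact(D, labels) == pytest.approx(p_oracle)
        # sampled p with the +1 convention converges to the same value
        res = rk.permanova(D, labels, n_permutations=1999, seed=3)
        assert res.p_perm == pytest.approx(p_oracle, abs=0.05)

    def test_invariant_to_sample_order_and_distance_scale(self):
        rng = np.random.default_rng(1)
        X = _random_community(rng, 10, 4)
        labels = ["a"] * 5 + ["b"] * 5
        D = rk.bray_curtis_matrix(X)
        f0 = rk.permanova(D, labels, 1, seed=0).pseudo_F

        perm = rng.permutation(10)
        D_perm = rk.DistanceMatrix([str(i) for i in range(10)],
                                   D.values[np.ix_(perm, perm)])
        f1 = rk.permanova(D_perm, list(np.asarray(labels)[perm]),
                          1, seed=0).pseudo_F
        assert f1 == pytest.approx(f0, rel=1e-12)

        D_scaled = rk.DistanceMatrix(D.sample_ids, D.values * 7.5)
        res = rk.permanova(D_scaled, labels, 1, seed=0)
        assert res.pseudo_F == pytest.approx(f0, rel=1e-12)
        assert res.ss_total == pytest.approx(
            7.5 ** 2 * rk.permanova(D, labels, 1, seed=0).ss_total, rel=1e-12)

    def test_partition_identity_and_dof(self):
        rng = np.random.default_rng(2)
        X = _random_community(rng, 9, 4)
        labels = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        res = rk.permanova(rk.bray_curtis_matrix(X), labels, 9, seed=0)
        assert res.ss_between + res.ss_within == \
            pytest.approx(res.ss_total, rel=1e-9)
        assert res.df_between + res.df_within == res.df_total == 8
        assert res.pseudo_F >= 0

    def test_matches_scikit_bio(self):
        skbio_dist = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(11)
        X = _random_community(rng, 12, 5)
        labels = ["a"] * 6 + ["b"] * 6
        D = rk.bray_curtis_matrix(X, scale=1.0)
        ours = rk.permanova(D, labels, 99, seed=0)
        dm = skbio_dist.DistanceMatrix(D.values, ids=D.sample_ids)
        theirs = skbio_dist.permanova(dm, grouping=labels, permutations=99)
        assert ours.pseudo_F == pytest.approx(theirs["test statistic"],
                                              rel=1e-10)

    def test_null_p_values_are_calibrated(self):
        """Under exchangeable data with random labels the permutation
        p-value rejects at about its nominal level."""
        rng = np.random.default_rng(99)
        rejections = 0
        n_datasets = 1000
        for _ in range(n_datasets):
            X = rng.uniform(0, 20, size=(12, 4))
            labels = ["a"] * 6 + ["b"] * 6
            res = rk.permanova(rk.euclidean_matrix(X), labels,
                               n_permutations=99,
                               seed=int(rng.integers(2 ** 31)))
            rejections += res.p_perm <= 0.05
        assert 0.03 <= rejections / n_datasets <= 0.07

    def test_error_cases(self):
        D = rk.euclidean_matrix(np.arange(4.0)[:, None])
        with pytest.raises(ValueError, match="two groups"):
            rk.permanova(D, ["a"] * 4, 9)
        with pytest.raises(ValueError, match="label per sample"):
            rk.permanova(D, ["a", "b"], 9)


class TestSimper:
    def test_contributions_sum_to_mean_between_group_dissimilarity(self):
        rng = np.random.default_rng(5)
        X = _random_community(rng, 10, 6)
        labels = ["a"] * 4 + ["b"] * 6
        res = rk.simper(pd.DataFrame(X), labels)
        # independent overall: mean pairwise between-group Bray-Curtis
        D = rk.bray_curtis_matrix(X).values
        between = [D[i, j] for i in range(4) for j in range(4, 10)]
        assert res.table["avg_contribution"].sum() == \
            pytest.approx(res.overall_avg_dissimilarity, rel=1e-9)
        assert res.overall_avg_dissimilarity == \
            pytest.approx(np.mean(between), rel=1e-9)
        assert res.table["percent"].sum() == pytest.approx(100, abs=0.01)
        cum = res.table["percent"].cumsum()
        assert np.allclose(res.table["cumulative_percent"], cum)

    def test_identical_groups_have_zero_dissimilarity(self):
        X = pd.DataFrame(np.tile([4.0, 1.0, 5.0], (6, 1)))
        res = rk.simper(X, ["a"] * 3 + ["b"] * 3)
        assert res.overall_avg_dissimilarity == 0.0
        assert (res.table["avg_contribution"] == 0).all()
        assert res.table["diss_sd_ratio"].isna().all()

    def test_requires_exactly_two_groups(self):
        X = pd.DataFrame(np.ones((6, 2)))
        with pytest.raises(ValueError, match="exactly 2"):
            rk.simper(X, ["a", "a", "b", "b", "c", "c"])

    def test_group_means_are_raw_column_means(self, litter_summary):
        X, labels = rk.source_table()
        res = rk.simper(X, labels)
        gen = X.iloc[:12]
        assert res.table.loc["FishingAquaculture", "mean_General"] == \
            pytest.approx(gen["FishingAquaculture"].mean())
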