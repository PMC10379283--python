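"""Correlation screening, PCA, HCPC clustering and the Wilcoxon comparison."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_table
from ratdiv.grid import PREDICTORS
from ratdiv.multivariate import (
    correlation_screen,
    hcpc,
    island_mainland_test,
    run_pca,
)


class TestCorrelationScreen:
    def test_perfect_correlation(self):
        x = np.linspace(0.1, 0.9, 20)
        X = np.random.default_rng(0).normal(size=(20, 5))
        X[:, 1] = x
        rep = correlation_screen(make_table(x, X)).table
        assert rep.loc[PREDICTORS[1], "r"] == pytest.approx(1.0)
        assert rep.loc[PREDICTORS[1], "p"] < 1e-10

    def test_perfect_anticorrelation(self):
        ho = np.array([0.3, 0.2, 0.1])
        X = np.zeros((3, 5))
        X[:, 0] = [1, 2, 3]
        X[:, 1:] = np.random.default_rng(1).normal(size=(3, 4))
        rep = correlation_screen(make_table(ho, X)).table
        assert rep.loc[PREDICTORS[0], "r"] == pytest.approx(-1.0)

    def test_constant_column_warns_not_crashes(self):
        ho = np.linspace(0.2, 0.8, 10)
        X = np.random.default_rng(2).normal(size=(10, 5))
        X[:, 3] = 7.0
        with pytest.warns(UserWarning, match="constant"):
            rep = correlation_screen(make_table(ho, X)).table
        assert np.isnan(rep.loc[PREDICTORS[3], "r"])
        assert np.isfinite(rep.loc[PREDICTORS[0], "r"])

    def test_too_few_rows_raises(self):
        with pytest.raises(ValueError):
            correlation_screen(make_table([0.1, 0.2]))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(scale=st.floats(-50, 50).filter(lambda s: abs(s) > 1e-6),
           shift=st.floats(-100, 100))
    def test_affine_rescaling_flips_sign_only(self, scale, shift):
        rng = np.random.default_rng(3)
        ho = rng.uniform(0.1, 0.9, 30)
        X = rng.normal(size=(30, 5))
        base = correlation_screen(make_table(ho, X)).table
        X2 = X.copy()
        X2[:, 2] = scale * X2[:, 2] + shift
        scaled = correlation_screen(make_table(ho, X2)).table
        assert scaled.loc[PREDICTORS[2], "r"] == pytest.approx(
            np.sign(scale) * base.loc[PREDICTORS[2], "r"], abs=1e-9
        )


class TestRunPca:
    def test_reconstruction_identity(self, small_table):
        pca = run_pca(small_table)
        Z = (small_table.data[pca.variables].to_numpy() - pca.means) / pca.sds
        np.testing.assert_allclose(pca.scores @ pca.loadings.to_numpy().T, Z,
                                   atol=1e-9)

    def test_explained_fractions_ordered_and_sum_to_one(self, small_table):
        pca = run_pca(small_table)
        assert pca.explained.sum() == pytest.approx(1.0)
        assert np.all(np.diff(pca.explained) <= 1e-12)
        assert np.all(pca.explained >= 0)

    def test_loadings_orthonormal(self, small_table):
        L = run_pca(small_table).loadings.to_numpy()
        np.testing.assert_allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-9)

    def test_rank_one_table_explained_fully_by_pc1(self):
        # every variable an affine image of one latent axis
        t = np.linspace(0, 1, 12)
        X = np.stack([2 * t + i for i in range(5)], axis=1)
        pca = run_pca(make_table(0.1 + 0.8 * t, X))
        assert pca.explained[0] == pytest.approx(1.0)

    def test_uncorrelated_variables_share_variance_equally(self):
        rng = np.random.default_rng(7)
        n = 10_000
        pca = run_pca(make_table(rng.uniform(0.05, 0.95, n),
                                 rng.normal(size=(n, 5))))
        np.testing.assert_allclose(pca.explained, 1 / 6, atol=0.02)

    def test_exclude_ho_flag(self, small_table):
        pca = run_pca(small_table, include_ho=False)
        assert pca.variables == list(PREDICTORS)
        assert pca.scores.shape[1] == 5

    def test_n_too_small_raises(self):
        with pytest.raises(ValueError):
            run_pca(make_table(np.linspace(0.1, 0.9, 5)))


class TestHcpc:
    def _clouds_table(self, seed=0, n_per=20, centers=(-10.0, 10.0), sd=0.1):
        rng = np.random.default_rng(seed)
        X = np.concatenate(
            [rng.normal(c, sd, size=(n_per, 5)) for c in centers]
        )
        ho = np.clip(0.5 + 0.02 * X[:, 0] / 10 + rng.normal(0, 0.01, len(X)),
                     0, 1)
        return make_table(ho, X)

    def test_two_separated_clouds_found_automatically(self):
        table = self._clouds_table()
        clusters = hcpc(run_pca(table))
        assert clusters.k == 2
        labels = clusters.labels
        # perfect agreement up to label permutation
        assert len(set(labels[:20])) == 1
        assert len(set(labels[20:])) == 1
        assert labels[0] != labels[-1]

    def test_k_equal_n_puts_each_point_alone(self, small_table):
        clusters = hcpc(run_pca(small_table), k=small_table.n)
        assert clusters.k == small_table.n
        assert len(np.unique(clusters.labels)) == small_table.n

    def test_duplicated_dataset_co_clusters_duplicates(self):
        table = self._clouds_table(seed=5, n_per=10)
        doubled = make_table(
            np.concatenate([table.ho, table.ho]),
            np.concatenate([table.predictors.to_numpy()] * 2),
        )
        clusters = hcpc(run_pca(doubled), k=2)
        labels = clusters.labels
        n = table.n
        assert (labels[:n] == labels[n:]).all()

    def test_explicit_k_respected(self, small_table):
        clusters = hcpc(run_pca(small_table), k=3)
        assert clusters.k == 3
        assert set(clusters.labels) == {1, 2, 3}

    def test_too_few_points_raise(self):
        pca = run_pca(make_table(np.linspace(0.1, 0.9, 10)))
        pca.scores = pca.scores[:2]  # truncate to 2 observations
        with pytest.raises(ValueError):
            hcpc(pca)


class TestIslandMainlandTest:
    def test_identical_groups_p_one(self):
        table = make_table([0.5, 0.5, 0.5, 0.5],
                           insularity=["island", "island", "mainland", "mainland"])
        _, p = island_mainland_test(table)
        assert p == pytest.approx(1.0)

    def test_exact_enumeration_three_vs_three(self):
        # disjoint ranks {1,2,3} vs {4,5,6}: the most extreme of C(6,3)=20
        # equally likely rank splits, two-sided p = 2/20
        table = make_table(
            np.array([1, 2, 3, 4, 5, 6]) / 10.0,
            insularity=["island"] * 3 + ["mainland"] * 3,
        )
        _, p = island_mainland_test(table)
        assert p == pytest.approx(0.1)

    def test_exact_matches_full_enumeration(self):
        rng = np.random.default_rng(11)
        ho = rng.uniform(0.1, 0.9, 10)
        ins = ["island"] * 4 + ["mainland"] * 6
        stat, p = island_mainland_test(make_table(ho, insularity=ins))
        # enumerate all C(10,4) assignments of the island ranks
        ranks = np.argsort(np.argsort(ho)) + 1
        observed = ranks[:4].sum()
        total = list(itertools.combinations(range(10), 4))
        null = [sum(ranks[list(c)]) for c in total]
        mu = np.mean(null)
        tail = sum(1 for s in null if abs(s - mu) >= abs(observed - mu) - 1e-12)
        assert p == pytest.approx(tail / len(total))

    def test_normal_approximation_close_to_exact(self):
        # tie-free groups of 8: the asymptotic p should sit within 0.02
        rng = np.random.default_rng(13)
        ho = rng.uniform(0.1, 0.9, 16)
        ins = ["island"] * 8 + ["mainland"] * 8
        from scipy.stats import mannwhitneyu

        exact = mannwhitneyu(ho[:8], ho[8:], alternative="two-sided",
                             method="exact").pvalue
        approx = mannwhitneyu(ho[:8], ho[8:], alternative="two-sided",
                              method="asymptotic").pvalue
        _, ours = island_mainland_test(make_table(ho, insularity=ins))
        assert ours == pytest.approx(exact)
        assert abs(approx - exact) < 0.02

    def test_empty_group_raises_with_name(self):
        table = make_table([0.2, 0.4, 0.6])
        with pytest.raises(ValueError, match="island"):
            island_mainland_test(table)
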