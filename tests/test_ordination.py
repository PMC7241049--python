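"""Ordination layer: Bray-Curtis, nMDS, PCA, vector fitting, surfaces."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy.spatial import procrustes
from scipy.spatial.distance import pdist, squareform

from streammox.landscape import (
    bray_curtis,
    fit_surface,
    fit_vectors,
    nmds,
    pca_env,
    relative_abundance,
    species_scores,
)


class TestRelativeAbundance:
    def test_single_otu_site(self):
        df = pd.DataFrame({"o1": [7]}, index=["s1"])
        assert relative_abundance(df).iloc[0, 0] == 1.0

    def test_uniform_counts(self):
        df = pd.DataFrame(np.full((2, 4), 5), columns=list("abcd"))
        assert np.allclose(relative_abundance(df).values, 0.25)

    def test_rows_sum_to_one_random(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.integers(0, 50, size=(10, 30)) + 1)
        assert np.allclose(relative_abundance(df).sum(axis=1), 1.0, atol=1e-12)

    def test_empty_site_rejected(self):
        df = pd.DataFrame({"o1": [0, 3]}, index=["s1", "s2"])
        with pytest.raises(ValueError, match="zero total"):
            relative_abundance(df)


class TestBrayCurtis:
    def test_hand_computed_value(self):
        # sum|x-y| / sum(x+y) = (0.5 + 0.5) / 2
        d = bray_curtis(pd.DataFrame([[1.0, 0.0], [0.5, 0.5]]))
        assert d.iloc[0, 1] == pytest.approx(0.5)

    def test_disjoint_supports(self):
        d = bray_curtis(pd.DataFrame([[1.0, 0.0], [0.0, 1.0]]))
        assert d.iloc[0, 1] == 1.0

    @given(arrays(np.float64, (5, 8),
                  elements=st.floats(0.0, 10.0)))
    @settings(max_examples=40, derandomize=True)
    def test_axioms_on_random_tables(self, x):
        x = x + 1e-3  # avoid all-zero rows
        d = bray_curtis(pd.DataFrame(x)).values
        assert np.allclose(np.diag(d), 0.0)
        assert np.allclose(d, d.T)
        assert (d >= -1e-12).all() and (d <= 1 + 1e-12).all()

    def test_all_zero_row_rejected(self):
        with pytest.raises(ValueError):
            bray_curtis(pd.DataFrame([[0.0, 0.0], [1.0, 1.0]]))


class TestNMDS:
    def test_recovers_planted_configuration(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(14, 2))
        d = squareform(pdist(x))
        res = nmds(pd.DataFrame(d), seed=0, n_starts=4)
        _, _, disparity = procrustes(x, res.sample_scores.values)
        assert disparity < 1e-3
        assert res.stress < 0.01

    def test_stress_monotone_descent(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(12, 4))
        d = squareform(pdist(x)) ** 1.5  # non-Euclidean, needs real iterations
        res = nmds(pd.DataFrame(d), seed=0, n_starts=5)
        for hist in res.stress_history:
            assert np.all(np.diff(hist) <= 1e-8)

    def test_collinear_configuration_near_zero_stress(self):
        x = np.linspace(0, 1, 8)[:, None] * np.array([[1.0, 2.0]])
        d = squareform(pdist(x))
        res = nmds(pd.DataFrame(d), seed=0, n_starts=3)
        assert res.stress < 0.01

    def test_stress_within_unit_interval_and_cross_check(self):
        """Stress-1 agrees with scikit-learn's non-metric MDS on a fixture."""
        from sklearn.manifold import MDS

        rng = np.random.default_rng(5)
        ab = rng.dirichlet(np.ones(30), size=10)
        d = bray_curtis(pd.DataFrame(ab))
        res = nmds(d, seed=0)
        assert 0.0 <= res.stress <= 1.0
        sk = MDS(n_components=2, metric=False, dissimilarity="precomputed",
                 normalized_stress=True, n_init=8, random_state=0,
                 eps=1e-9, max_iter=500).fit(d.values)
        # same objective: neither implementation should be much worse
        assert res.stress <= np.sqrt(sk.stress_) + 0.02

    def test_species_scores_are_weighted_site_averages(self):
        rng = np.random.default_rng(2)
        ab = pd.DataFrame(rng.dirichlet(np.ones(6), size=5),
                          index=[f"s{i}" for i in range(5)],
                          columns=[f"o{j}" for j in range(6)])
        res = nmds(bray_curtis(ab), seed=0, n_starts=5)
        sp = species_scores(res, ab)
        j = "o2"
        w = ab[j] / ab[j].sum()
        manual = (res.sample_scores.values * w.values[:, None]).sum(axis=0)
        assert np.allclose(sp.loc[j].values, manual)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            nmds(np.zeros((3, 3)), k=2)


class TestPCA:
    def test_known_covariance_eigendirections(self):
        rng = np.random.default_rng(0)
        z = rng.normal(size=(500, 2))
        # correlated 2-D data with analytically known eigenvectors
        cov = np.array([[2.0, 1.0], [1.0, 2.0]])
        x = z @ np.linalg.cholesky(cov).T
        env = pd.DataFrame(x, columns=["a", "b"])
        res = pca_env(env, scale=False)
        v1 = res.species_scores["PC1"].values
        expected = np.array([1.0, 1.0]) / np.sqrt(2)  # eigvec of [[2,1],[1,2]]
        assert abs(abs(v1 @ expected) - 1.0) < 0.01

    def test_duplicated_variable_adds_no_direction(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(20, 2))
        env = pd.DataFrame(np.column_stack([x, x[:, 0]]),
                           columns=["a", "b", "a2"])
        res = pca_env(env, scale=True)
        assert res.explained[-1] == pytest.approx(0.0, abs=1e-12)

    def test_variance_fractions_non_increasing_and_bounded(self):
        rng = np.random.default_rng(2)
        env = pd.DataFrame(rng.normal(size=(14, 6)))
        res = pca_env(env)
        assert np.all(np.diff(res.explained) <= 1e-12)
        assert res.explained.sum() <= 1 + 1e-9

    def test_constant_column_with_scaling_rejected(self):
        env = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        with pytest.raises(ValueError, match="constant"):
            pca_env(env, scale=True)


class TestFitVectors:
    def _ord(self, n=14, seed=0):
        rng = np.random.default_rng(seed)
        env = pd.DataFrame(rng.normal(size=(n, 4)))
        return pca_env(env, scale=False)

    def test_axis_aligned_variable(self):
        ordn = self._ord()
        v = pd.DataFrame({"x": ordn.sample_scores["PC1"]})
        out = fit_vectors(ordn, v, n_perm=99, seed=0)
        assert out.loc["x", "r2"] == pytest.approx(1.0)
        assert abs(out.loc["x", "axis1"]) == pytest.approx(1.0, abs=1e-9)
        assert out.loc["x", "p"] <= 0.05

    def test_constant_variable_rejected(self):
        ordn = self._ord()
        with pytest.raises(ValueError, match="constant"):
            fit_vectors(ordn, pd.DataFrame({"c": np.ones(14)},
                                           index=ordn.sample_scores.index),
                        n_perm=9)

    def test_zero_permutations_rejected(self):
        ordn = self._ord()
        with pytest.raises(ValueError):
            fit_vectors(ordn, pd.DataFrame({"x": np.arange(14.0)},
                                           index=ordn.sample_scores.index),
                        n_perm=0)


class TestFitSurface:
    def _scores(self, n=14, seed=0):
        rng = np.random.default_rng(seed)
        env = pd.DataFrame(rng.normal(size=(n, 4)))
        return pca_env(env, scale=False)

    def test_linear_plane_reproduced(self):
        ordn = self._scores()
        x = ordn.sample_scores.iloc[:, :2].values
        y = pd.Series(2.0 * x[:, 0] - x[:, 1] + 1.0,
                      index=ordn.sample_scores.index)
        surf = fit_surface(ordn, y)
        assert surf.loo_r2 > 0.95
        assert np.allclose(surf.predict(x), y.values, atol=1e-6)

    def test_quadratic_bowl_recovered(self):
        ordn = self._scores(n=20, seed=3)
        x = ordn.sample_scores.iloc[:, :2].values
        y = pd.Series(x[:, 0] ** 2 + x[:, 1] ** 2,
                      index=ordn.sample_scores.index)
        surf = fit_surface(ordn, y)
        rmse = np.sqrt(np.mean((surf.predict(x) - y.values) ** 2))
        assert rmse < 0.05 * (y.max() - y.min())

    def test_constant_variable_gives_flat_surface(self):
        ordn = self._scores()
        y = pd.Series(np.full(14, 3.0), index=ordn.sample_scores.index)
        surf = fit_surface(ordn, y)
        grid = np.random.default_rng(0).normal(size=(20, 2))
        assert np.allclose(surf.predict(grid), 3.0, atol=1e-6)

    def test_too_few_sites_rejected(self):
        ordn = self._scores(n=5)
        y = pd.Series(np.arange(5.0), index=ordn.sample_scores.index)
        with pytest.raises(ValueError):
            fit_surface(ordn, y)
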