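"""Community landscape: density, peaks, MOB clustering, hulls, overrepresentation."""

import warnings

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from streammox.landscape import (
    cluster_mob,
    community_landscape,
    density_landscape,
    exclude_sparse_sites,
    find_peaks,
    hull_members,
    mob_flags_from_taxonomy,
    overrepresentation,
)
from streammox.types import OtuTable


def _two_blob_scores(n=200, sep=4.0, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal(size=(n // 2, 2)) * 0.3
    b = rng.normal(size=(n - n // 2, 2)) * 0.3 + [sep, 0.0]
    pts = np.vstack([a, b])
    return pd.DataFrame(pts, index=[f"o{i}" for i in range(n)],
                        columns=["NMDS1", "NMDS2"])


class TestDensity:
    def test_integrates_to_one(self):
        gx, gy, z = density_landscape(_two_blob_scores(), grid_n=120)
        integral = np.trapezoid(np.trapezoid(z, gx, axis=1), gy)
        assert integral == pytest.approx(1.0, abs=0.02)
        assert (z >= 0).all()

    def test_two_separated_blobs_give_two_maxima(self):
        gx, gy, z = density_landscape(_two_blob_scores(), grid_n=120)
        saddle = z[:, np.argmin(np.abs(gx - 2.0))].max()
        peaks = find_peaks(gx, gy, z, cutoff=saddle * 1.5)
        assert len(peaks) == 2

    def test_single_tight_cluster_peaks_at_centroid(self):
        rng = np.random.default_rng(0)
        pts = pd.DataFrame(rng.normal(size=(100, 2)) * 0.1)
        gx, gy, z = density_landscape(pts, grid_n=80)
        peaks = find_peaks(gx, gy, z, cutoff=z.max() * 0.5)
        assert len(peaks) == 1
        assert abs(peaks[0]["x"] - pts.values[:, 0].mean()) < 0.1

    def test_degenerate_scores_rejected(self):
        pts = pd.DataFrame(np.zeros((10, 2)))
        with pytest.raises(ValueError, match="degenerate"):
            density_landscape(pts)


class TestFindPeaks:
    def test_cutoff_zero_on_positive_grid_gives_one_component(self):
        gx, gy, z = density_landscape(_two_blob_scores(), grid_n=60)
        assert len(find_peaks(gx, gy, z + 1e-12, cutoff=0.0)) == 1

    def test_cutoff_above_max_gives_empty(self):
        gx, gy, z = density_landscape(_two_blob_scores(), grid_n=60)
        assert find_peaks(gx, gy, z, cutoff=z.max() * 1.01) == []

    def test_count_non_increasing_above_saddle(self):
        # component counts can only merge-or-vanish once the cutoff clears
        # the highest saddle; below it a region may split in two
        gx, gy, z = density_landscape(_two_blob_scores(), grid_n=80)
        saddle = z[:, np.argmin(np.abs(gx - 2.0))].max()
        counts = [len(find_peaks(gx, gy, z, c))
                  for c in np.linspace(saddle * 1.01, z.max() * 1.05, 10)]
        assert all(b <= a for a, b in zip(counts, counts[1:]))
        assert counts[-1] == 0

    def test_unimodal_count_non_increasing(self):
        rng = np.random.default_rng(1)
        pts = pd.DataFrame(rng.normal(size=(300, 2)))
        gx, gy, z = density_landscape(pts, grid_n=80)
        counts = [len(find_peaks(gx, gy, z, c))
                  for c in np.linspace(0.0, z.max() * 1.05, 12)]
        assert all(b <= a for a, b in zip(counts, counts[1:]))

    def test_negative_cutoff_rejected(self):
        with pytest.raises(ValueError):
            find_peaks(np.arange(3.0), np.arange(3.0), np.ones((3, 3)), -1.0)


class TestClusterMob:
    def test_planted_groups_recovered_exactly(self):
        scores = _two_blob_scores(n=30, sep=5.0)
        truth = np.array([0] * 15 + [1] * 15)
        labels = cluster_mob(scores, k=2, seed=0)
        assert adjusted_rand_score(truth, labels.values) == 1.0
        assert set(labels) == {1, 2}

    def test_k1_gives_single_label(self):
        labels = cluster_mob(_two_blob_scores(n=20), k=1, seed=0)
        assert set(labels) == {1}

    def test_far_points_unassigned(self):
        scores = _two_blob_scores(n=30, sep=5.0)
        scores.loc["far"] = [2.5, 40.0]
        labels = cluster_mob(scores, k=2, seed=0)
        assert labels["far"] == 0

    def test_fewer_points_than_k_rejected(self):
        with pytest.raises(ValueError):
            cluster_mob(_two_blob_scores(n=3), k=4)


class TestHullMembers:
    def test_uniform_scatter_matches_hull_area(self):
        """Points uniform on a square: the count inside a known hull matches
        its area fraction within binomial 99% bounds."""
        rng = np.random.default_rng(0)
        n = 4000
        pts = pd.DataFrame(rng.uniform(0, 1, size=(n, 2)),
                           index=[f"b{i}" for i in range(n)])
        square = pd.DataFrame(
            [[0.2, 0.2], [0.2, 0.6], [0.6, 0.2], [0.6, 0.6]],
            index=[f"m{i}" for i in range(4)])
        allpts = pd.concat([square, pts])
        flags = pd.Series([True] * 4 + [False] * n, index=allpts.index)
        inside = hull_members(square, allpts, flags)
        p = 0.16
        sd = np.sqrt(n * p * (1 - p))
        assert abs(len(inside) - n * p) < 2.58 * sd

    def test_own_members_inside_and_empty_region(self):
        cluster = pd.DataFrame([[0, 0], [1, 0], [0, 1]],
                               index=["a", "b", "c"])
        others = pd.DataFrame([[10.0, 10.0]], index=["far"])
        allpts = pd.concat([cluster, others])
        flags = pd.Series([True, True, True, False], index=allpts.index)
        assert hull_members(cluster, allpts, flags) == []

    def test_boundary_counts_as_inside(self):
        cluster = pd.DataFrame([[0, 0], [2, 0], [0, 2]])
        allpts = pd.DataFrame([[1.0, 0.0]], index=["edge"])
        flags = pd.Series([False], index=allpts.index)
        assert hull_members(cluster, allpts, flags) == ["edge"]

    def test_collinear_cluster_falls_back_with_warning(self):
        cluster = pd.DataFrame([[0, 0], [1, 1], [2, 2]])
        allpts = pd.DataFrame([[1.0, 1.0], [5.0, 0.0]], index=["on", "off"])
        flags = pd.Series([False, False], index=allpts.index)
        with pytest.warns(UserWarning, match="collinear"):
            inside = hull_members(cluster, allpts, flags)
        assert inside == ["on"]


class TestOverrepresentation:
    TAX = pd.Series({
        **{f"a{i}": "Bacteria;P1;ClassA;o;g" for i in range(10)},
        **{f"b{i}": "Bacteria;P2;ClassB;o;g" for i in range(10)},
    })

    def test_pure_member_set(self):
        bg = list(self.TAX.index)
        out = overrepresentation([f"a{i}" for i in range(5)], self.TAX, bg)
        assert out.loc["ClassA", "share_in"] == 1.0
        assert out.loc["ClassB", "ratio"] == 0.0

    def test_uniform_members_have_unit_ratios(self):
        bg = list(self.TAX.index)
        members = ["a0", "a1", "b0", "b1"]
        out = overrepresentation(members, self.TAX, bg)
        assert np.allclose(out["ratio"].values, 1.0)

    def test_empty_members_rejected(self):
        with pytest.raises(ValueError):
            overrepresentation([], self.TAX, list(self.TAX.index))

    def test_member_not_in_background_rejected(self):
        with pytest.raises(ValueError):
            overrepresentation(["zzz"], self.TAX, list(self.TAX.index))


class TestPipeline:
    def test_mob_flags_from_taxonomy(self):
        tax = pd.Series({
            "x": "Bacteria;Proteobacteria;Gammaproteobacteria;"
                 "Methylococcales;Methylococcaceae;Crenothrix",
            "y": "Bacteria;Nitrospirae;Nitrospira;Nitrospirales;Nitrospira",
        })
        flags = mob_flags_from_taxonomy(tax)
        assert flags["x"] and not flags["y"]

    def test_sparse_sites_excluded(self):
        counts = pd.DataFrame(
            {"m1": [5, 1, 0], "m2": [4, 0, 0], "n1": [10, 10, 10]},
            index=["rich", "one_mob", "no_mob"])
        table = OtuTable(counts=counts,
                         taxonomy=pd.Series("t", index=counts.columns),
                         is_mob=pd.Series([True, True, False],
                                          index=counts.columns))
        sub, excluded = exclude_sparse_sites(table, min_mob_otus=2)
        assert set(excluded) == {"one_mob", "no_mob"}
        assert list(sub.counts.index) == ["rich"]

    def test_end_to_end_recovery_of_planted_clusters(self, landscape_run):
        """The full nMDS → density → k-means pipeline recovers the planted
        23 + 7 MOB co-occurrence clusters and sets the sporadic outliers
        aside (alpine sites drop out by the sparse-site rule)."""
        result, ordination, truth = landscape_run
        planted = pd.Series({o: truth.mob_cluster[o]
                             for o in result.mob_clusters.index})
        ari = adjusted_rand_score(planted.values, result.mob_clusters.values)
        assert ari >= 0.9
        clusters = set(result.mob_clusters) - {0}
        assert clusters == {1, 2}
        sizes = result.mob_clusters.value_counts()
        assert sizes[1] == 23 and sizes[2] == 7 and sizes.get(0, 0) == 6
        assert 0 < ordination.stress < 0.2
        assert all(s.startswith("Alp") for s in result.excluded_sites)

    def test_hulls_capture_covarying_background(self, landscape_run):
        result, _, _ = landscape_run
        # both clusters have hulls with co-occurring non-MOB OTUs
        assert set(result.hull_members) == {1, 2}
        assert len(result.hull_members[1]) > len(result.hull_members[2]) > 0
        for c, df in result.overrep.items():
            assert np.isclose(df["share_in"].sum(), 1.0)
            assert np.isclose(df["share_bg"].sum(), 1.0)
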