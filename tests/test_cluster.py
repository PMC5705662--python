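"""Cosine hierarchical clustering, PCA, correlation, KDE and spatial mapping."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from sga.cluster import (
    cluster_cells,
    cluster_genes,
    cosine_distance_matrix,
    gene_correlation_matrix,
    gene_density,
    hierarchical_cluster,
    pca_biplot,
    recluster_on_gene_subset,
    select_k_silhouette,
    spatial_map,
)


def brute_force_average_linkage(D):
    """Independent agglomeration oracle: repeatedly merge the closest pair of
    clusters under average linkage, ties to the smallest index pair.

    Returns the list of merged member-sets, in merge order.
    """
    D = np.asarray(D, dtype=float)
    clusters = [frozenset([i]) for i in range(len(D))]
    merges = []
    while len(clusters) > 1:
        best = None
        for (i, a), (j, b) in itertools.combinations(enumerate(clusters), 2):
            d = np.mean([D[p, q] for p in a for q in b])
            key = (d, min(min(a), min(b)), max(min(a), min(b)))
            if best is None or key < best[0]:
                best = (key, i, j)
        _, i, j = best
        merged = clusters[i] | clusters[j]
        merges.append(merged)
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    return merges


def scipy_merge_sets(Z, n):
    members = {i: frozenset([i]) for i in range(n)}
    out = []
    for row, (a, b) in enumerate(Z[:, :2].astype(int)):
        merged = members[a] | members[b]
        members[n + row] = merged
        out.append(merged)
    return out


class TestCosine:
    def test_identical_vectors_distance_zero(self):
        X = np.array([[1.0, 2.0], [2.0, 4.0]])
        D = cosine_distance_matrix(X)
        assert D[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_vectors_distance_one(self):
        X = np.array([[1.0, 0.0], [0.0, 3.0]])
        assert cosine_distance_matrix(X)[0, 1] == pytest.approx(1.0)

    def test_known_angle(self):
        X = np.array([[1.0, 0.0], [1.0, 1.0]])
        assert cosine_distance_matrix(X)[0, 1] == pytest.approx(1 - 1 / np.sqrt(2), abs=1e-12)

    def test_zero_norm_row_named_in_error(self):
        X = pd.DataFrame([[1.0, 1.0], [0.0, 0.0]], index=["ok", "silent"])
        with pytest.raises(ValueError, match="silent"):
            cosine_distance_matrix(X)


class TestHierarchical:
    def test_two_separated_pairs(self):
        X = np.array([[0, 1.0], [0.05, 1.0], [1.0, 0.0], [1.0, 0.02]])
        res = hierarchical_cluster(cosine_distance_matrix(X), k=2)
        labels = res.assignment.to_numpy()
        assert labels[0] == labels[1] and labels[2] == labels[3] and labels[0] != labels[2]

    def test_k_equals_n_gives_singletons(self):
        X = np.random.default_rng(0).normal(size=(6, 3))
        res = hierarchical_cluster(cosine_distance_matrix(X), k=6)
        assert res.assignment.nunique() == 6

    def test_merge_order_matches_brute_force_oracle(self):
        """Six points with distinct pairwise distances: the merge sequence
        equals an independent brute-force agglomeration."""
        rng = np.random.default_rng(7)
        X = rng.normal(size=(6, 4))
        D = cosine_distance_matrix(X)
        res = hierarchical_cluster(D, k=1)
        assert scipy_merge_sets(res.linkage_matrix, 6) == brute_force_average_linkage(D)

    def test_row_permutation_invariance(self, pop5_zscore):
        zscore, _ = pop5_zscore
        rng = np.random.default_rng(11)
        perm = rng.permutation(len(zscore))
        a = cluster_cells(zscore, k=5).assignment
        b = cluster_cells(zscore.iloc[perm], k=5).assignment
        assert adjusted_rand_score(a.loc[zscore.index], b.loc[zscore.index]) == 1.0

    def test_cut_reproduces_assignment(self, pop5_zscore):
        zscore, _ = pop5_zscore
        res = cluster_cells(zscore, k=5)
        pd.testing.assert_series_equal(res.cut(5), res.assignment, check_names=False)

    def test_k_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            hierarchical_cluster(np.zeros((3, 3)), k=5)


class TestSelectK:
    def test_three_blobs(self):
        rng = np.random.default_rng(1)
        centers = np.array([[10, 0, 0], [0, 10, 0], [0, 0, 10]], dtype=float)
        X = np.vstack([c + rng.normal(0, 0.5, size=(20, 3)) for c in centers])
        D = cosine_distance_matrix(X)
        k, _ = select_k_silhouette(D, range(2, 8))
        assert k == 3

    def test_singleton_range(self):
        rng = np.random.default_rng(2)
        D = cosine_distance_matrix(rng.uniform(0.1, 1, size=(10, 3)))
        k, _ = select_k_silhouette(D, [2])
        assert k == 2

    def test_five_planted_populations(self, pop5_zscore):
        zscore, pops = pop5_zscore
        res = cluster_cells(zscore)  # silhouette over k = 2..10
        assert res.k == 5
        assert adjusted_rand_score(pops.to_numpy(), res.assignment.to_numpy()) >= 0.9


class TestGeneStructure:
    def test_full_subset_equals_full_clustering(self, pop5_zscore):
        zscore, _ = pop5_zscore
        full = cluster_cells(zscore, k=5).assignment
        sub = recluster_on_gene_subset(zscore, list(zscore.columns), k=5).assignment
        assert adjusted_rand_score(full, sub.loc[full.index]) == 1.0

    def test_single_gene_subset_equals_1d_grouping(self):
        """Clustering on one z-scored gene reduces to grouping by sign: in one
        dimension the cosine between two values is +1 (same side) or -1."""
        values = np.array([-1.2, -1.0, -1.1, 0.9, 1.1, 1.0])
        z = pd.DataFrame({"only": values, "pad": values})
        res = recluster_on_gene_subset(z, ["only"], k=2)
        labels = res.assignment.to_numpy()
        oracle = (values > 0).astype(int)  # brute-force 1D threshold grouping
        assert adjusted_rand_score(oracle, labels) == 1.0

    def test_unknown_gene_listed(self, pop5_zscore):
        zscore, _ = pop5_zscore
        with pytest.raises(KeyError, match="nope"):
            recluster_on_gene_subset(zscore, ["nope"])

    def test_marker_subset_separates_their_populations(self, pop5_zscore):
        """Reclustering on the markers of two populations separates exactly
        those two populations among their cells."""
        zscore, pops = pop5_zscore
        markers = list(zscore.columns[:14])  # blocks of populations 0 and 1
        res = recluster_on_gene_subset(zscore, markers, k=2)
        cells = res.assignment.index.intersection(pops.index[pops < 2])
        ari = adjusted_rand_score(pops.loc[cells], res.assignment.loc[cells])
        assert ari >= 0.8

    def test_planted_gene_module_recovered(self, pop5_zscore):
        zscore, _ = pop5_zscore
        res = cluster_genes(zscore)
        module = set(zscore.columns[:7])
        label = res.assignment[zscore.columns[0]]
        members = set(res.assignment[res.assignment == label].index)
        assert members == module


class TestCorrelation:
    def test_hand_computed_values(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [2.0, 4.0, 6.0], "c": [3.0, 1.0, 2.0]})
        corr = gene_correlation_matrix(X)
        assert corr.loc["a", "a"] == 1.0
        assert corr.loc["a", "b"] == pytest.approx(1.0)
        assert corr.loc["a", "c"] == pytest.approx(-0.5)  # direct formula by hand

    def test_negated_gene_anticorrelates(self):
        X = pd.DataFrame({"a": [1.0, 3.0, 2.0, 5.0]})
        X["neg"] = -X["a"]
        assert gene_correlation_matrix(X).loc["a", "neg"] == pytest.approx(-1.0)

    def test_zero_variance_gene_zeroed(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0], "flat": [1.0, 1.0, 1.0]})
        with pytest.warns(UserWarning, match="zero-variance"):
            corr = gene_correlation_matrix(X)
        assert corr.loc["a", "flat"] == 0.0
        assert corr.loc["flat", "flat"] == 1.0


class TestPCA:
    def test_collinear_data_one_component(self):
        t = np.linspace(0, 1, 30)
        X = pd.DataFrame({"x": t, "y": 2 * t})
        res = pca_biplot(X)
        assert res.variance_explained[0] == pytest.approx(1.0, abs=1e-9)
        assert res.variance_explained[1] == pytest.approx(0.0, abs=1e-9)

    def test_isotropic_data_near_uniform_shares(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(4000, 4)))
        res = pca_biplot(X)
        assert np.all(np.abs(res.variance_explained - 0.25) < 0.03)

    def test_planted_two_component_share(self):
        """Covariance built with a 0.70 top-two eigenvalue share: the
        empirical share lands within 0.02 of it at n = 5000."""
        rng = np.random.default_rng(4)
        eigvals = np.array([4.5, 2.5] + [0.375] * 8)
        assert eigvals[:2].sum() / eigvals.sum() == pytest.approx(0.70)
        Q, _ = np.linalg.qr(rng.normal(size=(10, 10)))
        C = Q @ np.diag(eigvals) @ Q.T
        X = pd.DataFrame(rng.multivariate_normal(np.zeros(10), C, size=5000))
        share = pca_biplot(X).variance_explained[:2].sum()
        assert share == pytest.approx(0.70, abs=0.02)

    def test_reconstruction_to_machine_precision(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.normal(size=(40, 6)))
        res = pca_biplot(X)
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T + res.mean
        np.testing.assert_allclose(recon, X.to_numpy(), atol=1e-10)

    def test_loadings_orthonormal_and_shares_ordered(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame(rng.normal(size=(50, 5)) * [3, 2, 1, 1, 0.5])
        res = pca_biplot(X)
        L = res.loadings.to_numpy()
        np.testing.assert_allclose(L.T @ L, np.eye(5), atol=1e-8)
        assert np.all(np.diff(res.variance_explained) <= 1e-12)
        assert res.variance_explained.sum() == pytest.approx(1.0, abs=1e-9)

    def test_biplot_scaling_bounded(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame(rng.normal(size=(30, 4)))
        res = pca_biplot(X)
        assert np.abs(res.biplot_scores.iloc[:, :2].to_numpy()).max() == pytest.approx(1.0)
        norms = np.linalg.norm(res.biplot_loadings.iloc[:, :2].to_numpy(), axis=1)
        assert norms.max() == pytest.approx(1.0)

    def test_single_observation_rejected(self):
        with pytest.raises(ValueError):
            pca_biplot(pd.DataFrame([[1.0, 2.0]]))


class TestSpatialMap:
    def _result(self, zscore, k=2):
        return cluster_cells(zscore, k=k)

    def test_single_cell_record(self):
        z = pd.DataFrame({"a": [1.0, 2.0], "b": [0.5, 0.1]}, index=[1, 2])
        res = self._result(z)
        meta = pd.DataFrame(
            {"cz": [1.0, 2.0], "cy": [3.0, 4.0], "cx": [5.0, 6.0]}, index=[1, 2]
        )
        out = spatial_map(res, meta)
        assert len(out) == 2
        assert out.loc[1, "cz"] == 1.0 and "cluster" in out.columns

    def test_missing_cells_rejected(self):
        z = pd.DataFrame({"a": [1.0, 2.0], "b": [0.5, 0.1]}, index=[1, 2])
        res = self._result(z)
        with pytest.raises(KeyError):
            spatial_map(res, pd.DataFrame({"cz": [0.0], "cy": [0.0], "cx": [0.0]}, index=[1]))

    def test_block_layout_clusters_are_spatially_coherent(self, small_truth):
        """Clusters from the planted block layout: mean within-cluster
        centroid distance below the between-cluster mean."""
        from sga.quantify import volume_normalize, zscore_per_sample

        truth = small_truth
        counts = truth.true_expression
        vols = truth.cell_table.set_index("cell_id")["volume_um3"]
        z = zscore_per_sample(
            volume_normalize(counts, vols), pd.Series("s", index=counts.index)
        )
        res = cluster_cells(z, k=2)
        meta = truth.cell_table.set_index("cell_id")
        out = spatial_map(res, meta)
        pts = out[["cz", "cy", "cx"]].to_numpy()
        same = out["cluster"].to_numpy()[:, None] == out["cluster"].to_numpy()[None, :]
        dists = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        mask = ~np.eye(len(out), dtype=bool)
        assert dists[same & mask].mean() < dists[~same].mean()


class TestGeneDensity:
    def test_symmetric_input_symmetric_density(self):
        vals = np.array([-2.0, -1.0, 1.0, 2.0])
        grid = np.linspace(-5, 5, 101)
        d = gene_density(vals, grid)
        np.testing.assert_allclose(d, d[::-1], atol=1e-12)

    def test_integrates_to_one(self):
        rng = np.random.default_rng(8)
        vals = rng.normal(3, 2, 500)
        grid = np.linspace(-15, 21, 2001)
        d = gene_density(vals, grid)
        assert np.trapezoid(d, grid) == pytest.approx(1.0, abs=1e-3)

    def test_standard_normal_peak_height(self):
        rng = np.random.default_rng(9)
        vals = rng.standard_normal(10_000)
        d = gene_density(vals, np.array([0.0]))
        assert d[0] == pytest.approx(1 / np.sqrt(2 * np.pi), rel=0.05)

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            gene_density(np.array([2.0, 2.0, 2.0]), np.linspace(0, 4, 10))
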