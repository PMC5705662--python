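"""Pixel classification, seeding, watershed and the cell-volume filter."""

import numpy as np
import pandas as pd
import pytest

from sga.geometry import VoxelGeometry
from sga.segment import (
    NoSeedsError,
    cell_table_from_labels,
    extract_features,
    filter_cells_by_volume,
    match_segmentation,
    predict_interior,
    seeds_from_probability,
    train_pixel_classifier,
    watershed_3d,
)

GEOM = VoxelGeometry(13.0, 39.0, 0.5)


def _cells_table(volumes):
    return pd.DataFrame(
        {
            "cell_id": np.arange(1, len(volumes) + 1),
            "volume_um3": np.asarray(volumes, dtype=float),
            "kept": True,
        }
    )


class TestFeatures:
    def test_constant_image_has_zero_gradient_and_laplacian(self):
        feats = extract_features(np.full((8, 16, 16), 7.0), scales=(1.0,), standardize=False)
        # zero up to float32 rounding of the filtered constant (value 7.0)
        np.testing.assert_allclose(feats[..., 1], 0.0, atol=7e-3)
        np.testing.assert_allclose(feats[..., 2], 0.0, atol=7e-3)

    def test_bright_plane_maximizes_gradient_next_to_it(self):
        img = np.zeros((16, 16, 16), dtype=np.float32)
        img[8] = 100.0
        feats = extract_features(img, scales=(1.0,), standardize=False)
        grad = feats[..., 1]
        peak_z = np.unravel_index(np.argmax(grad), grad.shape)[0]
        assert peak_z in (7, 9)

    def test_step_edge_gradient_matches_closed_form(self):
        """A step of height h filtered at scale sigma peaks at h/(sigma*sqrt(2*pi))."""
        h, sigma = 50.0, 2.0
        img = np.zeros((8, 16, 64), dtype=np.float32)
        img[:, :, 32:] = h
        feats = extract_features(img, scales=(sigma,), standardize=False)
        peak = feats[..., 1].max()
        assert peak == pytest.approx(h / (sigma * np.sqrt(2 * np.pi)), rel=0.05)

    def test_subvoxel_scale_warns(self):
        with pytest.warns(UserWarning, match="below voxel size"):
            extract_features(np.zeros((4, 8, 8)), scales=(0.5,))


class TestClassifier:
    @staticmethod
    def _toy(n=200, seed=0):
        """Linearly separable two-feature voxel set embedded in a volume."""
        rng = np.random.default_rng(seed)
        feats = np.zeros((1, 1, n, 2), dtype=np.float32)
        labels = np.full((1, 1, n), -1, dtype=np.int8)
        y = rng.integers(0, 2, n)
        feats[0, 0, :, 0] = y * 4.0 + rng.normal(0, 0.5, n)
        feats[0, 0, :, 1] = rng.normal(0, 1, n)
        labels[0, 0, :] = y
        return feats, labels

    def test_separable_set_high_oob(self):
        feats, labels = self._toy()
        clf = train_pixel_classifier(feats, labels, seed=0)
        assert clf.oob_score_ >= 0.95

    def test_deterministic_given_seed(self):
        feats, labels = self._toy()
        p1 = predict_interior(train_pixel_classifier(feats, labels, seed=1), feats)
        p2 = predict_interior(train_pixel_classifier(feats, labels, seed=1), feats)
        np.testing.assert_array_equal(p1, p2)

    def test_single_class_labels_rejected(self):
        feats, labels = self._toy()
        labels[labels == 0] = -1
        with pytest.raises(ValueError, match="both"):
            train_pixel_classifier(feats, labels)

    def test_probabilities_bounded(self):
        feats, labels = self._toy()
        clf = train_pixel_classifier(feats, labels, seed=0)
        rng = np.random.default_rng(9)
        p = predict_interior(clf, rng.normal(size=(2, 3, 4, 2)).astype(np.float32))
        assert p.min() >= 0.0 and p.max() <= 1.0

    def test_feature_dimension_mismatch_rejected(self):
        feats, labels = self._toy()
        clf = train_pixel_classifier(feats, labels, seed=0)
        with pytest.raises(ValueError, match="dimensionality"):
            predict_interior(clf, np.zeros((1, 1, 5, 3), dtype=np.float32))


class TestSeeds:
    def test_no_signal_raises(self):
        with pytest.raises(NoSeedsError):
            seeds_from_probability(np.zeros((5, 10, 10)), 0.5, 10)

    def test_two_blobs_two_seeds(self):
        prob = np.zeros((6, 20, 20))
        prob[2:5, 2:8, 2:8] = 0.9
        prob[2:5, 12:18, 12:18] = 0.9
        seeds = seeds_from_probability(prob, 0.5, min_seed_voxels=50)
        assert seeds.max() == 2

    def test_size_filter_counts_components(self):
        """Blobs of 10, 60 and 200 voxels with a 50-voxel floor: two seeds."""
        prob = np.zeros((4, 30, 30))
        prob[1, 1:11, 1] = 0.9  # 10 voxels
        prob[1:4, 14:19, 14:18] = 0.9  # 60 voxels
        prob[0:4, 20:30, 24:29] = 0.9  # 200 voxels
        seeds = seeds_from_probability(prob, 0.5, min_seed_voxels=50)
        assert seeds.max() == 2

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValueError):
            seeds_from_probability(np.zeros((2, 2, 2)), 1.5, 1)


class TestWatershed:
    def test_single_seed_floods_everything(self):
        elevation = np.zeros((4, 8, 8))
        seeds = np.zeros((4, 8, 8), dtype=np.int32)
        seeds[2, 4, 4] = 1
        labels = watershed_3d(elevation, seeds)
        assert (labels == 1).all()

    def test_wall_splits_symmetrically(self):
        elevation = np.zeros((4, 8, 21))
        elevation[:, :, 10] = 10.0
        seeds = np.zeros_like(elevation, dtype=np.int32)
        seeds[2, 4, 3] = 1
        seeds[2, 4, 17] = 2
        labels = watershed_3d(elevation, seeds)
        # symmetric catchments either side of the ridge (the ridge column
        # itself ties arbitrarily to one side)
        assert (labels[:, :, :10] == 1).all()
        assert (labels[:, :, 11:] == 2).all()
        assert (labels[:, :, :10] == 1).sum() == (labels[:, :, 11:] == 2).sum()

    def test_touching_spheres_recover_volumes(self):
        """Two touching spheres split by a membrane gap: each catchment's
        volume within 10% of its ground-truth sphere."""
        shape = (24, 24, 44)
        zz, yy, xx = np.indices(shape)
        c1, c2 = (12, 12, 13), (12, 12, 29)
        d1 = np.sqrt((zz - c1[0]) ** 2 + (yy - c1[1]) ** 2 + (xx - c1[2]) ** 2)
        d2 = np.sqrt((zz - c2[0]) ** 2 + (yy - c2[1]) ** 2 + (xx - c2[2]) ** 2)
        truth = np.where(d1 <= 8, 1, np.where(d2 <= 8, 2, 0))
        interior = (truth > 0) & ~((np.abs(d1 - d2) < 1.2) & (truth > 0))
        prob = np.where(interior, 0.95, 0.05)
        seeds = np.zeros(shape, dtype=np.int32)
        seeds[c1] = 1
        seeds[c2] = 2
        labels = watershed_3d(1 - prob, seeds, barrier_mask=prob < 0.2)
        for k in (1, 2):
            assert (labels == k).sum() == pytest.approx((truth == k).sum(), rel=0.10)

    def test_relabeling_invariance(self):
        elevation = np.zeros((4, 8, 21))
        elevation[:, :, 10] = 10.0
        seeds = np.zeros_like(elevation, dtype=np.int32)
        seeds[2, 4, 3] = 1
        seeds[2, 4, 17] = 2
        swapped = seeds.copy()
        swapped[seeds == 1] = 2
        swapped[seeds == 2] = 1
        a = watershed_3d(elevation, seeds)
        b = watershed_3d(elevation, swapped)
        assert np.array_equal(a == 1, b == 2) and np.array_equal(a == 2, b == 1)

    def test_volume_conservation(self, small_truth):
        labels = small_truth.labels
        table = cell_table_from_labels(labels, GEOM)
        assert table["voxel_count"].sum() == (labels > 0).sum()


class TestVolumeFilter:
    def test_equal_volumes_none_excluded(self):
        with pytest.warns(UserWarning, match="MAD"):
            out, excluded = filter_cells_by_volume(_cells_table(np.full(20, 400.0)))
        assert excluded == 0.0 and out["kept"].all()

    def test_gaussian_population_mostly_kept(self):
        rng = np.random.default_rng(5)
        vols = rng.normal(500, 100, 300)
        _, excluded = filter_cells_by_volume(_cells_table(vols))
        assert excluded <= 0.05

    def test_single_huge_cell_is_the_one_excluded(self):
        rng = np.random.default_rng(6)
        vols = rng.normal(500, 100, 299)
        table = _cells_table(np.append(vols, 10 * np.median(vols)))
        out, _ = filter_cells_by_volume(table)
        excluded_ids = out.loc[~out["kept"], "cell_id"].tolist()
        assert excluded_ids == [300]

    def test_tiny_table_skipped_with_diagnostic(self):
        with pytest.warns(UserWarning, match="skipped"):
            _, excluded = filter_cells_by_volume(_cells_table([100, 200, 300]))
        assert excluded == 0.0


def test_segmentation_recovers_cells_on_simulated_tissue(small_truth):
    """Classifier trained on 1% ground-truth voxels + watershed: at least 90%
    of true cells matched one-to-one at IoU >= 0.5, and held-out voxel
    accuracy of the interior map stays above 0.9."""
    from sga.simulate import render_membrane

    truth = small_truth
    membrane = render_membrane(truth, 0)
    feats = extract_features(membrane)
    rng = np.random.default_rng(17)
    sparse = np.full(truth.labels.shape, -1, dtype=np.int8)
    pick = rng.random(truth.labels.shape) < 0.01
    sparse[pick] = (truth.labels[pick] > 0).astype(np.int8)
    clf = train_pixel_classifier(feats, sparse, seed=0)
    prob = predict_interior(clf, feats)

    holdout = (~pick) & (rng.random(truth.labels.shape) < 0.01)
    acc = ((prob[holdout] > 0.5) == (truth.labels[holdout] > 0)).mean()
    assert acc >= 0.9

    min_seed = int(round(30.0 / truth.config.voxel_geometry.voxel_volume_um3))
    seeds = seeds_from_probability(prob, 0.5, min_seed)
    labels = watershed_3d(1.0 - prob, seeds, barrier_mask=prob < 0.2)
    m = match_segmentation(truth.labels, labels, iou_threshold=0.5)
    assert m.matched_fraction >= 0.9
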