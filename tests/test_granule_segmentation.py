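"""Segmentation: features, classifier, shape filtering, clusters, sizes."""

import numpy as np
import pytest

from granuvisc.flim_synth import make_phantom
from granuvisc.granule_segmentation import (
    GranuleRecord,
    classify_clusters,
    compare_size_distributions,
    components_from_mask,
    compute_features,
    measure_granules,
    segment,
    size_distribution,
    train_classifier,
)


def disk_mask(shape, center, radius):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


def synthetic_intensity(shape, disks, fg=500.0, bg=25.0, seed=0):
    rng = np.random.default_rng(seed)
    img = np.full(shape, bg)
    for c, r in disks:
        img[disk_mask(shape, c, r)] = fg
    return rng.poisson(img).astype(float)


@pytest.fixture(scope="module")
def trained_classifier():
    """Classifier trained on one high-contrast disk image with known truth."""
    disks = [((20, 20), 5), ((50, 30), 4), ((30, 60), 6), ((70, 70), 5)]
    img = synthetic_intensity((96, 96), disks, seed=1)
    truth = np.zeros((96, 96), bool)
    for c, r in disks:
        truth |= disk_mask((96, 96), c, r)
    labels = np.where(truth, 1, 2).astype(np.uint8)
    return train_classifier([compute_features(img)], [labels], seed=0)


class TestFeatures:
    def test_constant_image_flat_derivative_features(self):
        stack = compute_features(np.full((32, 32), 7.0))
        names = list(stack.names)
        grad = stack.features[..., names.index("gradient")]
        lap = stack.features[..., names.index("laplacian")]
        var = stack.features[..., names.index("local_variance")]
        assert np.all(grad == 0) and np.all(lap == 0) and np.all(var == 0)

    def test_gradient_peaks_on_disk_rim(self):
        img = np.where(disk_mask((64, 64), (32, 32), 10), 500.0, 25.0)
        stack = compute_features(img)
        grad = stack.features[..., list(stack.names).index("gradient")]
        r_peak = np.hypot(*(np.array(np.unravel_index(grad.argmax(), grad.shape)) - 32))
        assert r_peak == pytest.approx(10.0, abs=1.5)

    def test_deterministic(self):
        rng = np.random.default_rng(0)
        img = rng.poisson(100, (48, 48)).astype(float)
        np.testing.assert_array_equal(
            compute_features(img).features, compute_features(img).features
        )

    def test_non_2d_rejected(self):
        with pytest.raises(ValueError):
            compute_features(np.zeros((4, 4, 4)))


class TestClassifier:
    def test_high_contrast_phantom_accuracy(self, trained_classifier):
        assert trained_classifier.holdout_accuracy >= 0.95

    def test_same_seed_identical_predictions(self, trained_classifier):
        probe = synthetic_intensity((64, 64), [((32, 32), 6)], seed=5)
        stack = compute_features(probe)
        disks = [((20, 20), 5), ((50, 30), 4), ((30, 60), 6), ((70, 70), 5)]
        img = synthetic_intensity((96, 96), disks, seed=1)
        truth = np.zeros((96, 96), bool)
        for c, r in disks:
            truth |= disk_mask((96, 96), c, r)
        labels = np.where(truth, 1, 2).astype(np.uint8)
        clf2 = train_classifier([compute_features(img)], [labels], seed=0)
        np.testing.assert_array_equal(
            trained_classifier.predict(stack), clf2.predict(stack)
        )

    def test_swapped_labels_invert_predictions(self):
        disks = [((20, 20), 5), ((40, 44), 6)]
        img = synthetic_intensity((64, 64), disks, seed=2)
        truth = np.zeros((64, 64), bool)
        for c, r in disks:
            truth |= disk_mask((64, 64), c, r)
        labels = np.where(truth, 1, 2).astype(np.uint8)
        swapped = np.where(truth, 2, 1).astype(np.uint8)
        stack = compute_features(img)
        a = train_classifier([stack], [labels], seed=0).predict(stack)
        b = train_classifier([stack], [swapped], seed=0).predict(stack)
        # label swap flips the decision for (virtually) every pixel; allow a
        # handful of probability ties at the decision boundary
        assert np.mean(a == ~b) >= 0.99

    def test_single_class_labels_rejected(self):
        img = synthetic_intensity((48, 48), [((24, 24), 5)], seed=3)
        labels = np.where(disk_mask((48, 48), (24, 24), 5), 1, 0).astype(np.uint8)
        with pytest.raises(ValueError):
            train_classifier([compute_features(img)], [labels], seed=0)


class TestSegment:
    def test_well_separated_disks_all_accepted(self, trained_classifier):
        rng = np.random.default_rng(9)
        centers = [(r, c) for r in range(12, 180, 24) for c in range(12, 180, 24)][:30]
        disks = [(c, 4) for c in centers]
        img = synthetic_intensity((192, 192), disks, seed=4)
        mask = segment(trained_classifier, img)
        assert len(mask.accepted_ids) == 30

    def test_line_object_rejected_for_circularity(self, trained_classifier):
        img = np.full((64, 64), 25.0)
        img[30, 10:40] = 500.0  # 1-px-wide, 30-px-long line
        img = np.random.default_rng(0).poisson(img).astype(float)
        mask = segment(trained_classifier, img)
        assert len(mask.accepted_ids) == 0
        assert "circularity" in mask.rejected.values()

    def test_rasterised_disk_circularity_above_0_9(self):
        fg = disk_mask((48, 48), (24, 24), 10)
        mask = components_from_mask(fg)
        recs = measure_granules(mask)
        assert len(recs) == 1
        assert recs[0].circularity >= 0.9

    @pytest.mark.parametrize("radius", [3, 5, 8, 12, 20])
    def test_circularity_scale_invariant_on_disks(self, radius):
        n = 4 * radius + 10
        fg = disk_mask((n, n), (n // 2, n // 2), radius)
        recs = measure_granules(components_from_mask(fg))
        assert recs and recs[0].circularity >= 0.85

    def test_accept_plus_reject_partition(self, trained_classifier):
        img = synthetic_intensity(
            (96, 96), [((20, 20), 5), ((60, 60), 4)], seed=6
        )
        img[80, 10:40] = 500.0
        mask = segment(trained_classifier, img)
        n_components = len(np.unique(mask.labels)) - 1
        assert len(mask.accepted_ids) + len(mask.rejected) == n_components

    def test_empty_foreground_is_empty_result(self, trained_classifier):
        img = np.random.default_rng(1).poisson(25.0, (48, 48)).astype(float)
        mask = segment(trained_classifier, img)
        assert len(mask.accepted_ids) == 0


class TestClusters:
    def test_near_tangent_disks_share_cluster(self):
        fg = disk_mask((48, 48), (24, 16), 5) | disk_mask((48, 48), (24, 28), 5)
        mask = classify_clusters(components_from_mask(fg))
        recs = measure_granules(mask)
        assert len(recs) == 2
        assert all(r.clustered for r in recs)
        assert recs[0].cluster_id == recs[1].cluster_id

    def test_isolated_disk_is_individual(self):
        fg = disk_mask((48, 48), (24, 24), 5)
        recs = measure_granules(classify_clusters(components_from_mask(fg)))
        assert not recs[0].clustered and recs[0].cluster_id is None

    def test_merged_blob_flagged_as_aggregate_candidate(self):
        # several small accepted disks set the median; one big merged pair
        fg = np.zeros((96, 96), bool)
        for c in [(15, 15), (15, 60), (60, 15)]:
            fg |= disk_mask((96, 96), c, 4)
        fg |= disk_mask((96, 96), (70, 60), 8) | disk_mask((96, 96), (70, 74), 8)
        mask = classify_clusters(components_from_mask(fg))
        assert len(mask.aggregate_candidates) == 1

    def test_generator_cluster_fraction_recovered(self):
        """Segmentation-side cluster annotation matches the generator's
        ground-truth clustered fraction within 10 points (a few seeds)."""
        diffs = []
        for seed in range(3):
            phantom, truth = make_phantom("nonCF", 40, frame=(160, 160), seed=seed)
            truth_frac = np.mean([g.cluster_id is not None for g in phantom.granules])
            mask = classify_clusters(components_from_mask(truth.granule_label_map > 0))
            recs = measure_granules(mask)
            seg_frac = np.mean([r.clustered for r in recs])
            diffs.append(abs(seg_frac - truth_frac))
        assert np.mean(diffs) <= 0.10


class TestSizeDistribution:
    def _records(self, diameters):
        return [
            GranuleRecord(
                granule_id=i,
                area=np.pi * (d / 2) ** 2,
                perimeter=np.pi * d,
                circularity=1.0,
                centroid=(0.0, 0.0),
                equivalent_diameter=float(d),
            )
            for i, d in enumerate(diameters)
        ]

    def test_identical_radii_zero_iqr(self):
        s = size_distribution(self._records([6, 6, 6, 6]))
        assert s["iqr"] == 0.0

    def test_median_of_three(self):
        assert size_distribution(self._records([4, 6, 8]))["median"] == 6.0

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            size_distribution([])

    def test_ks_distance_zero_for_identical_sets(self):
        recs = self._records([4, 5, 6, 7])
        assert compare_size_distributions(recs, recs)["ks_distance"] == 0.0
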