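import numpy as np
import pytest

from ccparc import clustering
from ccparc.clustering import ClassModel, ClusterMap
from ccparc.phantoms import make_plateau_image


def model_from_centers(centers, sigma):
    """Pure-centroid PNN model: one pattern unit per class."""
    centers = np.asarray(centers, dtype=float)
    return ClassModel(
        k=centers.size,
        centers=centers,
        sigma=sigma,
        pattern_units=[np.array([c]) for c in centers],
    )


def pnn_oracle(x, model):
    """Direct summation of per-class kernel densities, no vectorization tricks."""
    scores = []
    for units in model.pattern_units:
        s = sum(
            np.exp(-((x - u) ** 2) / (2 * model.sigma**2)) for u in units
        ) / len(units)
        scores.append(s)
    return int(np.argmax(scores)) + 1


class TestKMeans:
    def test_separated_clusters_recovered_exactly(self):
        img = np.array([[0.0, 0.0, 0.0, 1.0, 1.0, 1.0]] * 2)
        m = clustering.kmeans_centers(img, 2, seed=0)
        np.testing.assert_allclose(m.centers, [0.0, 1.0])

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError):
            clustering.kmeans_centers(np.linspace(0, 1, 36).reshape(6, 6), 1, seed=0)

    def test_k_exceeding_distinct_intensities_rejected(self):
        img = np.array([[0.0, 1.0]] * 4)
        with pytest.raises(ValueError, match="distinct"):
            clustering.kmeans_centers(img, 3, seed=0)

    def test_two_gaussian_means_recovered(self):
        rng = np.random.default_rng(1)
        x = np.concatenate(
            [rng.normal(0.2, 0.05, 100), rng.normal(0.8, 0.05, 100)]
        ).reshape(10, 20)
        m = clustering.kmeans_centers(np.clip(x, 0, 1), 2, seed=1)
        assert abs(m.centers[0] - 0.2) < 0.03
        assert abs(m.centers[1] - 0.8) < 0.03

    def test_deterministic_given_seed(self):
        img = make_plateau_image([0.1, 0.5, 0.9], noise_sigma=0.05, seed=4)
        a = clustering.kmeans_centers(img, 3, seed=9)
        b = clustering.kmeans_centers(img, 3, seed=9)
        np.testing.assert_array_equal(a.centers, b.centers)


class TestPNN:
    def test_pixel_at_centroid_gets_that_class(self):
        m = model_from_centers([0.1, 0.45, 0.9], sigma=0.1)
        img = np.full((4, 4), 0.45)
        assert (clustering.pnn_classify(img, m).labels == 2).all()

    def test_equidistant_pixel_breaks_tie_to_lower_class(self):
        m = model_from_centers([0.25, 0.75], sigma=0.1)  # exactly representable
        img = np.full((4, 4), 0.5)
        assert (clustering.pnn_classify(img, m).labels == 1).all()

    def test_matches_direct_summation_oracle(self):
        m = model_from_centers([0.1, 0.45, 0.9], sigma=0.1)
        img = np.linspace(0, 1, 64).reshape(8, 8)
        got = clustering.pnn_classify(img, m).labels
        want = np.array([[pnn_oracle(v, m) for v in row] for row in img])
        np.testing.assert_array_equal(got, want)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(5)
        img = np.clip(rng.normal(0.5, 0.25, (12, 12)), 0, 1)
        m = clustering.kmeans_centers(img, 3, seed=0)
        base = clustering.pnn_classify(img, m).labels
        perm = [2, 0, 1]  # new class c holds old class perm[c]
        m2 = ClassModel(
            k=3,
            centers=m.centers[perm],
            sigma=m.sigma,
            pattern_units=[m.pattern_units[p] for p in perm],
        )
        relabelled = clustering.pnn_classify(img, m2).labels
        inverse = np.argsort(perm)  # old class o now sits at index inverse[o]
        np.testing.assert_array_equal(relabelled, inverse[base - 1] + 1)

    def test_full_coverage(self):
        img = make_plateau_image([0.2, 0.8], noise_sigma=0.05, seed=0)
        m = clustering.kmeans_centers(img, 2, seed=0)
        lab = clustering.pnn_classify(img, m).labels
        assert set(np.unique(lab)) <= {1, 2}
        assert (lab > 0).all()


class TestVmep:
    def test_two_flat_regions_score_higher_as_two_classes(self):
        img = make_plateau_image([0.2, 0.8], size=(16, 16), noise_sigma=0.0)
        two = ClusterMap(labels=(img > 0.5).astype(int) + 1, k=2)
        three = two.labels.copy()
        three[:8][img[:8] > 0.5] = 3  # split one flat region spatially
        three = ClusterMap(labels=three, k=3)
        assert clustering.vmep_score(two, img) > clustering.vmep_score(three, img)

    def test_deterministic(self):
        img = make_plateau_image([0.1, 0.9], noise_sigma=0.03, seed=1)
        cm = ClusterMap(labels=(img > 0.5).astype(int) + 1, k=2)
        assert clustering.vmep_score(cm, img) == clustering.vmep_score(cm, img)

    def test_empty_class_rejected(self):
        img = make_plateau_image([0.1, 0.9], size=(16, 16))
        cm = ClusterMap(labels=np.ones_like(img, dtype=int), k=2)
        with pytest.raises(ValueError, match="empty"):
            clustering.vmep_score(cm, img)

    def test_single_class_rejected(self):
        img = make_plateau_image([0.1, 0.9], size=(16, 16))
        cm = ClusterMap(labels=np.ones_like(img, dtype=int), k=1)
        with pytest.raises(ValueError):
            clustering.vmep_score(cm, img)


class TestSelection:
    def test_empty_range_rejected(self):
        img = make_plateau_image([0.1, 0.9], noise_sigma=0.02)
        with pytest.raises(ValueError, match="empty"):
            clustering.select_num_classes(img, (4, 3), seed=0)

    def test_range_outside_bounds_rejected(self):
        img = make_plateau_image([0.1, 0.9], noise_sigma=0.02)
        with pytest.raises(ValueError):
            clustering.select_num_classes(img, (1, 4), seed=0)

    def test_three_plateaus_select_three_classes(self):
        img = make_plateau_image([0.1, 0.5, 0.9], noise_sigma=0.02, seed=11)
        cm = clustering.select_num_classes(img, (2, 6), seed=11)
        assert cm.k == 3
        assert cm.vmep is not None and np.isfinite(cm.vmep)

    def test_two_plateaus_select_two_classes(self):
        img = make_plateau_image([0.2, 0.8], noise_sigma=0.02, seed=11)
        assert clustering.select_num_classes(img, (2, 5), seed=11).k == 2
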