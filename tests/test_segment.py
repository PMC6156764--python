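import numpy as np
import pytest
from scipy import ndimage as ndi

from eduscan.segment import (
    DegenerateImageError,
    DoGParams,
    SegmentationParams,
    dog_filter,
    filter_regions,
    hybrid_watershed,
    kmeans_threshold,
    segment_nuclei,
)
from eduscan.simulate import SimulationConfig, simulate_field

# ------------------------------------------------------------------ oracles


def brute_force_gaussian_kernel(sigma: float, radius: int) -> np.ndarray:
    """Dense normalized Gaussian kernel as scipy truncates it (radius taps)."""
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    g = np.exp(-(x**2) / (2 * sigma**2))
    g /= g.sum()
    return np.outer(g, g)


def exhaustive_two_means_split(values: np.ndarray, counts: np.ndarray) -> int:
    """Try every ordered split of the sorted unique values; return the index
    of the first upper-cluster value minimizing total within-cluster SSE."""
    best_sse, best_i = np.inf, None
    for i in range(1, len(values)):
        sse = 0.0
        for v, c, in_lower in [(values[:i], counts[:i], True), (values[i:], counts[i:], False)]:
            mu = np.average(v, weights=c)
            sse += float(np.sum(c * (v - mu) ** 2))
        if sse < best_sse:
            best_sse, best_i = sse, i
    return best_i


def oracle_mask(image: np.ndarray) -> np.ndarray:
    values, counts = np.unique(image.ravel(), return_counts=True)
    i = exhaustive_two_means_split(values, counts)
    return image >= values[i]


# --------------------------------------------------------------- dog_filter


def test_dog_of_constant_image_is_zero():
    img = np.full((64, 64), 137.0)
    out = dog_filter(img, DoGParams(1.0, 4.0))
    assert np.allclose(out, 0.0, atol=1e-9)


def test_dog_is_linear(rng):
    img = rng.uniform(0, 100, (32, 32))
    p = DoGParams(1.0, 3.0)
    np.testing.assert_allclose(dog_filter(2 * img, p), 2 * dog_filter(img, p),
                               rtol=1e-10, atol=1e-10)


def test_dog_impulse_response_matches_dense_convolution_oracle():
    # scipy truncates each Gaussian at radius = round(truncate * sigma)
    n = 41
    img = np.zeros((n, n))
    img[n // 2, n // 2] = 1.0
    out = dog_filter(img, DoGParams(1.0, 2.0))
    truncate = 4.0
    k_low = brute_force_gaussian_kernel(1.0, round(truncate * 1.0))
    k_high = brute_force_gaussian_kernel(2.0, round(truncate * 2.0))
    expected = np.zeros((n, n))
    for k, sign in ((k_low, 1.0), (k_high, -1.0)):
        r = k.shape[0] // 2
        c = n // 2
        expected[c - r:c + r + 1, c - r:c + r + 1] += sign * k
    np.testing.assert_allclose(out, expected, atol=1e-12)


def test_dog_mean_near_zero_on_large_constant_background(rng):
    img = np.full((256, 256), 500.0)
    out = dog_filter(img, DoGParams(1.0, 10.0))
    interior = out[40:-40, 40:-40]
    assert abs(interior.mean()) < 1e-6 * 500.0


def test_dog_sigma_order_enforced():
    with pytest.raises(ValueError):
        dog_filter(np.zeros((8, 8)), DoGParams(3.0, 1.0))


# --------------------------------------------------------- kmeans_threshold


def test_two_point_distribution_thresholds_exactly():
    rng = np.random.default_rng(0)
    img = np.full((50, 50), 10.0)
    bright = rng.random((50, 50)) < 0.1
    img[bright] = 200.0
    thr, mask = kmeans_threshold(img)
    assert 10.0 < thr < 200.0
    assert np.array_equal(mask, bright)


def test_six_value_sample_splits_between_3_and_10():
    img = np.array([[1.0, 2.0, 3.0], [10.0, 11.0, 12.0]])
    thr, mask = kmeans_threshold(img)
    assert 3.0 < thr < 10.0
    assert np.array_equal(mask, img >= 10.0)


@pytest.mark.parametrize("seed", range(8))
def test_mask_matches_exhaustive_split_oracle_on_random_images(seed):
    rng = np.random.default_rng(seed)
    # bimodal-ish random image with discrete levels
    img = np.where(
        rng.random((64, 64)) < 0.3,
        rng.integers(120, 255, (64, 64)),
        rng.integers(0, 100, (64, 64)),
    ).astype(np.float64)
    _, mask = kmeans_threshold(img)
    assert np.array_equal(mask, oracle_mask(img))


def test_constant_image_is_degenerate():
    with pytest.raises(DegenerateImageError):
        kmeans_threshold(np.full((16, 16), 7.0))


def test_three_cluster_foreground_is_brightest_cluster_only():
    rng = np.random.default_rng(3)
    img = rng.choice([5.0, 100.0, 200.0], p=[0.7, 0.2, 0.1], size=(64, 64))
    thr, mask = kmeans_threshold(img, k_clusters=3)
    assert np.array_equal(mask, img == 200.0)
    assert 100.0 < thr < 200.0


# --------------------------------------------------------- hybrid_watershed


def disc_mask(shape, center, radius):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return np.hypot(yy - center[0], xx - center[1]) <= radius


def test_single_disc_yields_one_label():
    mask = disc_mask((64, 64), (32, 32), 12)
    labels = hybrid_watershed(np.ones((64, 64)), mask)
    assert labels.max() == 1
    assert np.array_equal(labels > 0, mask)


def test_fused_discs_are_split_into_two_comparable_halves():
    mask = disc_mask((64, 64), (32, 25), 10) | disc_mask((64, 64), (32, 39), 10)
    labels = hybrid_watershed(np.ones((64, 64)), mask)
    assert labels.max() == 2
    disc_area = np.pi * 10**2
    for lab in (1, 2):
        assert abs((labels == lab).sum() - disc_area) / disc_area < 0.15

    # flooding oracle: nearest distance-transform maximum wins
    dist = ndi.distance_transform_edt(mask)
    maxima = [(32, 25), (32, 39)]
    yy, xx = np.nonzero(mask)
    owner = np.argmin(
        [np.hypot(yy - m[0], xx - m[1]) for m in maxima], axis=0
    )
    agree = 0
    left_label = labels[32, 25]
    for (y, x), o in zip(zip(yy, xx), owner):
        expected = left_label if o == 0 else (3 - left_label)
        agree += labels[y, x] == expected
    assert agree / len(yy) > 0.95


def test_empty_mask_gives_zero_labels():
    labels = hybrid_watershed(np.ones((32, 32)), np.zeros((32, 32), bool))
    assert labels.max() == 0


def test_labels_partition_the_mask(noisy_field):
    _, channels, _ = noisy_field
    f = dog_filter(channels["dapi"], DoGParams())
    _, mask = kmeans_threshold(f)
    labels = hybrid_watershed(channels["dapi"], mask)
    assert np.array_equal(labels > 0, mask)


# ----------------------------------------------------------- filter_regions


def test_dim_region_removed():
    labels = np.zeros((20, 20), int)
    labels[5:10, 5:10] = 1
    img = np.full((20, 20), 50.0)
    out = filter_regions(labels, img, SegmentationParams(min_mean_intensity=60.0,
                                                         min_region_area=1))
    assert out.max() == 0


def test_vacuous_filter_is_identity():
    rng = np.random.default_rng(5)
    labels, _ = ndi.label(rng.random((40, 40)) < 0.2)
    img = rng.uniform(1, 100, (40, 40))
    out = filter_regions(labels, img, SegmentationParams(min_mean_intensity=0.0,
                                                         min_region_area=1))
    assert np.array_equal(out, labels)


def test_filter_matches_per_region_brute_force(rng):
    labels, n = ndi.label(rng.random((60, 60)) < 0.3)
    img = rng.uniform(0, 100, (60, 60))
    params = SegmentationParams(min_mean_intensity=45.0, min_region_area=3)
    out = filter_regions(labels, img, params)
    surviving_in = set()
    for lab in range(1, n + 1):
        pix = labels == lab
        if pix.sum() >= 3 and img[pix].mean() >= 45.0:
            surviving_in.add(lab)
    # survivors map 1:1 onto contiguous output labels, order preserved
    out_ids = set(np.unique(out)) - {0}
    assert len(out_ids) == len(surviving_in)
    for new, old in zip(sorted(out_ids), sorted(surviving_in)):
        assert np.array_equal(out == new, labels == old)


@pytest.mark.parametrize("param,values", [
    ("min_mean_intensity", [0.0, 30.0, 60.0, 90.0]),
    ("min_region_area", [1, 5, 20, 80]),
])
def test_nucleus_count_monotone_in_filters(rng, param, values):
    labels, _ = ndi.label(rng.random((80, 80)) < 0.25)
    img = rng.uniform(0, 100, (80, 80))
    counts = []
    for v in values:
        p = SegmentationParams(**{param: v})
        counts.append(filter_regions(labels, img, p).max())
    assert counts == sorted(counts, reverse=True)


# ----------------------------------------------------------- segment_nuclei


def test_clean_field_recovered_with_subpixel_centroids():
    cfg = SimulationConfig(
        image_shape=(300, 300), n_cells=20, touching_fraction=0.0,
        noise_sd=0.0, background_amplitude=0.0, seed=21,
    )
    channels, truth = simulate_field(cfg)
    labels = segment_nuclei(channels["dapi"])
    assert labels.max() == 20
    centroids = np.asarray(
        ndi.center_of_mass(np.ones_like(labels), labels, np.arange(1, 21))
    )
    true_pts = truth.cells[["row", "col"]].to_numpy()
    # match each true center to nearest detected centroid
    for pt in true_pts:
        d = np.min(np.hypot(*(centroids - pt).T))
        assert d < 2.0


def test_blank_image_raises_degenerate():
    with pytest.raises(DegenerateImageError):
        segment_nuclei(np.full((64, 64), 42.0))


def test_fused_pairs_resolved_in_noise_free_field():
    cfg = SimulationConfig(
        image_shape=(400, 400), n_cells=100, touching_fraction=0.1,
        noise_sd=0.0, background_amplitude=0.0, seed=7,
    )
    channels, truth = simulate_field(cfg)
    labels = segment_nuclei(channels["dapi"])
    assert labels.max() == truth.n_cells
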