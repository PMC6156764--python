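"""Nucleus detection: DoG filtering, k-means thresholding, hybrid watershed.

The detector runs four stages on the DAPI channel:

1. a difference-of-Gaussian (DoG) band-pass filter — a narrow blur minus a
   wide blur — suppressing both pixel noise and smooth background;
2. adaptive thresholding by k-means clustering of the filtered intensities
   (k=2 by default), keeping the brightest cluster as foreground;
3. a hybrid watershed: the Euclidean distance transform of the foreground
   mask is smoothed, h-maxima act as markers, and marker-controlled
   watershed flooding on the inverted distance transform splits fused
   nuclei;
4. a post-filter that discards candidate regions whose mean intensity in
   the source image falls below a minimum (and regions below a minimum
   area), then relabels contiguously.

For k=2 the clustering is solved exactly by exhaustive split-point search
over the sorted unique intensities, which minimizes the identical
within-cluster sum of squares objective without any initialization
nondeterminism.  For k>2 an exact dynamic program runs on a quantized
histogram.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import h_maxima
from skimage.segmentation import watershed


class DegenerateImageError(ValueError):
    """Raised when an image admits no threshold (e.g. it is constant)."""


@dataclass
class DoGParams:
    """Sigmas (pixels) of the two Gaussian blurs; ``sigma_low`` keeps fine
    structure, ``sigma_high`` estimates the background that is subtracted."""

    sigma_low: float = 1.0
    sigma_high: float = 15.0

    def validate(self) -> None:
        if not 0 < self.sigma_low < self.sigma_high:
            raise ValueError(
                f"require 0 < sigma_low < sigma_high, got "
                f"({self.sigma_low}, {self.sigma_high})"
            )


@dataclass
class SegmentationParams:
    """Thresholding and region-filter settings.

    ``min_mean_intensity`` is the minimum average source-image intensity a
    candidate region must reach to be accepted as a nucleus; the default is
    calibrated on the synthetic generator's intensity scale.
    """

    k_clusters: int = 2
    min_mean_intensity: float = 1000.0
    min_region_area: int = 40
    clear_border: bool = False
    marker_h: float = 0.5  # h-maxima depth (px of distance) for watershed markers
    marker_smoothing: float = 0.5  # Gaussian sigma applied to the distance map

    def validate(self) -> None:
        if self.k_clusters < 2:
            raise ValueError("k_clusters must be >= 2")
        if self.min_mean_intensity < 0:
            raise ValueError("min_mean_intensity must be >= 0")
        if self.min_region_area < 1:
            raise ValueError("min_region_area must be >= 1")


def dog_filter(image: np.ndarray, params: DoGParams) -> np.ndarray:
    """Band-pass the image: blur(sigma_low) - blur(sigma_high).

    Output is signed float64 with the input's shape; a constant image maps
    to (numerically) zero everywhere.
    """
    params.validate()
    img = np.asarray(image, dtype=np.float64)
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite values")
    low = ndi.gaussian_filter(img, params.sigma_low, mode="nearest")
    high = ndi.gaussian_filter(img, params.sigma_high, mode="nearest")
    return low - high


def _split_two_clusters(values: np.ndarray, counts: np.ndarray) -> int:
    """Exact 1-D 2-means on weighted sorted unique values.

    Returns the index of the first value in the upper cluster; minimizes the
    total within-cluster sum of squares over all n-1 ordered splits using
    prefix sums.
    """
    w = counts.astype(np.float64)
    wx = w * values
    wx2 = w * values**2
    cw = np.cumsum(w)
    cwx = np.cumsum(wx)
    cwx2 = np.cumsum(wx2)
    tot_w, tot_wx, tot_wx2 = cw[-1], cwx[-1], cwx2[-1]

    # candidate splits: lower cluster = values[:i], i in 1..n-1
    i = np.arange(1, len(values))
    lw, lwx, lwx2 = cw[i - 1], cwx[i - 1], cwx2[i - 1]
    rw, rwx, rwx2 = tot_w - lw, tot_wx - lwx, tot_wx2 - lwx2
    sse = (lwx2 - lwx**2 / lw) + (rwx2 - rwx**2 / rw)
    return int(i[np.argmin(sse)])


def _kmeans_1d_dp(values: np.ndarray, counts: np.ndarray, k: int) -> list[int]:
    """Exact weighted 1-D k-means via dynamic programming over split points.

    Returns the start indices of clusters 1..k-1 (cluster 0 starts at 0).
    O(k * n^2); callers quantize large inputs first.
    """
    n = len(values)
    w = counts.astype(np.float64)
    cw = np.concatenate([[0.0], np.cumsum(w)])
    cwx = np.concatenate([[0.0], np.cumsum(w * values)])
    cwx2 = np.concatenate([[0.0], np.cumsum(w * values**2)])

    def sse(a: int, b: int) -> float:  # [a, b)
        ww = cw[b] - cw[a]
        if ww <= 0:
            return np.inf
        s = cwx[b] - cwx[a]
        s2 = cwx2[b] - cwx2[a]
        return s2 - s * s / ww

    INF = np.inf
    cost = np.full((k + 1, n + 1), INF)
    back = np.zeros((k + 1, n + 1), dtype=int)
    cost[0, 0] = 0.0
    for j in range(1, k + 1):
        for b in range(j, n + 1):
            best, arg = INF, 0
            for a in range(j - 1, b):
                c = cost[j - 1, a] + sse(a, b)
                if c < best:
                    best, arg = c, a
            cost[j, b] = best
            back[j, b] = arg
    starts = []
    b = n
    for j in range(k, 0, -1):
        a = back[j, b]
        starts.append(a)
        b = a
    return sorted(starts)[1:]  # drop the leading 0


def kmeans_threshold(image: np.ndarray, k_clusters: int = 2):
    """Adaptive threshold via k-means clustering of the intensities.

    Pixels are partitioned into ``k_clusters`` intensity clusters minimizing
    the within-cluster sum of squares; the mask keeps the brightest cluster
    only.  The returned threshold is the midpoint between the two cluster
    boundary values adjacent to the foreground split, so
    ``mask == (image > threshold)``.

    Raises
    ------
    DegenerateImageError
        If the image is constant (fewer distinct values than clusters).
    """
    if k_clusters < 2:
        raise ValueError("k_clusters must be >= 2")
    img = np.asarray(image, dtype=np.float64)
    values, counts = np.unique(img.ravel(), return_counts=True)
    if len(values) < k_clusters:
        raise DegenerateImageError(
            f"image has {len(values)} distinct value(s); "
            f"cannot form {k_clusters} clusters"
        )
    if k_clusters == 2:
        split = _split_two_clusters(values, counts)
    else:
        if len(values) > 1024:
            # quantize to a fixed histogram so the DP stays tractable
            edges = np.linspace(values[0], values[-1], 1025)
            idx = np.clip(np.digitize(img.ravel(), edges[1:-1]), 0, 1023)
            counts = np.bincount(idx, minlength=1024)
            centers = 0.5 * (edges[:-1] + edges[1:])
            keep = counts > 0
            values, counts = centers[keep], counts[keep]
        splits = _kmeans_1d_dp(values, counts, k_clusters)
        split = splits[-1]  # only the brightest cluster is foreground
    threshold = 0.5 * (values[split - 1] + values[split])
    mask = img > threshold
    return float(threshold), mask


def hybrid_watershed(source_image: np.ndarray, mask: np.ndarray,
                     marker_h: float = 0.5, marker_smoothing: float = 0.5) -> np.ndarray:
    """Split the foreground mask into labeled nuclei.

    The Euclidean distance transform of the mask is smoothed and its
    h-maxima (depth ``marker_h``) seed a marker-controlled watershed on the
    inverted distance map.  Every foreground pixel receives exactly one
    label; fused nuclei are cut along the watershed line between their
    distance maxima.  An empty mask yields an empty (all-zero) label map.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != np.shape(source_image):
        raise ValueError("mask and source image shapes differ")
    labels = np.zeros(mask.shape, dtype=np.int32)
    if not mask.any():
        return labels
    dist = ndi.distance_transform_edt(mask)
    if marker_smoothing > 0:
        dist = ndi.gaussian_filter(dist, marker_smoothing)
    peaks = h_maxima(dist, marker_h)
    markers, n_markers = ndi.label(peaks)
    if n_markers == 0:
        # mask too thin for the h criterion: fall back to connected components
        labels, _ = ndi.label(mask)
        return labels.astype(np.int32)
    labels = watershed(-dist, markers, mask=mask)
    return labels.astype(np.int32)


def filter_regions(labels: np.ndarray, intensity_image: np.ndarray,
                   params: SegmentationParams) -> np.ndarray:
    """Keep regions with mean source intensity >= ``min_mean_intensity`` and
    area >= ``min_region_area``; relabel survivors contiguously (1..n, in
    ascending original-label order)."""
    params.validate()
    labels = np.asarray(labels)
    if labels.shape != np.shape(intensity_image):
        raise ValueError("labels and intensity image shapes differ")
    out = np.zeros_like(labels, dtype=np.int32)
    ids = np.unique(labels)
    ids = ids[ids > 0]
    if ids.size == 0:
        return out
    img = np.asarray(intensity_image, dtype=np.float64)
    means = ndi.mean(img, labels=labels, index=ids)
    areas = ndi.sum_labels(np.ones_like(labels, dtype=np.float64), labels=labels, index=ids)
    keep = (means >= params.min_mean_intensity) & (areas >= params.min_region_area)
    survivors = ids[keep]
    if params.clear_border and survivors.size:
        border = np.concatenate(
            [labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]]
        )
        touching = np.unique(border)
        survivors = survivors[~np.isin(survivors, touching)]
    lut = np.zeros(int(labels.max()) + 1, dtype=np.int32)
    lut[survivors] = np.arange(1, len(survivors) + 1, dtype=np.int32)
    out = lut[labels]
    return out


def segment_nuclei(image: np.ndarray, dog: DoGParams | None = None,
                   seg: SegmentationParams | None = None) -> np.ndarray:
    """Full nucleus detector: DoG -> k-means threshold -> hybrid watershed ->
    mean-intensity/area filter.  The watershed splits the thresholded mask;
    the intensity filter is evaluated on the *source* image."""
    dog = dog or DoGParams()
    seg = seg or SegmentationParams()
    dog.validate()
    seg.validate()
    filtered = dog_filter(image, dog)
    _, mask = kmeans_threshold(filtered, seg.k_clusters)
    labels = hybrid_watershed(image, mask, seg.marker_h, seg.marker_smoothing)
    return filter_regions(labels, image, seg)
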