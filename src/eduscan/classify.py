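"""Per-nucleus channel measurement and transfected / proliferating calls.

Flag (transfection marker) intensity is measured on the identically
DoG-preprocessed Flag channel, restricted to the nucleus positions from the
DAPI segmentation (optionally dilated); the nuclear EdU marker is measured
directly over the nucleus regions.  The transfection threshold is selected
automatically from the bimodal Flag intensity distribution, with a
percentile fallback when no bimodality is detected, and may always be
overridden manually.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from eduscan.segment import DoGParams, dog_filter, _split_two_clusters


@dataclass
class ClassifyParams:
    """Thresholds for the per-cell calls.

    ``flag_threshold`` separates the two modes of the marker distribution
    ("auto" selects it from the data); ``flag_min_intensity`` and
    ``edu_min_intensity`` are minimum mean intensities analogous to the
    nucleus acceptance filter.  Transfection uses a strict ``>`` at the
    distribution threshold; the minimum-intensity filters are inclusive
    (``>=``).
    """

    flag_threshold: float | str = "auto"
    edu_min_intensity: float = 2000.0
    flag_min_intensity: float = 0.0
    fallback_percentile: float = 75.0
    flag_dilation_px: int = 0

    def validate(self) -> None:
        if self.flag_threshold != "auto" and float(self.flag_threshold) < 0:
            raise ValueError("flag_threshold must be >= 0 or 'auto'")
        if self.edu_min_intensity < 0 or self.flag_min_intensity < 0:
            raise ValueError("minimum intensities must be >= 0")


def measure_channels(
    nuclei: np.ndarray,
    flag_image: np.ndarray,
    edu_image: np.ndarray,
    dog: DoGParams | None = None,
    dapi_image: np.ndarray | None = None,
    pixel_size: float | None = None,
    flag_dilation_px: int = 0,
) -> pd.DataFrame:
    """One record per nucleus with centroid, area and per-channel means.

    The Flag channel is band-passed with the same DoG parameters as the
    DAPI segmentation before averaging over each nucleus (so a constant
    Flag channel measures as zero); EdU is averaged on the raw channel.
    ``flag_dilation_px`` grows the measurement region isotropically to
    capture marker signal just outside the nucleus.
    """
    nuclei = np.asarray(nuclei)
    for name, img in (("flag", flag_image), ("edu", edu_image)):
        if np.shape(img) != nuclei.shape:
            raise ValueError(f"{name} image shape differs from label map")
    if dapi_image is not None and np.shape(dapi_image) != nuclei.shape:
        raise ValueError("dapi image shape differs from label map")

    ids = np.unique(nuclei)
    ids = ids[ids > 0]
    cols = [
        "cell_id", "centroid_row", "centroid_col", "area_px", "area_um2",
        "mean_dapi", "mean_flag", "mean_edu",
    ]
    if ids.size == 0:
        return pd.DataFrame(columns=cols)

    dog = dog or DoGParams()
    flag_pp = dog_filter(flag_image, dog)

    flag_labels = nuclei
    if flag_dilation_px > 0:
        # expand each label without crossing into a neighbour: nearest-label
        # assignment within the dilation radius
        dist, (ir, ic) = ndi.distance_transform_edt(nuclei == 0, return_indices=True)
        flag_labels = np.where(dist <= flag_dilation_px, nuclei[ir, ic], 0)

    centroids = ndi.center_of_mass(np.ones_like(nuclei), labels=nuclei, index=ids)
    centroids = np.asarray(centroids, dtype=np.float64)
    areas = ndi.sum_labels(np.ones(nuclei.shape), labels=nuclei, index=ids)
    mean_flag = ndi.mean(flag_pp, labels=flag_labels, index=ids)
    mean_edu = ndi.mean(np.asarray(edu_image, dtype=np.float64), labels=nuclei, index=ids)
    if dapi_image is not None:
        mean_dapi = ndi.mean(np.asarray(dapi_image, dtype=np.float64),
                             labels=nuclei, index=ids)
    else:
        mean_dapi = np.full(ids.shape, np.nan)

    area_um2 = areas * (pixel_size**2) if pixel_size else np.full(ids.shape, np.nan)
    return pd.DataFrame(
        {
            "cell_id": ids.astype(int),
            "centroid_row": centroids[:, 0],
            "centroid_col": centroids[:, 1],
            "area_px": areas.astype(int),
            "area_um2": area_um2,
            "mean_dapi": mean_dapi,
            "mean_flag": mean_flag,
            "mean_edu": mean_edu,
        }
    )


class UnimodalWarning(UserWarning):
    """Emitted when no bimodality is detected and the fallback is used."""


def select_transfection_threshold(
    flag_intensities, fallback_percentile: float = 75.0,
    separation: float = 3.0,
) -> float:
    """Choose the marker threshold separating the two intensity modes.

    A two-component split minimizing within-class variance is computed on
    log-transformed intensities when all values are positive (raw
    fluorescence means); band-passed means can be negative, in which case
    the split runs on the raw values.  If the two component means are
    separated by less than ``separation`` pooled within-class standard
    deviations, the distribution is treated as unimodal: a warning is
    emitted and the ``fallback_percentile`` of the raw intensities is
    returned instead.  The default separation of 3.0 sits above the ~2.7
    that a two-means split of a single Gaussian produces by construction,
    so unimodal data reliably take the fallback.
    """
    x = np.asarray(list(flag_intensities), dtype=np.float64)
    if x.size < 10:
        raise ValueError(f"need at least 10 intensities, got {x.size}")
    use_log = x.min() > 0
    tx = np.log(x) if use_log else x
    values, counts = np.unique(tx, return_counts=True)
    if len(values) < 2:
        warnings.warn(
            "flag intensities are all identical; using percentile fallback",
            UnimodalWarning,
        )
        return float(np.percentile(x, fallback_percentile))
    split = _split_two_clusters(values, counts)
    lo_v, lo_c = values[:split], counts[:split]
    hi_v, hi_c = values[split:], counts[split:]
    mu_lo = np.average(lo_v, weights=lo_c)
    mu_hi = np.average(hi_v, weights=hi_c)
    var_lo = np.average((lo_v - mu_lo) ** 2, weights=lo_c)
    var_hi = np.average((hi_v - mu_hi) ** 2, weights=hi_c)
    n_lo, n_hi = lo_c.sum(), hi_c.sum()
    pooled_sd = np.sqrt((n_lo * var_lo + n_hi * var_hi) / (n_lo + n_hi))
    if pooled_sd > 0 and (mu_hi - mu_lo) / pooled_sd < separation:
        warnings.warn(
            "no clear bimodality in flag intensities; using percentile fallback",
            UnimodalWarning,
        )
        return float(np.percentile(x, fallback_percentile))
    thr = 0.5 * (values[split - 1] + values[split])
    return float(np.exp(thr)) if use_log else float(thr)


def classify_cells(
    records: pd.DataFrame,
    params: ClassifyParams | None = None,
    flag_threshold: float | None = None,
) -> pd.DataFrame:
    """Set the ``transfected`` and ``proliferating`` flags on a copy of
    ``records``.

    transfected   <=>  mean_flag >  flag_threshold  and  mean_flag >= flag_min_intensity
    proliferating <=>  mean_edu  >=  edu_min_intensity

    ``flag_threshold`` resolves the parameter's "auto" setting; it must be
    given when the parameter is "auto".
    """
    params = params or ClassifyParams()
    params.validate()
    if flag_threshold is None:
        if params.flag_threshold == "auto":
            if len(records) == 0:
                flag_threshold = 0.0
            else:
                flag_threshold = select_transfection_threshold(
                    records["mean_flag"], params.fallback_percentile
                )
        else:
            flag_threshold = float(params.flag_threshold)
    out = records.copy()
    if len(out) == 0:
        out["transfected"] = pd.Series(dtype=bool)
        out["proliferating"] = pd.Series(dtype=bool)
        return out
    out["transfected"] = (out["mean_flag"] > flag_threshold) & (
        out["mean_flag"] >= params.flag_min_intensity
    )
    out["proliferating"] = out["mean_edu"] >= params.edu_min_intensity
    return out


def overlay_image(
    nuclei: np.ndarray, records: pd.DataFrame, shape: tuple[int, int] | None = None
) -> np.ndarray:
    """RGB visualization of the calls: transfected cells green, EdU-positive
    red, double-positive yellow; other nuclei gray.  Returns a uint8 image."""
    nuclei = np.asarray(nuclei)
    shape = shape or nuclei.shape
    rgb = np.zeros(shape + (3,), dtype=np.uint8)
    max_label = int(nuclei.max()) if nuclei.size else 0
    colors = np.zeros((max_label + 1, 3), dtype=np.uint8)
    for _, r in records.iterrows():
        cid = int(r["cell_id"])
        if cid > max_label:
            continue
        t = bool(r.get("transfected", False))
        p = bool(r.get("proliferating", False))
        if t and p:
            colors[cid] = (255, 255, 0)
        elif t:
            colors[cid] = (0, 255, 0)
        elif p:
            colors[cid] = (255, 0, 0)
        else:
            colors[cid] = (110, 110, 110)
    rgb = colors[nuclei]
    return rgb
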