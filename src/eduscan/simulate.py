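"""Synthetic three-channel microscopy fields with full ground truth.

Each field emulates the statistical structure the downstream pipeline
assumes: roundish nuclei (a configurable fraction placed fused to a
neighbour), a bimodal transfection-marker (Flag) intensity distribution
over cells, per-class EdU positivity probabilities, a smooth low-frequency
background gradient and additive Gaussian noise.  Nuclei are rendered as
discs with a flat top and Gaussian-profile edges, so the true pixel mask of
every cell is analytic and exported as a label map.

All intensities are generated in floating point; quantization to 16-bit
happens only on TIFF export.  A single integer seed drives one pseudo-random
stream per field, so identical configurations give bit-identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile


class PackingError(RuntimeError):
    """Raised when the requested cells cannot be placed in the image."""


@dataclass
class SimulationConfig:
    """Generative parameters for one synthetic field.

    Intensities are in arbitrary camera units on a 16-bit scale; lengths in
    pixels unless noted.  ``pixel_size`` (um/pixel) only affects reported
    physical areas, not rendering.
    """

    image_shape: tuple[int, int] = (512, 512)
    pixel_size: float = 0.65  # um/pixel, typical 10x slide-scanner sampling
    n_cells: int = 300
    radius_mean: float = 8.0
    radius_sd: float = 1.2
    touching_fraction: float = 0.1
    transfected_fraction: float = 0.4
    edu_fraction_transfected: float = 0.2
    edu_fraction_control: float = 0.5
    dapi_mean: float = 8000.0
    dapi_sd: float = 800.0
    flag_mean_neg: float = 500.0
    flag_mean_pos: float = 6000.0
    flag_sd: float = 600.0
    edu_mean_pos: float = 7000.0
    edu_mean_neg: float = 400.0
    edu_sd: float = 500.0
    background_amplitude: float = 300.0
    noise_sd: float = 100.0
    edge_sigma: float = 1.0  # Gaussian falloff width outside the disc
    spacing_factor: float = 2.7  # grid spacing in units of radius_mean
    seed: int = 0

    def validate(self) -> None:
        fracs = {
            "touching_fraction": self.touching_fraction,
            "transfected_fraction": self.transfected_fraction,
            "edu_fraction_transfected": self.edu_fraction_transfected,
            "edu_fraction_control": self.edu_fraction_control,
        }
        for name, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.radius_mean <= 0:
            raise ValueError("radius_mean must be > 0")
        if self.flag_mean_pos <= self.flag_mean_neg:
            raise ValueError("flag_mean_pos must exceed flag_mean_neg")
        if len(self.image_shape) != 2 or min(self.image_shape) < 8:
            raise ValueError("image_shape must be 2-D and at least 8x8")

    def to_file(self, path: str | Path) -> None:
        """Serialize as plain ``key: value`` lines."""
        lines = []
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if f.name == "image_shape":
                v = f"{v[0]}x{v[1]}"
            lines.append(f"{f.name}: {v}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationConfig":
        kwargs: dict = {}
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#") or ":" not in line:
                continue
            key, _, raw = line.partition(":")
            key, raw = key.strip(), raw.strip()
            if key not in types:
                raise ValueError(f"unknown config key: {key}")
            if key == "image_shape":
                h, _, w = raw.partition("x")
                kwargs[key] = (int(h), int(w))
            elif key in ("n_cells", "seed"):
                kwargs[key] = int(raw)
            else:
                kwargs[key] = float(raw)
        return cls(**kwargs)


@dataclass
class GroundTruth:
    """True per-cell labels and the analytic label map for one field."""

    cells: pd.DataFrame  # columns: id, row, col, radius, transfected, proliferating
    true_label_map: np.ndarray  # int32, 0 = background, labels match cells.id
    intensities: pd.DataFrame = field(repr=False, default=None)
    # per-cell drawn channel amplitudes: id, dapi, flag, edu

    @property
    def n_cells(self) -> int:
        return len(self.cells)


def _place_centers(cfg: SimulationConfig, rng: np.random.Generator):
    """Place nucleus centers on a jittered grid; a ``touching_fraction``
    share is deliberately fused to a neighbour.

    Independent cells occupy randomly chosen sites of a grid whose spacing
    keeps typical nuclei separated; per-site jitter breaks the regularity.
    Fused pairs get a partner at ~0.7 * (r1 + r2) from their anchor, so the
    two discs overlap and the watershed stage has genuine splits to make.

    Returns (centers (n, 2) float, radii (n,) float).
    """
    h, w = cfg.image_shape
    margin = cfg.radius_mean + 3 * cfg.radius_sd + 2
    if 2 * margin >= min(h, w):
        raise PackingError("image too small for the configured radii")

    n_touch_pairs = int(round(cfg.n_cells * cfg.touching_fraction / 2))
    n_single = cfg.n_cells - 2 * n_touch_pairs
    n_anchors = n_single + n_touch_pairs

    radii = np.clip(
        rng.normal(cfg.radius_mean, cfg.radius_sd, cfg.n_cells),
        0.4 * cfg.radius_mean,
        2.0 * cfg.radius_mean,
    )

    spacing = cfg.spacing_factor * cfg.radius_mean
    gy = int((h - 2 * margin) // spacing) + 1
    gx = int((w - 2 * margin) // spacing) + 1
    if gy * gx < n_anchors:
        raise PackingError(
            f"cannot place {cfg.n_cells} cells in {h}x{w}: only {gy * gx} "
            f"grid sites at spacing {spacing:.1f} px"
        )
    sites = np.stack(
        np.meshgrid(
            margin + spacing * np.arange(gy), margin + spacing * np.arange(gx),
            indexing="ij",
        ),
        axis=-1,
    ).reshape(-1, 2)
    chosen = sites[rng.choice(len(sites), size=n_anchors, replace=False)]
    jitter = rng.uniform(-0.15 * spacing, 0.15 * spacing, size=chosen.shape)
    anchors = chosen + jitter

    centers: list[np.ndarray] = []
    k = 0
    # fused pairs first: equal-radius sisters at ~0.7 * (r1 + r2) = 1.4 radii,
    # a two-lobe geometry whose ground-truth split is well defined
    for i in range(n_touch_pairs):
        anchor = anchors[i]
        radii[k + 1] = radii[k]
        d = 0.7 * (radii[k] + radii[k + 1])
        for _ in range(64):
            theta = rng.uniform(0, 2 * np.pi)
            partner = anchor + d * np.array([np.cos(theta), np.sin(theta)])
            if margin <= partner[0] <= h - margin and margin <= partner[1] <= w - margin:
                break
        centers.append(anchor)
        centers.append(partner)
        k += 2
    for i in range(n_touch_pairs, n_anchors):
        centers.append(anchors[i])
        k += 1
    return np.asarray(centers), radii


def _render_channel(
    shape: tuple[int, int],
    centers: np.ndarray,
    radii: np.ndarray,
    amplitudes: np.ndarray,
    edge_sigma: float,
) -> np.ndarray:
    """Paint flat-top discs with Gaussian-profile edges; overlaps take the max."""
    h, w = shape
    img = np.zeros(shape, dtype=np.float64)
    reach = 3.0 * edge_sigma
    for (cy, cx), r, a in zip(centers, radii, amplitudes):
        r0 = max(int(np.floor(cy - r - reach)), 0)
        r1 = min(int(np.ceil(cy + r + reach)) + 1, h)
        c0 = max(int(np.floor(cx - r - reach)), 0)
        c1 = min(int(np.ceil(cx + r + reach)) + 1, w)
        yy, xx = np.mgrid[r0:r1, c0:c1]
        d = np.hypot(yy - cy, xx - cx)
        excess = np.maximum(d - r, 0.0)
        profile = np.exp(-(excess**2) / (2.0 * edge_sigma**2))
        profile[excess > reach] = 0.0  # compact support: no long-range bleed
        patch = img[r0:r1, c0:c1]
        np.maximum(patch, a * profile, out=patch)
    return img


def _true_label_map(
    shape: tuple[int, int], centers: np.ndarray, radii: np.ndarray
) -> np.ndarray:
    """Analytic mask: pixel belongs to cell i if inside its disc; overlap
    pixels go to the cell with the smallest radius-normalized distance."""
    h, w = shape
    labels = np.zeros(shape, dtype=np.int32)
    best = np.full(shape, np.inf)
    for i, ((cy, cx), r) in enumerate(zip(centers, radii), start=1):
        r0 = max(int(np.floor(cy - r)), 0)
        r1 = min(int(np.ceil(cy + r)) + 1, h)
        c0 = max(int(np.floor(cx - r)), 0)
        c1 = min(int(np.ceil(cx + r)) + 1, w)
        yy, xx = np.mgrid[r0:r1, c0:c1]
        d = np.hypot(yy - cy, xx - cx)
        norm = d / r
        inside = d <= r
        patch_best = best[r0:r1, c0:c1]
        take = inside & (norm < patch_best)
        labels[r0:r1, c0:c1][take] = i
        patch_best[take] = norm[take]
    return labels


def _background(shape: tuple[int, int], amplitude: float, rng: np.random.Generator):
    """Smooth low-frequency gradient: a random-orientation linear ramp plus a
    half-period sinusoid, scaled to peak at ``amplitude``."""
    if amplitude == 0:
        return np.zeros(shape)
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    theta = rng.uniform(0, 2 * np.pi)
    ramp = (np.cos(theta) * yy / h + np.sin(theta) * xx / w)
    ramp = (ramp - ramp.min()) / max(float(np.ptp(ramp)), 1e-12)
    phase = rng.uniform(0, 2 * np.pi)
    wave = 0.5 + 0.5 * np.sin(np.pi * yy / h + phase) * np.sin(np.pi * xx / w + phase)
    bg = 0.6 * ramp + 0.4 * wave
    return amplitude * bg


def simulate_field(config: SimulationConfig):
    """Generate one three-channel field.

    Returns ``(channels, truth)`` where ``channels`` is a dict with float64
    arrays under keys ``"dapi"``, ``"flag"``, ``"edu"`` and ``truth`` is a
    :class:`GroundTruth`.

    Raises
    ------
    PackingError
        If the configured number of cells cannot be placed after a bounded
        number of attempts.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    centers, radii = _place_centers(config, rng)
    n = config.n_cells

    transfected = rng.random(n) < config.transfected_fraction
    p_edu = np.where(
        transfected, config.edu_fraction_transfected, config.edu_fraction_control
    )
    proliferating = rng.random(n) < p_edu

    dapi_amp = np.maximum(rng.normal(config.dapi_mean, config.dapi_sd, n), 0.0)
    flag_amp = np.maximum(
        rng.normal(
            np.where(transfected, config.flag_mean_pos, config.flag_mean_neg),
            config.flag_sd,
        ),
        0.0,
    )
    edu_amp = np.maximum(
        rng.normal(
            np.where(proliferating, config.edu_mean_pos, config.edu_mean_neg),
            config.edu_sd,
        ),
        0.0,
    )

    channels = {}
    for name, amp in (("dapi", dapi_amp), ("flag", flag_amp), ("edu", edu_amp)):
        img = _render_channel(config.image_shape, centers, radii, amp, config.edge_sigma)
        img += _background(config.image_shape, config.background_amplitude, rng)
        if config.noise_sd > 0:
            img += rng.normal(0.0, config.noise_sd, config.image_shape)
        channels[name] = img

    cells = pd.DataFrame(
        {
            "id": np.arange(1, n + 1, dtype=np.int32),
            "row": centers[:, 0],
            "col": centers[:, 1],
            "radius": radii,
            "transfected": transfected,
            "proliferating": proliferating,
        }
    )
    intensities = pd.DataFrame(
        {"id": cells["id"], "dapi": dapi_amp, "flag": flag_amp, "edu": edu_amp}
    )
    truth = GroundTruth(
        cells=cells,
        true_label_map=_true_label_map(config.image_shape, centers, radii),
        intensities=intensities,
    )
    return channels, truth


def quantize_u16(image: np.ndarray) -> np.ndarray:
    """Clip to [0, 65535] and round to uint16 (camera bit depth on export)."""
    return np.clip(np.rint(image), 0, 65535).astype(np.uint16)


def write_field(
    out_dir: str | Path,
    channels: dict,
    truth: GroundTruth,
    config: SimulationConfig | None = None,
    prefix: str = "field",
) -> dict:
    """Write per-channel 16-bit TIFFs, ground-truth CSV, true label-map TIFF
    and (optionally) the config.  Returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, img in channels.items():
        p = out / f"{prefix}_{name}.tif"
        tifffile.imwrite(p, quantize_u16(img))
        paths[name] = p
    truth_csv = out / f"{prefix}_truth.csv"
    truth.cells.to_csv(truth_csv, index=False)
    paths["truth"] = truth_csv
    label_tif = out / f"{prefix}_true_labels.tif"
    tifffile.imwrite(label_tif, truth.true_label_map.astype(np.uint16))
    paths["true_labels"] = label_tif
    if config is not None:
        cfg_path = out / f"{prefix}_config.txt"
        config.to_file(cfg_path)
        paths["config"] = cfg_path
    return paths
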