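"""Synthetic endoscopy-like image/mask generator.

Real colonoscopy frames share a few coarse statistics: a black "void" border
outside the circular optical field of view (6-28 % of the frame), a single
polyp blob covering anywhere from under 1 % to over 80 % of the valid area,
and a characteristic brightness/contrast profile.  This module generates
frames that hit those statistics with controllable parameters so that every
downstream stage (augmentation, training, metrics, statistics) can be
exercised and tested without access to clinical data.

The generator makes no attempt at photorealism: the mucosa is a smoothly
textured reddish field, the polyp a slightly paler elliptical blob.  Only
the area/brightness statistics matter downstream.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, asdict, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .sample import ImageSample, save_sample

__all__ = [
    "SyntheticConfig",
    "DatasetRanges",
    "make_fov_mask",
    "generate_sample",
    "generate_dataset",
    "KVASIR_LIKE",
    "ENDOSCENE_LIKE",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one synthetic frame.

    brightness_level is the target mean of the HSV value channel over the
    whole frame (void included), on the 0-255 scale; contrast_level is the
    standard deviation of the mucosa texture in intensity units;
    texture_scale is the correlation length of that texture in pixels.
    """

    height: int = 256
    width: int = 256
    void_fraction: float = 0.15
    polyp_area_fraction: float = 0.17
    brightness_level: float = 158.6
    contrast_level: float = 12.0
    texture_scale: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ValueError("height and width must be positive")
        if not 0.0 <= self.void_fraction < 1.0:
            raise ValueError("void_fraction must be in [0, 1)")
        if not 0.0 <= self.polyp_area_fraction < 1.0:
            raise ValueError("polyp_area_fraction must be in [0, 1)")
        if not 0.0 <= self.brightness_level <= 255.0:
            raise ValueError("brightness_level must be in [0, 255]")
        if self.contrast_level < 0:
            raise ValueError("contrast_level must be >= 0")


@dataclass(frozen=True)
class DatasetRanges:
    """Per-sample uniform jitter ranges for :func:`generate_dataset`.

    Each field is a (low, high) interval; per-sample parameters are drawn
    uniformly within it, so the dataset-level mean equals the interval
    midpoint.
    """

    void_fraction: tuple[float, float] = (0.06, 0.28)
    polyp_area_fraction: tuple[float, float] = (0.006, 0.34)
    brightness_level: tuple[float, float] = (153.6, 163.6)
    contrast_level: tuple[float, float] = (8.0, 16.0)

    def midpoints(self) -> dict[str, float]:
        return {k: (v[0] + v[1]) / 2.0 for k, v in asdict(self).items()}


# Presets whose dataset-level statistics emulate the two public polyp
# segmentation benchmarks (void area ~15 % vs ~24 %, polyp area ~17 % vs
# ~12 % of the valid area, mean HSV brightness 0.622 vs 0.560).
KVASIR_LIKE = DatasetRanges(
    void_fraction=(0.06, 0.2446),
    polyp_area_fraction=(0.006, 0.3412),
    brightness_level=(0.617 * 255, 0.627 * 255),
    contrast_level=(10.0, 18.0),
)
ENDOSCENE_LIKE = DatasetRanges(
    void_fraction=(0.1462, 0.2783),
    polyp_area_fraction=(0.0075, 0.2425),
    brightness_level=(0.555 * 255, 0.565 * 255),
    contrast_level=(6.0, 12.0),
)


def make_fov_mask(height: int, width: int, void_fraction: float) -> np.ndarray:
    """Binary void mask for a centered circular field of view.

    Returns an (H, W) uint8 array with 1 outside a centered disc whose
    radius is solved by bisection so that the 1-fraction matches
    ``void_fraction`` to within 0.01 (pixel quantization permitting).
    """
    if not 0.0 <= void_fraction < 1.0:
        raise ValueError("void_fraction must be in [0, 1)")
    if void_fraction == 0.0:
        return np.zeros((height, width), dtype=np.uint8)
    cy, cx = (height - 1) / 2.0, (width - 1) / 2.0
    yy, xx = np.ogrid[:height, :width]
    r2 = (yy - cy) ** 2 + (xx - cx) ** 2
    total = height * width

    def frac_outside(radius: float) -> float:
        return float((r2 > radius * radius).sum()) / total

    lo, hi = 0.0, float(np.hypot(cy + 1, cx + 1))
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if frac_outside(mid) > void_fraction:
            lo = mid
        else:
            hi = mid
    radius = 0.5 * (lo + hi)
    return (r2 > radius * radius).astype(np.uint8)


def _smooth_noise(shape: tuple[int, int], scale: float, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean unit-sd spatially correlated noise field."""
    noise = rng.standard_normal(shape)
    if scale > 0:
        noise = ndimage.gaussian_filter(noise, sigma=scale, mode="reflect")
    sd = noise.std()
    return noise / sd if sd > 0 else noise


def _rasterize_ellipse(
    shape: tuple[int, int],
    center: tuple[float, float],
    semi_axes: tuple[float, float],
    theta: float,
) -> np.ndarray:
    h, w = shape
    yy, xx = np.mgrid[:h, :w]
    dy, dx = yy - center[0], xx - center[1]
    c, s = np.cos(theta), np.sin(theta)
    u = c * dx + s * dy
    v = -s * dx + c * dy
    a, b = semi_axes
    return ((u / a) ** 2 + (v / b) ** 2 <= 1.0).astype(np.uint8)


def _place_polyp(
    valid: np.ndarray,
    target_px: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Rasterize an ellipse of ~target_px pixels fully inside the valid area.

    The semi-axis scale is adjusted iteratively so the pixel count lands
    within 5 % (relative) of the target even for small blobs.
    """
    # large blobs get a near-circular shape so they can fit the disc FOV
    max_aspect = 1.15 if target_px > 0.4 * valid.sum() else 2.0
    aspect = rng.uniform(1.0, max_aspect)
    theta = rng.uniform(0.0, np.pi)
    a = np.sqrt(target_px * aspect / np.pi)
    b = a / aspect
    # centers must keep the ellipse's bounding radius inside the valid area
    dist = ndimage.distance_transform_edt(valid)
    candidates = np.argwhere(dist >= a + 1.0)
    if len(candidates) == 0:
        raise ValueError(
            f"polyp of {target_px} px cannot fit inside the valid area"
        )
    cy, cx = candidates[rng.integers(len(candidates))]
    scale = 1.0
    blob = np.zeros_like(valid)
    for _ in range(12):
        blob = _rasterize_ellipse(valid.shape, (cy, cx), (a * scale, b * scale), theta)
        blob &= valid  # containment is guaranteed by placement up to +-1 px
        count = int(blob.sum())
        if count == 0:
            scale *= 1.5
            continue
        if abs(count - target_px) <= max(1, 0.05 * target_px):
            break
        scale *= np.sqrt(target_px / count)
    return blob


def generate_sample(config: SyntheticConfig, rng: np.random.Generator | None = None) -> ImageSample:
    """Generate one frame: textured mucosa, black void border, one polyp.

    The polyp is an ellipse fully inside the valid area whose pixel count is
    within 10 % (relative) of ``polyp_area_fraction`` x valid area; the mask
    marks exactly that ellipse.  Bit-identical output for identical
    (config, seed).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    h, w = config.height, config.width
    void = make_fov_mask(h, w, config.void_fraction)
    valid = 1 - void
    n_valid = int(valid.sum())

    # mucosa base color: reddish, value channel dominated by the R channel
    texture = _smooth_noise((h, w), config.texture_scale, rng) * config.contrast_level
    base_v = 150.0 + texture  # arbitrary level; rescaled to target below
    channel_ratios = np.array([1.0, 0.62, 0.55])
    img = base_v[..., None] * channel_ratios[None, None, :]

    mask = np.zeros((h, w), dtype=np.uint8)
    if config.polyp_area_fraction > 0:
        target_px = int(round(config.polyp_area_fraction * n_valid))
        if target_px > 0:
            mask = _place_polyp(valid.astype(np.uint8), target_px, rng)
            # paler, slightly yellower blob with a smoothed boundary
            alpha = ndimage.gaussian_filter(mask.astype(float), sigma=1.5)
            alpha = np.clip(alpha, 0.0, 1.0)
            polyp_gain = np.array([1.22, 1.30, 0.95])
            img = img * (1.0 + alpha[..., None] * (polyp_gain[None, None, :] - 1.0))

    img *= valid[..., None]

    # rescale so the mean HSV value channel (max over RGB) hits the target
    v = img.max(axis=2)
    cur = v.mean()
    if cur > 0:
        img = img * (config.brightness_level / cur)
    img = np.clip(np.floor(img + 0.5), 0, 255).astype(np.uint8)
    img[void.astype(bool)] = 0

    return ImageSample(image=img, mask=mask, void_mask=void, id=f"synth_{config.seed}")


def generate_dataset(
    config: SyntheticConfig,
    n: int,
    rng: np.random.Generator | int | None = None,
    ranges: DatasetRanges | None = None,
    out_dir: str | None = None,
) -> tuple[list[ImageSample], pd.DataFrame]:
    """Generate ``n`` samples with per-sample parameters jittered uniformly.

    ``config`` supplies the frame geometry and the seed; ``ranges`` supplies
    the per-sample uniform intervals (defaults to intervals centered on the
    config values, zero width).  Deterministic under (config, ranges, n).
    If ``out_dir`` is given, PNGs and a ``manifest.csv`` are written there.

    Returns (samples, manifest).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    elif isinstance(rng, int):
        rng = np.random.default_rng(rng)

    records = []
    samples = []
    for i in range(n):
        if ranges is not None:
            params = {
                k: float(rng.uniform(lo, hi))
                for k, (lo, hi) in asdict(ranges).items()
            }
        else:
            params = {
                "void_fraction": config.void_fraction,
                "polyp_area_fraction": config.polyp_area_fraction,
                "brightness_level": config.brightness_level,
                "contrast_level": config.contrast_level,
            }
        cfg_i = replace(config, **params)
        sample = generate_sample(cfg_i, rng)
        sample.id = f"synth_{i:04d}"
        samples.append(sample)
        rec = {"id": sample.id, **params}
        records.append(rec)

    manifest = pd.DataFrame.from_records(records)
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        paths = [save_sample(s, out_dir) for s in samples]
        # manifest paths are relative to out_dir so datasets are relocatable
        manifest["image_path"] = [os.path.relpath(p["images"], out_dir) for p in paths]
        manifest["mask_path"] = [os.path.relpath(p["masks"], out_dir) for p in paths]
        manifest["void_path"] = [os.path.relpath(p["void"], out_dir) for p in paths]
        manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    return samples, manifest
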