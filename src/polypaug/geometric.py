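"""Image-based augmentations applied jointly to image and masks.

All spatial operators share one contract: the image is resampled bilinearly,
masks with nearest-neighbour (so they stay binary), exposed regions are
filled by edge replication, and the identical coordinate mapping is applied
to the image, the polyp mask and the void mask.  Affine operators are
expressed as inverse maps about the image center and executed with
``scipy.ndimage.affine_transform``; the elastic deformation uses a smoothed
random displacement field and ``map_coordinates``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .sample import ImageSample

__all__ = [
    "GeometricParams",
    "apply_shift",
    "apply_rotation",
    "apply_shear",
    "apply_zoom",
    "apply_flip",
    "elastic_deform",
    "displacement_field",
    "warp_with_field",
    "apply_geometric",
]


@dataclass(frozen=True)
class GeometricParams:
    """One realized draw of the image-based transformation parameters.

    Identity values (all zeros, zooms of 1, flips off, alpha 0) reproduce
    the input bit-exactly.
    """

    shift_x: float = 0.0          # signed fraction of width
    shift_y: float = 0.0          # signed fraction of height
    rotation: float = 0.0         # degrees
    shear: float = 0.0            # degrees, counter-clockwise
    zoom_x: float = 1.0           # factor < 1 magnifies content
    zoom_y: float = 1.0
    flip_h: bool = False
    flip_v: bool = False
    elastic_alpha: float = 0.0    # displacement scale (pixels x intensity)
    elastic_sigma: float = 40.0   # Gaussian smoothing width (pixels)

    def __post_init__(self) -> None:
        if self.zoom_x <= 0 or self.zoom_y <= 0:
            raise ValueError("zoom factors must be positive")
        if abs(self.shift_x) > 1 or abs(self.shift_y) > 1:
            raise ValueError("|shift| must be <= 1")
        for ang in (self.rotation, self.shear):
            if not -180.0 <= ang <= 180.0:
                raise ValueError("rotation and shear must lie in [-180, 180]")

    @property
    def is_identity(self) -> bool:
        return (
            self.shift_x == 0 and self.shift_y == 0 and self.rotation == 0
            and self.shear == 0 and self.zoom_x == 1 and self.zoom_y == 1
            and not self.flip_h and not self.flip_v and self.elastic_alpha == 0
        )


def _round_u8(arr: np.ndarray) -> np.ndarray:
    # round half away from zero, then clip to the 8-bit range
    return np.clip(np.floor(arr + 0.5), 0, 255).astype(np.uint8)


def _affine_sample(sample: ImageSample, matrix: np.ndarray, offset: np.ndarray) -> ImageSample:
    """Apply inverse-map ``in = matrix @ out + offset`` to image and masks."""
    img = np.stack(
        [
            ndimage.affine_transform(
                sample.image[..., c].astype(float), matrix, offset=offset,
                order=1, mode="nearest",
            )
            for c in range(3)
        ],
        axis=-1,
    )
    mask = ndimage.affine_transform(
        sample.mask, matrix, offset=offset, order=0, mode="nearest"
    )
    void = ndimage.affine_transform(
        sample.void_mask, matrix, offset=offset, order=0, mode="nearest"
    )
    return replace(
        sample,
        image=_round_u8(img),
        mask=(mask > 0.5).astype(np.uint8),
        void_mask=(void > 0.5).astype(np.uint8),
    )


def _centered_affine(sample: ImageSample, matrix: np.ndarray) -> ImageSample:
    h, w = sample.shape
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    offset = center - matrix @ center
    return _affine_sample(sample, matrix, offset)


def apply_shift(sample: ImageSample, fx: float, fy: float) -> ImageSample:
    """Translate content by (round(fx*W), round(fy*H)) whole pixels.

    Positive fx moves content to the right, positive fy moves it down.
    The exposed border is filled by edge replication; masks move with the
    identical integer offset, so no interpolation ever touches them.
    """
    if abs(fx) > 1 or abs(fy) > 1:
        raise ValueError("|shift fraction| must be <= 1")
    h, w = sample.shape
    dx = int(round(fx * w))
    dy = int(round(fy * h))
    if dx == 0 and dy == 0:
        return sample.copy()
    rows = np.clip(np.arange(h) - dy, 0, h - 1)
    cols = np.clip(np.arange(w) - dx, 0, w - 1)
    return replace(
        sample,
        image=sample.image[rows][:, cols].copy(),
        mask=sample.mask[rows][:, cols].copy(),
        void_mask=sample.void_mask[rows][:, cols].copy(),
    )


def apply_rotation(sample: ImageSample, angle: float) -> ImageSample:
    """Rotate content by ``angle`` degrees about the image center."""
    if not -180.0 <= angle <= 180.0:
        raise ValueError("angle must lie in [-180, 180]")
    if angle == 0:
        return sample.copy()
    t = np.deg2rad(angle)
    # inverse map: rotate output coordinates by -angle
    matrix = np.array([[np.cos(t), np.sin(t)], [-np.sin(t), np.cos(t)]])
    return _centered_affine(sample, matrix)


def apply_shear(sample: ImageSample, angle: float) -> ImageSample:
    """Shear content by ``angle`` degrees (counter-clockwise) about center."""
    if not -180.0 <= angle <= 180.0:
        raise ValueError("angle must lie in [-180, 180]")
    if abs(abs(angle) - 90.0) < 1e-12:
        raise ValueError("shear of +-90 degrees is degenerate (tan undefined)")
    if angle == 0:
        return sample.copy()
    t = np.deg2rad(angle)
    matrix = np.array([[1.0, np.tan(t)], [0.0, 1.0]])
    return _centered_affine(sample, matrix)


def apply_zoom(sample: ImageSample, zx: float, zy: float) -> ImageSample:
    """Scale content about the center; factor < 1 magnifies (zoom in)."""
    if zx <= 0 or zy <= 0:
        raise ValueError("zoom factors must be positive")
    if zx == 1 and zy == 1:
        return sample.copy()
    matrix = np.array([[zy, 0.0], [0.0, zx]])
    return _centered_affine(sample, matrix)


def apply_flip(sample: ImageSample, horizontal: bool, vertical: bool) -> ImageSample:
    """Reverse columns (horizontal) and/or rows (vertical)."""
    if not horizontal and not vertical:
        return sample.copy()
    sl_r = slice(None, None, -1) if vertical else slice(None)
    sl_c = slice(None, None, -1) if horizontal else slice(None)
    return replace(
        sample,
        image=sample.image[sl_r, sl_c].copy(),
        mask=sample.mask[sl_r, sl_c].copy(),
        void_mask=sample.void_mask[sl_r, sl_c].copy(),
    )


def displacement_field(
    shape: tuple[int, int], alpha: float, sigma: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Random elastic displacement field (dy, dx).

    Per-pixel uniform(-1, 1) fields are smoothed by a Gaussian of width
    ``sigma`` and scaled by ``alpha``.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    dy = ndimage.gaussian_filter(rng.uniform(-1, 1, size=shape), sigma, mode="reflect") * alpha
    dx = ndimage.gaussian_filter(rng.uniform(-1, 1, size=shape), sigma, mode="reflect") * alpha
    return dy, dx


def warp_with_field(sample: ImageSample, dy: np.ndarray, dx: np.ndarray) -> ImageSample:
    """Remap coordinates by a given displacement field (shared by all planes)."""
    h, w = sample.shape
    yy, xx = np.mgrid[:h, :w].astype(float)
    coords = np.array([yy + dy, xx + dx])
    img = np.stack(
        [
            ndimage.map_coordinates(
                sample.image[..., c].astype(float), coords, order=1, mode="nearest"
            )
            for c in range(3)
        ],
        axis=-1,
    )
    mask = ndimage.map_coordinates(sample.mask, coords, order=0, mode="nearest")
    void = ndimage.map_coordinates(sample.void_mask, coords, order=0, mode="nearest")
    return replace(
        sample,
        image=_round_u8(img),
        mask=(mask > 0.5).astype(np.uint8),
        void_mask=(void > 0.5).astype(np.uint8),
    )


def elastic_deform(
    sample: ImageSample, alpha: float, sigma: float, rng: np.random.Generator
) -> ImageSample:
    """Elastic deformation: smoothed random displacement field, jointly applied.

    alpha = 0 returns the input unchanged (no rng draw is consumed then
    either, keeping identity bit-exact and cheap).
    """
    if alpha == 0:
        return sample.copy()
    dy, dx = displacement_field(sample.shape, alpha, sigma, rng)
    return warp_with_field(sample, dy, dx)


def apply_geometric(
    sample: ImageSample, params: GeometricParams, rng: np.random.Generator | None = None
) -> ImageSample:
    """Apply a full parameter draw in a fixed canonical order.

    Order: flips, shift, rotation, shear, zoom, elastic.  In the ablation
    protocol only one field deviates from identity at a time, so the order
    only matters for hand-built combinations.
    """
    out = sample
    if params.flip_h or params.flip_v:
        out = apply_flip(out, params.flip_h, params.flip_v)
    if params.shift_x != 0 or params.shift_y != 0:
        out = apply_shift(out, params.shift_x, params.shift_y)
    if params.rotation != 0:
        out = apply_rotation(out, params.rotation)
    if params.shear != 0:
        out = apply_shear(out, params.shear)
    if params.zoom_x != 1 or params.zoom_y != 1:
        out = apply_zoom(out, params.zoom_x, params.zoom_y)
    if params.elastic_alpha > 0:
        if rng is None:
            raise ValueError("elastic deformation requires an rng")
        out = elastic_deform(out, params.elastic_alpha, params.elastic_sigma, rng)
    return out.copy() if out is sample else out
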