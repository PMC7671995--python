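"""Application-based augmentations: synthetic specular highlights and blur.

Specular highlights — the saturated reflections of the light source on wet
mucosa — are modelled as white ellipses: axis lengths and the per-image count
follow distributions whose moments were measured on the manually segmented
specular-light class of CVC-EndoSceneStill (major axis 7.77 +- 10.36 px, max
259.81; minor axis 3.82 +- 4.29 px, max 137.39; count per image 18.20 +-
16.97).  Both the count and the axis lengths have coefficient of variation
near or above one, so a moment-matched gamma distribution is used for each
(rounded to an integer for the count, clipped to the observed maxima for the
axes).  Rendering sets every in-ellipse pixel to 255 in all channels.

Blur is a plain mean filter with edge replication, the standard way to mimic
out-of-focus frames.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .sample import ImageSample

__all__ = [
    "SpecularModel",
    "EllipseSpec",
    "sample_specular_count",
    "sample_ellipse",
    "render_specular",
    "add_specular_lights",
    "mean_filter",
    "BLUR_WINDOWS",
]

BLUR_WINDOWS = (1, 3, 5, 7, 9, 11, 13, 15)


@dataclass(frozen=True)
class SpecularModel:
    """Moments of the specular-highlight geometry (full axis lengths, pixels).

    Defaults are the CVC-EndoSceneStill fit.
    """

    major_axis_mean: float = 7.77
    major_axis_sd: float = 10.36
    major_axis_max: float = 259.81
    minor_axis_mean: float = 3.82
    minor_axis_sd: float = 4.29
    minor_axis_max: float = 137.39
    count_mean: float = 18.20
    count_sd: float = 16.97

    def __post_init__(self) -> None:
        vals = (
            self.major_axis_mean, self.major_axis_sd, self.major_axis_max,
            self.minor_axis_mean, self.minor_axis_sd, self.minor_axis_max,
            self.count_mean, self.count_sd,
        )
        if any(v < 0 for v in vals):
            raise ValueError("all moments and maxima must be >= 0")


@dataclass(frozen=True)
class EllipseSpec:
    """A rasterizable ellipse: center (pixels), semi-axes, orientation."""

    center_row: float
    center_col: float
    semi_major: float
    semi_minor: float
    orientation: float  # degrees in [0, 180)

    def __post_init__(self) -> None:
        if not self.semi_major >= self.semi_minor >= 0:
            raise ValueError("require semi_major >= semi_minor >= 0")
        if not 0.0 <= self.orientation < 180.0:
            raise ValueError("orientation must lie in [0, 180)")


def _gamma_draw(mean: float, sd: float, rng: np.random.Generator, size=None):
    """Moment-matched gamma draw; degenerate moments give the constant mean."""
    if mean <= 0 or sd <= 0:
        return np.full(size, mean) if size is not None else mean
    shape = (mean / sd) ** 2
    scale = sd * sd / mean
    return rng.gamma(shape, scale, size=size)


def sample_specular_count(model: SpecularModel, rng: np.random.Generator) -> int:
    """Number of highlights for one frame: rounded moment-matched gamma."""
    draw = _gamma_draw(model.count_mean, model.count_sd, rng)
    return int(max(0, round(float(draw))))


def sample_ellipse(
    model: SpecularModel,
    image_shape: tuple[int, int],
    valid_mask: np.ndarray,
    rng: np.random.Generator,
) -> EllipseSpec:
    """Draw one highlight ellipse.

    Axis lengths come from moment-matched gamma distributions clipped to the
    observed maxima; the minor axis is capped by the major so the ordering
    invariant holds; orientation is uniform in [0, 180); the center is
    uniform over the valid (non-void) pixels, where reflections occur.
    """
    valid_mask = np.asarray(valid_mask)
    idx = np.flatnonzero(valid_mask.ravel())
    if idx.size == 0:
        raise ValueError("valid_mask has no pixels to place a highlight on")
    major = min(float(_gamma_draw(model.major_axis_mean, model.major_axis_sd, rng)),
                model.major_axis_max)
    minor = min(float(_gamma_draw(model.minor_axis_mean, model.minor_axis_sd, rng)),
                model.minor_axis_max, major)
    flat = idx[rng.integers(idx.size)]
    r, c = np.unravel_index(flat, valid_mask.shape)
    return EllipseSpec(
        center_row=float(r),
        center_col=float(c),
        semi_major=major / 2.0,   # measured statistics are full axis lengths
        semi_minor=minor / 2.0,
        orientation=float(rng.uniform(0.0, 180.0)),
    )


def render_specular(sample: ImageSample, ellipses: list[EllipseSpec]) -> ImageSample:
    """Set every pixel inside any ellipse to 255 in all channels.

    Masks are untouched; ellipses extending past the frame are clipped at
    the border.  Idempotent.
    """
    out = sample.copy()
    h, w = sample.shape
    yy, xx = np.mgrid[:h, :w]
    hit = np.zeros((h, w), dtype=bool)
    for e in ellipses:
        if e.semi_major == 0:
            continue
        t = np.deg2rad(e.orientation)
        dy = yy - e.center_row
        dx = xx - e.center_col
        u = np.cos(t) * dx + np.sin(t) * dy
        v = -np.sin(t) * dx + np.cos(t) * dy
        b = max(e.semi_minor, 0.5)  # hairline ellipses still light one pixel row
        hit |= (u / max(e.semi_major, 0.5)) ** 2 + (v / b) ** 2 <= 1.0
    out.image[hit] = 255
    return out


def add_specular_lights(
    sample: ImageSample, model: SpecularModel, rng: np.random.Generator
) -> ImageSample:
    """Full specular augmentation: draw a count, draw ellipses, render."""
    valid = 1 - sample.void_mask
    if valid.sum() == 0:
        valid = np.ones_like(sample.void_mask)
    n = sample_specular_count(model, rng)
    ellipses = [sample_ellipse(model, sample.shape, valid, rng) for _ in range(n)]
    return render_specular(sample, ellipses)


def mean_filter(image: np.ndarray, window: int) -> np.ndarray:
    """Per-channel arithmetic-mean filter with edge replication.

    ``window`` must be odd and in [1, 15] (even windows have no center
    pixel); output is rounded half-away-from-zero to 8-bit.
    """
    if window not in BLUR_WINDOWS:
        raise ValueError(f"window must be one of {BLUR_WINDOWS}")
    if window == 1:
        return image.copy()
    out = np.stack(
        [
            ndimage.uniform_filter(image[..., c].astype(float), size=window, mode="nearest")
            for c in range(image.shape[-1])
        ],
        axis=-1,
    )
    return np.clip(np.floor(out + 0.5), 0, 255).astype(np.uint8)
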