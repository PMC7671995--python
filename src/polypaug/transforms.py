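"""Transformation vocabulary, parameter sampling and dispatch.

Fourteen transformation families are analysed in the ablation, grouped into
three categories:

* image-based (applied jointly to image and masks): width/height shift,
  rotation, shear, zoom in/out, horizontal/vertical flip, elastic
  deformation;
* pixel-based (image only): additive brightness and multiplicative contrast,
  each with all channels equal or per channel independently;
* application-based: specular highlights and mean-filter blur.

A :class:`TransformRange` names one family together with the interval its
parameter is drawn from; ``sample_*`` functions realize one random draw, and
:func:`apply_random_transform` draws-and-applies, which is what the training
loop calls every time a sample is served.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import artifact, geometric, photometric
from .artifact import SpecularModel
from .geometric import GeometricParams
from .photometric import PhotometricParams
from .sample import ImageSample

__all__ = [
    "TransformRange",
    "GEOMETRIC_NAMES",
    "PIXEL_NAMES",
    "APPLICATION_NAMES",
    "ALL_NAMES",
    "TRANSFORM_FAMILY",
    "TABLE_GRID",
    "spec_for",
    "sample_geometric_params",
    "sample_photometric_params",
    "apply_random_transform",
]

GEOMETRIC_NAMES = (
    "width_shift", "height_shift", "rotation", "shear",
    "zoom_in", "zoom_out", "flip_horizontal", "flip_vertical", "elastic",
)
PIXEL_NAMES = (
    "brightness_equal", "brightness_independent",
    "contrast_equal", "contrast_independent",
)
APPLICATION_NAMES = ("specular", "blur")
ALL_NAMES = GEOMETRIC_NAMES + PIXEL_NAMES + APPLICATION_NAMES

#: category of each transformation family
TRANSFORM_FAMILY = {
    **{n: "image" for n in GEOMETRIC_NAMES},
    **{n: "pixel" for n in PIXEL_NAMES},
    **{n: "application" for n in APPLICATION_NAMES},
}

#: the full grid of analysed ranges, in canonical order
TABLE_GRID: dict[str, list] = {
    "width_shift": [round(0.1 * k, 1) for k in range(1, 10)],
    "height_shift": [round(0.1 * k, 1) for k in range(1, 10)],
    "rotation": [3, 6, 10, 15, 45, 90, 135, 180],
    "shear": [3, 6, 10, 15, 45, 90, 135, 180],
    "zoom_in": [(round(1 - 0.1 * k, 1), 1.0) for k in range(1, 10)],
    "zoom_out": [(1.0, round(1 + 0.1 * k, 1)) for k in range(1, 11)],
    "flip_horizontal": [True],
    "flip_vertical": [True],
    "elastic": [(a, 40) for a in (250, 500, 1000, 2000, 3000, 4000, 5000, 6000)],
    "brightness_equal": [25 * k for k in range(1, 8)],
    "brightness_independent": [25 * k for k in range(1, 8)],
    "contrast_equal": [(round(1 - x, 1), round(1 + x, 1)) for x in (0.2, 0.4, 0.6, 0.8, 1.0)],
    "contrast_independent": [(round(1 - x, 1), round(1 + x, 1)) for x in (0.2, 0.4, 0.6, 0.8)],
    "specular": [True],
    "blur": [3, 5, 7, 9, 11, 13, 15],
}


@dataclass(frozen=True)
class TransformRange:
    """A named transformation family with its parameter interval.

    ``symmetric`` ranges draw uniformly in [-high, high]; asymmetric ones in
    [low, high].  Parameterless families (flips, specular) carry (0, 0).
    """

    name: str
    low: float = 0.0
    high: float = 0.0
    symmetric: bool = False

    def __post_init__(self) -> None:
        if self.name not in ALL_NAMES and self.name != "none":
            raise ValueError(f"unknown transformation {self.name!r}")
        # elastic stores (alpha, sigma) in (low, high), which is not an interval
        if self.name != "elastic" and self.low > self.high:
            raise ValueError("require low <= high")


def spec_for(name: str, value=None) -> TransformRange:
    """Build a :class:`TransformRange` from a grid-style range value.

    ``value`` is a scalar for symmetric families (shift fraction, degrees,
    brightness delta, blur window), a (low, high) pair for zoom/contrast
    intervals, and ignored for flips/specular.
    """
    if name == "none":
        return TransformRange("none")
    if name not in ALL_NAMES:
        raise ValueError(f"unknown transformation {name!r}")
    if name in ("flip_horizontal", "flip_vertical", "specular"):
        return TransformRange(name)
    if value is None:
        raise ValueError(f"{name} requires a range value")
    if isinstance(value, (tuple, list)):
        lo, hi = float(value[0]), float(value[1])
        return TransformRange(name, lo, hi, symmetric=False)
    v = float(value)
    symmetric = name in (
        "width_shift", "height_shift", "rotation", "shear",
        "brightness_equal", "brightness_independent",
    )
    return TransformRange(name, -v if symmetric else v, v, symmetric=symmetric)


def _draw(spec: TransformRange, rng: np.random.Generator) -> float:
    lo = -spec.high if spec.symmetric else spec.low
    return float(rng.uniform(lo, spec.high))


def sample_geometric_params(spec: TransformRange, rng: np.random.Generator) -> GeometricParams:
    """Realize one draw: exactly the named parameter deviates from identity."""
    name = spec.name
    if name == "width_shift":
        return GeometricParams(shift_x=_draw(spec, rng))
    if name == "height_shift":
        return GeometricParams(shift_y=_draw(spec, rng))
    if name == "rotation":
        return GeometricParams(rotation=_draw(spec, rng))
    if name == "shear":
        return GeometricParams(shear=_draw(spec, rng))
    if name in ("zoom_in", "zoom_out"):
        z = float(rng.uniform(spec.low, spec.high))  # one shared factor
        return GeometricParams(zoom_x=z, zoom_y=z)
    if name == "flip_horizontal":
        return GeometricParams(flip_h=bool(rng.uniform() < 0.5))
    if name == "flip_vertical":
        return GeometricParams(flip_v=bool(rng.uniform() < 0.5))
    if name == "elastic":
        return GeometricParams(elastic_alpha=spec.low, elastic_sigma=spec.high)
    raise ValueError(f"{name!r} is not an image-based transformation")


def sample_photometric_params(
    spec: TransformRange, independent: bool | None = None, rng: np.random.Generator | None = None
) -> PhotometricParams:
    """Realize one pixel-based draw.

    Brightness offsets are uniform in [-r, r]; contrast factors uniform in
    [low, high].  With shared channels a single draw is broadcast to all
    three.
    """
    assert rng is not None, "rng is required"
    name = spec.name
    if independent is None:
        independent = name.endswith("independent")
    size = 3 if independent else 1
    if name.startswith("brightness"):
        d = rng.uniform(-spec.high, spec.high, size=size)
        d = tuple(np.broadcast_to(d, (3,)).tolist())
        return PhotometricParams(brightness_delta=d, independent_channels=independent)
    if name.startswith("contrast"):
        lo = max(spec.low, 1e-6)  # factors must stay positive even for the [0, 2] range
        f = rng.uniform(lo, spec.high, size=size)
        f = tuple(np.broadcast_to(f, (3,)).tolist())
        return PhotometricParams(contrast_factor=f, independent_channels=independent)
    raise ValueError(f"{name!r} is not a pixel-based transformation")


def apply_random_transform(
    sample: ImageSample,
    spec,
    rng: np.random.Generator,
    specular_model: SpecularModel | None = None,
) -> ImageSample:
    """Draw parameters for ``spec`` and apply them to the sample.

    ``spec`` may be None / "none" (identity), one :class:`TransformRange`,
    or a list of them (a combination: applied image-based first, then
    pixel-based, then application-based, preserving in-category order).
    """
    if spec is None or (isinstance(spec, TransformRange) and spec.name == "none"):
        return sample.copy()
    if isinstance(spec, (list, tuple)):
        order = {"image": 0, "pixel": 1, "application": 2}
        ordered = sorted(spec, key=lambda s: order[TRANSFORM_FAMILY[s.name]])
        out = sample
        for s in ordered:
            out = apply_random_transform(out, s, rng, specular_model)
        return out

    name = spec.name
    if name in GEOMETRIC_NAMES:
        params = sample_geometric_params(spec, rng)
        return geometric.apply_geometric(sample, params, rng)
    if name in PIXEL_NAMES:
        params = sample_photometric_params(spec, rng=rng)
        out = sample.copy()
        if name.startswith("brightness"):
            out.image = photometric.adjust_brightness(out.image, params.brightness_delta)
        else:
            out.image = photometric.adjust_contrast(out.image, params.contrast_factor)
        return out
    if name == "specular":
        return artifact.add_specular_lights(sample, specular_model or SpecularModel(), rng)
    if name == "blur":
        out = sample.copy()
        out.image = artifact.mean_filter(out.image, int(spec.high))
        return out
    raise ValueError(f"unknown transformation {name!r}")
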