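"""Pixel-based augmentations: additive brightness and multiplicative contrast.

These operate on the image only; masks are never passed through them.  Both
ops work per RGB channel, either with a shared value for all channels or an
independent value per channel.  Output is always clipped to the 8-bit range;
rounding is half-away-from-zero so results are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PhotometricParams", "adjust_brightness", "adjust_contrast"]

_MAX_BRIGHTNESS = 175.0


@dataclass(frozen=True)
class PhotometricParams:
    """One realized draw of the pixel-based parameters (per RGB channel)."""

    brightness_delta: tuple[float, float, float] = (0.0, 0.0, 0.0)
    contrast_factor: tuple[float, float, float] = (1.0, 1.0, 1.0)
    independent_channels: bool = False

    def __post_init__(self) -> None:
        if any(abs(d) > _MAX_BRIGHTNESS for d in self.brightness_delta):
            raise ValueError(f"|brightness delta| must be <= {_MAX_BRIGHTNESS}")
        if any(f <= 0 for f in self.contrast_factor):
            raise ValueError("contrast factors must be positive")
        if not self.independent_channels:
            if len(set(self.brightness_delta)) > 1 or len(set(self.contrast_factor)) > 1:
                raise ValueError("shared-channel params must be equal across channels")


def adjust_brightness(image: np.ndarray, delta) -> np.ndarray:
    """out = clip(in + delta_c, 0, 255) per channel.

    ``delta`` may be a scalar (all channels equally) or a length-3 sequence.
    """
    delta = np.broadcast_to(np.atleast_1d(np.asarray(delta, dtype=float)), (3,))
    out = image.astype(float) + delta[None, None, :]
    return np.clip(np.floor(out + 0.5), 0, 255).astype(np.uint8)


def adjust_contrast(image: np.ndarray, factor) -> np.ndarray:
    """out = clip(round(in * factor_c), 0, 255) per channel.

    Pure multiplication about zero, no recentering; ``factor`` may be a
    scalar or a length-3 sequence of positive multipliers.
    """
    factor = np.broadcast_to(np.atleast_1d(np.asarray(factor, dtype=float)), (3,))
    if (factor <= 0).any():
        raise ValueError("contrast factors must be positive")
    out = image.astype(float) * factor[None, None, :]
    return np.clip(np.floor(out + 0.5), 0, 255).astype(np.uint8)
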