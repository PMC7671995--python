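"""Core data container: an RGB endoscopy frame with its polyp and void masks.

Every augmentation operator in this package consumes and returns an
:class:`ImageSample`.  The polyp mask is binary (1 = polyp), the void mask
marks the black region outside the optical field of view (1 = void); the
complement of the void mask is the "valid area" of the frame.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import imageio.v3 as iio
import numpy as np

__all__ = ["ImageSample", "load_sample", "save_sample", "load_dataset"]


@dataclass
class ImageSample:
    """Paired RGB image, binary polyp mask and binary void mask.

    Attributes
    ----------
    image : (H, W, 3) uint8 array, values in [0, 255].
    mask : (H, W) uint8 array in {0, 1}; 1 marks polyp pixels.
    void_mask : (H, W) uint8 array in {0, 1}; 1 marks the black border
        outside the endoscopic field of view.
    id : identifier used in manifests and result tables.
    """

    image: np.ndarray
    mask: np.ndarray
    void_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    id: str = ""

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=np.uint8)
        self.mask = np.asarray(self.mask, dtype=np.uint8)
        if self.void_mask is None:
            self.void_mask = np.zeros(self.mask.shape, dtype=np.uint8)
        self.void_mask = np.asarray(self.void_mask, dtype=np.uint8)
        if self.image.ndim != 3 or self.image.shape[2] != 3:
            raise ValueError("image must be H x W x 3")
        if self.image.shape[:2] != self.mask.shape or self.mask.shape != self.void_mask.shape:
            raise ValueError("image, mask and void_mask must share spatial dimensions")
        if not np.isin(self.mask, (0, 1)).all():
            raise ValueError("mask must be binary {0,1}")
        if not np.isin(self.void_mask, (0, 1)).all():
            raise ValueError("void_mask must be binary {0,1}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape  # type: ignore[return-value]

    def copy(self) -> "ImageSample":
        return replace(
            self,
            image=self.image.copy(),
            mask=self.mask.copy(),
            void_mask=self.void_mask.copy(),
        )


def save_sample(sample: ImageSample, root: str) -> dict[str, str]:
    """Write ``images/<id>.png``, ``masks/<id>.png`` and ``void/<id>.png``.

    Masks are stored as 0/255 PNGs, the usual convention for binary
    ground truth in segmentation datasets.  Returns the paths written.
    """
    paths = {}
    for sub, arr in (
        ("images", sample.image),
        ("masks", sample.mask * 255),
        ("void", sample.void_mask * 255),
    ):
        d = os.path.join(root, sub)
        os.makedirs(d, exist_ok=True)
        p = os.path.join(d, f"{sample.id}.png")
        iio.imwrite(p, arr.astype(np.uint8))
        paths[sub] = p
    return paths


def load_sample(root: str, sample_id: str) -> ImageSample:
    """Load one image/mask/void triple written by :func:`save_sample`."""
    image = iio.imread(os.path.join(root, "images", f"{sample_id}.png"))
    mask = iio.imread(os.path.join(root, "masks", f"{sample_id}.png"))
    void_path = os.path.join(root, "void", f"{sample_id}.png")
    void = iio.imread(void_path) if os.path.exists(void_path) else None
    mask = (np.asarray(mask) > 127).astype(np.uint8)
    if mask.ndim == 3:
        mask = mask[..., 0]
    if void is not None:
        void = (np.asarray(void) > 127).astype(np.uint8)
        if void.ndim == 3:
            void = void[..., 0]
    return ImageSample(image=image, mask=mask, void_mask=void, id=sample_id)


def load_dataset(root: str) -> list[ImageSample]:
    """Load every sample under ``root`` (paired images/ and masks/ PNGs)."""
    img_dir = os.path.join(root, "images")
    ids = sorted(os.path.splitext(f)[0] for f in os.listdir(img_dir) if f.endswith(".png"))
    return [load_sample(root, i) for i in ids]
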