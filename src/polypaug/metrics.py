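"""Dataset characterization metrics.

Five per-image statistics summarize an endoscopy dataset: the void-area
percentage (black border outside the field of view), the polyp area as a
percentage of the valid area, the mean HSV value channel, and two measures
of the luminance histogram — flatness (geometric mean of bin counts over
arithmetic mean) and spread (interquartile distance of the cumulative
histogram over the dynamic range).  ``dataset_summary`` aggregates them as
mean +- sd with min/max, the conventional way such tables are reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sample import ImageSample

__all__ = [
    "void_area_fraction",
    "polyp_area_fraction",
    "mean_value_channel",
    "histogram_flatness",
    "histogram_spread",
    "sample_metrics",
    "dataset_summary",
    "format_summary",
]

#: pixels with all channels at or below this count as void when no mask exists
DARKNESS_THRESHOLD = 8


def _value_channel(image: np.ndarray) -> np.ndarray:
    # HSV value channel: max over RGB
    return np.asarray(image).max(axis=2)


def void_area_fraction(sample: ImageSample, darkness_threshold: int = DARKNESS_THRESHOLD) -> float:
    """Percent of the frame that is void (black border).

    Uses the sample's void mask when present; otherwise detects pixels whose
    three channels are all at or below ``darkness_threshold`` (robust to
    compression noise).
    """
    if sample.void_mask.any():
        void = sample.void_mask.astype(bool)
    else:
        void = (sample.image <= darkness_threshold).all(axis=2)
    return 100.0 * float(void.sum()) / void.size


def polyp_area_fraction(sample: ImageSample) -> float:
    """Polyp pixels as a percent of the valid (non-void) area."""
    valid = (1 - sample.void_mask).sum()
    if valid == 0:
        raise ValueError("sample has no valid area")
    return 100.0 * float(sample.mask.sum()) / float(valid)


def mean_value_channel(image: np.ndarray) -> float:
    """Mean HSV value channel, max(R,G,B)/255, over all pixels."""
    return float(_value_channel(image).mean()) / 255.0


def _luminance_hist(image: np.ndarray) -> np.ndarray:
    return np.bincount(_value_channel(image).ravel(), minlength=256).astype(float)


def histogram_flatness(image: np.ndarray) -> float:
    """Geometric over arithmetic mean of the 256 luminance-histogram bins.

    1 for a perfectly uniform histogram; 0 as soon as any bin is empty.
    """
    counts = _luminance_hist(image)
    if (counts == 0).any():
        return 0.0
    gm = np.exp(np.mean(np.log(counts)))
    return float(gm / counts.mean())


def histogram_spread(image: np.ndarray) -> float:
    """Interquartile distance of the cumulative luminance histogram / 255."""
    counts = _luminance_hist(image)
    cum = np.cumsum(counts)
    total = cum[-1]
    q1 = int(np.searchsorted(cum, 0.25 * total))
    q3 = int(np.searchsorted(cum, 0.75 * total))
    return (q3 - q1) / 255.0


METRIC_NAMES = (
    "void_area_pct",
    "polyp_area_pct",
    "brightness_mean",
    "hist_flatness",
    "hist_spread",
)


def sample_metrics(sample: ImageSample) -> dict[str, float]:
    """All five metrics for one sample."""
    return {
        "void_area_pct": void_area_fraction(sample),
        "polyp_area_pct": polyp_area_fraction(sample),
        "brightness_mean": mean_value_channel(sample.image),
        "hist_flatness": histogram_flatness(sample.image),
        "hist_spread": histogram_spread(sample.image),
    }


@dataclass(frozen=True)
class MetricSummary:
    mean: float
    sd: float
    min: float
    max: float


def dataset_summary(samples: list[ImageSample]) -> dict[str, MetricSummary]:
    """(mean, sd, min, max) of each metric over a dataset."""
    if not samples:
        raise ValueError("dataset_summary needs at least one sample")
    table = pd.DataFrame([sample_metrics(s) for s in samples])
    out = {}
    for name in METRIC_NAMES:
        col = table[name]
        out[name] = MetricSummary(
            mean=float(col.mean()),
            sd=float(col.std(ddof=1)) if len(col) > 1 else 0.0,
            min=float(col.min()),
            max=float(col.max()),
        )
    return out


def format_summary(s: MetricSummary, decimals: int = 3) -> str:
    """Render one row as ``m +- s (max-min)``, e.g. ``0.622 ± 0.003 (1.000–0.000)``."""
    f = f"{{:.{decimals}f}}"
    return (
        f"{f.format(s.mean)} ± {f.format(s.sd)} "
        f"({f.format(s.max)}–{f.format(s.min)})"
    )
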