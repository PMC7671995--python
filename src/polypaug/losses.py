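"""Segmentation losses and the Jaccard index.

Pixel-wise polyp segmentation is heavily class-imbalanced (most pixels are
background), so the training loss combines binary cross-entropy with the
Jaccard index / IoU:

    Loss = -(1/n) sum_ij [ y_ij log yhat_ij + (1 - y_ij) log(1 - yhat_ij) ]
           - log J

where J is the soft (probability-weighted) Jaccard

    J = sum(y * yhat) / (sum y + sum yhat - sum(y * yhat)),

so the loss stays differentiable; evaluation-time IoU uses binarized masks.
Both terms are non-negative, so the loss is >= 0 and is 0 only for a perfect
prediction (up to the epsilon clamp).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "EPS",
    "jaccard_index",
    "soft_jaccard",
    "combined_loss",
    "combined_loss_grad",
    "binarize",
]

EPS = 1e-7


def jaccard_index(a: np.ndarray, b: np.ndarray) -> float:
    """Set-based IoU |A n B| / |A u B| between two binary masks.

    Returns 1.0 when both masks are empty: correctly predicting "no polyp"
    counts as a perfect match.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("mask shapes differ")
    a = a.astype(bool)
    b = b.astype(bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def soft_jaccard(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Probability-weighted Jaccard; 1.0 when both y and y_hat sum to zero."""
    inter = float((y * y_hat).sum())
    denom = float(y.sum() + y_hat.sum() - inter)
    if denom <= 0:
        return 1.0
    return inter / denom


def combined_loss(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Mean binary cross-entropy minus log of the soft Jaccard."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape:
        raise ValueError("y and y_hat shapes differ")
    p = np.clip(y_hat, EPS, 1.0 - EPS)
    bce = -np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))
    # the Jaccard term uses the unclamped probabilities so that an all-zero
    # prediction of an all-zero ground truth yields J = 1 (loss = BCE only)
    return float(bce - np.log(max(soft_jaccard(y, y_hat), EPS)))


def combined_loss_grad(y: np.ndarray, y_hat: np.ndarray) -> tuple[float, np.ndarray]:
    """Loss value and its gradient with respect to the probabilities."""
    y = np.asarray(y, dtype=float)
    raw = np.asarray(y_hat, dtype=float)
    p = np.clip(raw, EPS, 1.0 - EPS)
    n = y.size
    bce = -np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))
    d_bce = (-(y / p) + (1.0 - y) / (1.0 - p)) / n

    inter = float((y * raw).sum())
    union = float(y.sum() + raw.sum() - inter)
    if union <= 0:
        return float(bce), d_bce
    j = max(inter / union, EPS)
    # dJ/dp_k = (y_k * union - inter * (1 - y_k)) / union^2 ;  d(-log J) = -dJ/J
    d_j = (y * union - inter * (1.0 - y)) / (union * union)
    grad = d_bce - d_j / j
    return float(bce - np.log(j)), grad


def binarize(prob_map: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold a probability map at ``threshold`` (ties go to 1)."""
    return (np.asarray(prob_map) >= threshold).astype(np.uint8)
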