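"""Segmentation losses and evaluation metrics.

Training optimizes a convex combination of soft Dice loss and binary
cross-entropy, L = alpha * (1 - Dice) + (1 - alpha) * BCE.  Evaluation
reports pixel accuracy, hard Dice, class-averaged IoU (foreground and
background) and the 95th-percentile Hausdorff distance between mask
boundaries (max of the two directed 95th percentiles, Euclidean pixel
distances scaled by the pixel spacing).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_erosion, distance_transform_edt

__all__ = [
    "LossConfig",
    "dice_coefficient",
    "dice_loss",
    "bce_loss",
    "combined_loss",
    "focal_loss",
    "iou",
    "miou",
    "pixel_accuracy",
    "hd95",
    "evaluate_pair",
]


@dataclass(frozen=True)
class LossConfig:
    alpha: float = 0.5
    epsilon: float = 1e-6
    prob_clip: float = 1e-7

    def validate(self) -> None:
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must lie in [0, 1]")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if not 0 < self.prob_clip < 0.5:
            raise ValueError("prob_clip must lie in (0, 0.5)")


def _check_shapes(a, b):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a, b


def dice_coefficient(pred, target, epsilon: float = 1e-6) -> float:
    """2|P∩G| / (|P|+|G|); soft variant when ``pred`` holds probabilities."""
    p, g = _check_shapes(pred, target)
    inter = (p * g).sum()
    denom = p.sum() + g.sum()
    return float((2 * inter + epsilon) / (denom + epsilon))


def dice_loss(pred, target, epsilon: float = 1e-6) -> float:
    return 1.0 - dice_coefficient(pred, target, epsilon)


def bce_loss(target, probs, prob_clip: float = 1e-7) -> float:
    """Mean binary cross-entropy with probability clamping for the logs."""
    y, p = _check_shapes(target, probs)
    p = np.clip(p, prob_clip, 1 - prob_clip)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def combined_loss(target, probs, cfg: LossConfig | None = None) -> float:
    cfg = cfg or LossConfig()
    cfg.validate()
    return cfg.alpha * dice_loss(probs, target, cfg.epsilon) + (1 - cfg.alpha) * bce_loss(
        target, probs, cfg.prob_clip
    )


def focal_loss(target, probs, gamma: float = 2.0, prob_clip: float = 1e-7) -> float:
    """Focal loss -(1/N) sum (1-p_t)^gamma log p_t; gamma=0 reduces to BCE."""
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    y, p = _check_shapes(target, probs)
    p = np.clip(p, prob_clip, 1 - prob_clip)
    pt = np.where(y > 0.5, p, 1 - p)
    return float(-np.mean((1 - pt) ** gamma * np.log(pt)))


def iou(pred, target, epsilon: float = 1e-6) -> float:
    """Foreground intersection-over-union of two binary masks."""
    p, g = _check_shapes(pred, target)
    inter = np.logical_and(p > 0.5, g > 0.5).sum()
    union = np.logical_or(p > 0.5, g > 0.5).sum()
    return float((inter + epsilon) / (union + epsilon))


def miou(pred, target, epsilon: float = 1e-6) -> float:
    """Mean IoU over the foreground and background classes."""
    p, g = _check_shapes(pred, target)
    return 0.5 * (iou(p, g, epsilon) + iou(1 - p, 1 - g, epsilon))


def pixel_accuracy(pred, target) -> float:
    p, g = _check_shapes(pred, target)
    return float(np.mean((p > 0.5) == (g > 0.5)))


def _boundary(mask: np.ndarray) -> np.ndarray:
    m = mask > 0.5
    return m & ~binary_erosion(m, border_value=0)


def hd95(mask_a, mask_b, spacing: tuple[float, float] = (1.0, 1.0)) -> float:
    """95th-percentile Hausdorff distance between two mask boundaries.

    Max of the two directed 95th percentiles of boundary-to-boundary
    nearest-neighbour Euclidean distances.  Undefined (raises) when
    either mask is empty.
    """
    a, b = _check_shapes(mask_a, mask_b)
    ba = _boundary(a)
    bb = _boundary(b)
    if not ba.any() or not bb.any():
        raise ValueError("hd95 is undefined for an empty mask")
    dist_to_b = distance_transform_edt(~bb, sampling=spacing)
    dist_to_a = distance_transform_edt(~ba, sampling=spacing)
    d_ab = np.percentile(dist_to_b[ba], 95)
    d_ba = np.percentile(dist_to_a[bb], 95)
    return float(max(d_ab, d_ba))


def evaluate_pair(pred, target, spacing=(1.0, 1.0)) -> dict:
    """ACC / Dice / mIoU / HD95 for one binarized prediction."""
    out = {
        "accuracy": pixel_accuracy(pred, target),
        "dice": dice_coefficient((np.asarray(pred) > 0.5).astype(float),
                                 (np.asarray(target) > 0.5).astype(float)),
        "miou": miou(pred, target),
    }
    try:
        out["hd95"] = hd95(pred, target, spacing)
    except ValueError:
        out["hd95"] = float("nan")
    return out
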