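"""Image preprocessing chain: resize, z-normalize, clip outliers, rescale.

The full chain maps an arbitrary grayscale image to a fixed-size array in
[0, 1]: bilinear resize to the target shape, per-image standardization
(population SD), clamping of z-scores to +/- clip_bound to remove values
that deviate strongly from the average, and an affine rescale to [0, 1].
Elastic deformation is provided as a training-time augmentation that
warps image and mask with one shared smooth displacement field.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates
from skimage.transform import resize as _sk_resize

__all__ = [
    "PreprocConfig",
    "resize_image",
    "resize_mask",
    "zscore_normalize",
    "clip_outliers",
    "rescale_unit",
    "preprocess_image",
    "elastic_deform",
]


@dataclass(frozen=True)
class PreprocConfig:
    target_size: tuple[int, int] = (256, 256)
    clip_bound: float = 5.0
    elastic_alpha: float = 34.0
    elastic_sigma: float = 4.0
    seed: int = 0

    def validate(self) -> None:
        if min(self.target_size) < 1:
            raise ValueError("target_size must be positive")
        if self.clip_bound <= 0:
            raise ValueError("clip_bound must be > 0")


def resize_image(image: np.ndarray, target: tuple[int, int]) -> np.ndarray:
    """Bilinear resize of a grayscale image to ``target`` (rows, cols)."""
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise ValueError("image is empty")
    if min(target) < 1:
        raise ValueError("target size must be positive")
    if tuple(image.shape) == tuple(target):
        return image.copy()
    return _sk_resize(image, target, order=1, anti_aliasing=False, preserve_range=True)


def resize_mask(mask: np.ndarray, target: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbour resize; keeps a binary mask binary."""
    mask = np.asarray(mask)
    if min(target) < 1:
        raise ValueError("target size must be positive")
    out = _sk_resize(
        mask.astype(float), target, order=0, anti_aliasing=False, preserve_range=True
    )
    return out.astype(mask.dtype)


def zscore_normalize(image: np.ndarray) -> np.ndarray:
    """Subtract the mean and divide by the population SD."""
    image = np.asarray(image, dtype=float)
    sd = image.std()
    if sd == 0:
        raise ValueError("cannot z-normalize a constant image (SD = 0)")
    return (image - image.mean()) / sd


def clip_outliers(image: np.ndarray, bound: float = 5.0) -> np.ndarray:
    """Clamp z-scores into [-bound, +bound]; values inside are unchanged."""
    if bound <= 0:
        raise ValueError("bound must be > 0")
    return np.clip(np.asarray(image, dtype=float), -bound, bound)


def rescale_unit(image: np.ndarray) -> np.ndarray:
    """Affine map of the intensity range onto [0, 1]."""
    image = np.asarray(image, dtype=float)
    lo, hi = image.min(), image.max()
    if hi == lo:
        raise ValueError("cannot rescale a constant image")
    return (image - lo) / (hi - lo)


def preprocess_image(image: np.ndarray, cfg: PreprocConfig | None = None) -> np.ndarray:
    """Full chain: resize -> z-normalize -> clip -> rescale to [0, 1]."""
    cfg = cfg or PreprocConfig()
    cfg.validate()
    out = resize_image(image, cfg.target_size)
    out = zscore_normalize(out)
    out = clip_outliers(out, cfg.clip_bound)
    return rescale_unit(out)


def elastic_deform(
    image: np.ndarray, mask: np.ndarray, cfg: PreprocConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Warp image and mask with one shared smooth random displacement field.

    The field is i.i.d. uniform noise smoothed with a Gaussian of width
    ``elastic_sigma`` and scaled to magnitude ``elastic_alpha`` — the
    standard elastic-augmentation construction.  The image is warped
    bilinearly, the mask nearest-neighbour so it stays binary.
    """
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask)
    if image.shape != mask.shape:
        raise ValueError("image and mask must share a shape")
    rng = np.random.default_rng(cfg.seed)
    shape = image.shape
    dy = gaussian_filter(rng.uniform(-1, 1, shape), cfg.elastic_sigma) * cfg.elastic_alpha
    dx = gaussian_filter(rng.uniform(-1, 1, shape), cfg.elastic_sigma) * cfg.elastic_alpha
    yy, xx = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    coords = np.array([yy + dy, xx + dx])
    warped = map_coordinates(image, coords, order=1, mode="reflect")
    warped_mask = map_coordinates(mask.astype(float), coords, order=0, mode="reflect")
    return warped, warped_mask.astype(mask.dtype)
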