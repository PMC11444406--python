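"""Shape-guided segmentation: SLIC superpixels, pooling, unpooling, SGB.

SLIC over-segments the guidance image into compact, boundary-adherent
superpixels.  The superpixel pooling module aggregates a feature map
within each superpixel (mean by default), the shape-shared unpooling
module broadcasts each pooled vector back onto its superpixel support,
and the shape-guided block fuses the resulting piecewise-constant,
shape-respecting map with the incoming features by residual addition.
A shared 1 x 1 classification layer maps features to per-pixel logits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.segmentation import slic as _sk_slic

__all__ = [
    "SuperpixelMap",
    "PooledFeatures",
    "slic_oversegment",
    "superpixel_pool",
    "shape_shared_unpool",
    "shape_guided_block",
    "shared_classification_layer",
    "default_n_segments",
]


@dataclass(frozen=True)
class SuperpixelMap:
    """Integer label image partitioning pixels into connected superpixels."""

    labels: np.ndarray
    n_segments: int
    compactness: float

    @property
    def n_actual(self) -> int:
        return int(self.labels.max()) + 1

    @property
    def shape(self):
        return self.labels.shape


@dataclass(frozen=True)
class PooledFeatures:
    """One aggregated feature vector per superpixel label: values (K, F)."""

    values: np.ndarray
    labels: np.ndarray  # label ids, shape (K,)


def default_n_segments(shape: tuple[int, int], density: float = 100 / 256**2) -> int:
    """Superpixel count scaled with image area (100 at 256 x 256)."""
    return max(4, round(density * shape[0] * shape[1]))


def slic_oversegment(
    image: np.ndarray, n_segments: int, compactness: float = 0.2
) -> SuperpixelMap:
    """SLIC over-segmentation of a grayscale image.

    The returned labels form a partition into 4-connected regions with
    contiguous ids starting at 0; the actual count may fall below the
    request when SLIC merges fragments.  ``compactness`` trades boundary
    adherence against regular shape and should be scaled with the image
    intensity range (default 0.2 suits unit-range images).
    """
    image = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(image)):
        raise ValueError("guidance image must be finite")
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    if n_segments > image.size:
        raise ValueError("cannot request more superpixels than pixels")
    if n_segments == 1:
        labels = np.zeros(image.shape, dtype=np.int64)
    else:
        labels = _sk_slic(
            image,
            n_segments=n_segments,
            compactness=compactness,
            channel_axis=None,
            start_label=0,
            enforce_connectivity=True,
        ).astype(np.int64)
        # compact the label range in case SLIC skipped ids
        _, labels = np.unique(labels, return_inverse=True)
        labels = labels.reshape(image.shape)
    return SuperpixelMap(labels=labels, n_segments=n_segments, compactness=compactness)


def superpixel_pool(
    features: np.ndarray, sp: SuperpixelMap, reduce: str = "mean"
) -> PooledFeatures:
    """Aggregate an (F, H, W) feature map within each superpixel."""
    features = np.asarray(features, dtype=float)
    if features.ndim != 3:
        raise ValueError("features must have shape (F, H, W)")
    if features.shape[1:] != sp.shape:
        raise ValueError(
            f"spatial shape mismatch: features {features.shape[1:]}, labels {sp.shape}"
        )
    flat_lab = sp.labels.ravel()
    k = sp.n_actual
    f = features.shape[0]
    flat_feat = features.reshape(f, -1).T  # (P, F)
    if reduce == "mean":
        counts = np.bincount(flat_lab, minlength=k).astype(float)
        sums = np.zeros((k, f))
        np.add.at(sums, flat_lab, flat_feat)
        values = sums / counts[:, None]
    elif reduce == "max":
        values = np.full((k, f), -np.inf)
        np.maximum.at(values, flat_lab, flat_feat)
    else:
        raise ValueError(f"unknown reduction {reduce!r}")
    return PooledFeatures(values=values, labels=np.arange(k))


def shape_shared_unpool(pooled: PooledFeatures, sp: SuperpixelMap) -> np.ndarray:
    """Broadcast pooled vectors back onto their superpixel supports."""
    present = np.unique(sp.labels)
    have = set(pooled.labels.tolist())
    missing = [int(l) for l in present if int(l) not in have]
    if missing:
        raise ValueError(f"pooled features lack rows for labels {missing}")
    lookup = np.zeros(int(pooled.labels.max()) + 1, dtype=int)
    lookup[pooled.labels] = np.arange(len(pooled.labels))
    rows = lookup[sp.labels.ravel()]
    out = pooled.values[rows].T.reshape((pooled.values.shape[1],) + sp.shape)
    return out


def shape_guided_block(
    features: np.ndarray,
    image: np.ndarray,
    n_segments: int | None = None,
    compactness: float = 0.2,
    combine: str = "residual",
    reduce: str = "mean",
) -> np.ndarray:
    """Refine features with superpixel shape guidance.

    Runs SLIC on the guidance image, pools the features within each
    superpixel, unpools the result back to pixel resolution and combines
    it with the input: ``residual`` adds (so constant features double),
    ``replace`` returns the smoothed map alone.
    """
    features = np.asarray(features, dtype=float)
    image = np.asarray(image, dtype=float)
    if features.shape[1:] != image.shape:
        raise ValueError("features and guidance image disagree in spatial shape")
    if n_segments is None:
        n_segments = default_n_segments(image.shape)
    sp = slic_oversegment(image, n_segments, compactness)
    smoothed = shape_shared_unpool(superpixel_pool(features, sp, reduce), sp)
    if combine == "residual":
        return features + smoothed
    if combine == "replace":
        return smoothed
    raise ValueError(f"unknown combination {combine!r}")


def export_labels_png(sp: SuperpixelMap, path) -> None:
    """Write the label image as a PNG for visual inspection.

    Uses 8-bit for up to 256 labels, 16-bit beyond.
    """
    import imageio.v3 as iio

    labels = sp.labels
    dtype = np.uint8 if labels.max() < 256 else np.uint16
    iio.imwrite(path, labels.astype(dtype))


def shared_classification_layer(
    features: np.ndarray,
    weights: np.ndarray,
    bias: float = 0.0,
    apply_sigmoid: bool = False,
) -> np.ndarray:
    """Per-pixel linear map (F,) . (F,H,W) -> (H,W), shared at every pixel."""
    features = np.asarray(features, dtype=float)
    weights = np.asarray(weights, dtype=float).ravel()
    if features.shape[0] != weights.shape[0]:
        raise ValueError(
            f"weight length {weights.shape[0]} != feature channels {features.shape[0]}"
        )
    logits = np.tensordot(weights, features, axes=(0, 0)) + bias
    if apply_sigmoid:
        return 1.0 / (1.0 + np.exp(-logits))
    return logits
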