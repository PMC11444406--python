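"""Readers and writers for images, masks, manifests and configuration.

Grayscale images come from PNG/TIFF (8- or 16-bit), NIfTI or DICOM;
multi-channel inputs are collapsed by luminance, and pixel-spacing
metadata is retained when the format provides it so boundary distances
can be reported in millimetres.  Masks are written as lossless 0/255
PNG.  Coordinates are row-major, 0-based (row, col) throughout.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "read_image",
    "write_mask",
    "write_image_png16",
    "read_config",
    "write_config",
]

_LUMA = np.array([0.2126, 0.7152, 0.0722])


class ImageFormatError(ValueError):
    pass


def read_image(path) -> tuple[np.ndarray, dict]:
    """Read a grayscale 2D image; returns (array, metadata).

    Metadata carries ``spacing`` (row, col) in the format's units when
    available, else 1.0 pixels.
    """
    path = Path(path)
    if not path.exists():
        raise ImageFormatError(f"no such file: {path}")
    suffixes = "".join(path.suffixes).lower()
    meta = {"spacing": (1.0, 1.0), "path": str(path)}
    try:
        if suffixes.endswith((".nii", ".nii.gz")):
            import nibabel as nib

            img = nib.load(str(path))
            arr = np.asanyarray(img.dataobj)
            zooms = img.header.get_zooms()
            meta["spacing"] = (float(zooms[0]), float(zooms[1]))
            if arr.ndim == 3:
                arr = arr[..., arr.shape[2] // 2]
        elif suffixes.endswith(".dcm"):
            import pydicom

            ds = pydicom.dcmread(str(path))
            arr = ds.pixel_array
            if hasattr(ds, "PixelSpacing"):
                meta["spacing"] = (float(ds.PixelSpacing[0]), float(ds.PixelSpacing[1]))
        elif suffixes.endswith((".png", ".tif", ".tiff")):
            import imageio.v3 as iio

            arr = iio.imread(path)
        else:
            raise ImageFormatError(f"unsupported image format: {path}")
    except ImageFormatError:
        raise
    except Exception as exc:  # pragma: no cover - backend-specific failures
        raise ImageFormatError(f"could not read {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):
        arr = arr[..., :3] @ _LUMA
    if arr.ndim != 2:
        raise ImageFormatError(f"expected a 2D image in {path}, got shape {arr.shape}")
    return arr.astype(float), meta


def write_mask(mask: np.ndarray, path) -> None:
    """Write a binary mask as lossless 0/255 8-bit PNG."""
    mask = np.asarray(mask)
    values = np.unique(mask)
    if not np.all(np.isin(values, [0, 1])):
        raise ValueError("mask must be binary {0, 1}")
    import imageio.v3 as iio

    iio.imwrite(Path(path), (mask.astype(np.uint8) * 255))


def write_image_png16(image: np.ndarray, path) -> None:
    """Write a float image as 16-bit PNG (range mapped to [0, 65535])."""
    image = np.asarray(image, dtype=float)
    lo, hi = image.min(), image.max()
    scaled = np.zeros_like(image) if hi == lo else (image - lo) / (hi - lo)
    import imageio.v3 as iio

    iio.imwrite(Path(path), (scaled * 65535).round().astype(np.uint16))


def read_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return cfg


def write_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
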