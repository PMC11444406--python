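"""Seeded synthetic phantoms emulating mammographic lesion-on-texture structure.

A phantom is a textured background (smoothed Gaussian noise with a chosen
correlation length) plus zero or more bright lesion blobs.  Lesions are
ellipses with a low-order radial Fourier perturbation of the boundary, so
their outlines are irregular the way real masses and architectural
distortions are; the image-domain lesion edge is additionally blurred
while the ground-truth mask stays crisp on the unblurred support.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

__all__ = ["PhantomSpec", "Phantom", "generate_phantom", "generate_dataset"]

_MAX_BOUNDARY_PERTURBATION = 0.15  # fraction of the nominal radius
_MIN_AXIS_RATIO = 0.75


@dataclass(frozen=True)
class PhantomSpec:
    """Generation parameters for one phantom.

    contrast is the lesion mean intensity above background, expressed in
    units of the background-noise standard deviation; boundary_sigma is
    the Gaussian blur (pixels) applied to the lesion edge in the image
    only; texture_scale is the background correlation length (pixels).
    """

    height: int = 64
    width: int = 64
    n_lesions: int = 1
    radius_range: tuple[float, float] = (6.0, 12.0)
    contrast: float = 3.0
    boundary_sigma: float = 1.5
    texture_scale: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError("phantom dimensions must be positive")
        if self.n_lesions < 0:
            raise ValueError("n_lesions must be >= 0")
        lo, hi = self.radius_range
        if not (0 < lo <= hi):
            raise ValueError("radius_range must satisfy 0 < min <= max")
        if hi >= min(self.height, self.width) / 2:
            raise ValueError(
                "max lesion radius must be smaller than half the shorter image side"
            )
        if self.contrast < 0:
            raise ValueError("contrast must be >= 0")


@dataclass(frozen=True)
class Phantom:
    image: np.ndarray
    mask: np.ndarray
    spec: PhantomSpec


def _lesion_support(
    shape: tuple[int, int], center: tuple[float, float], radius: float, rng
) -> np.ndarray:
    """Boolean support of one irregular elliptical blob, fully inside frame."""
    h, w = shape
    cy, cx = center
    axis_ratio = rng.uniform(_MIN_AXIS_RATIO, 1.0)
    theta0 = rng.uniform(0, 2 * np.pi)
    # three low-order harmonics, total amplitude capped
    amps = rng.uniform(0, _MAX_BOUNDARY_PERTURBATION / 3, size=3)
    phases = rng.uniform(0, 2 * np.pi, size=3)

    yy, xx = np.mgrid[0:h, 0:w]
    dy = yy - cy
    dx = xx - cx
    # rotate then squeeze the minor axis
    ct, st = np.cos(theta0), np.sin(theta0)
    u = ct * dx + st * dy
    v = (-st * dx + ct * dy) / axis_ratio
    r = np.hypot(u, v)
    ang = np.arctan2(v, u)
    rho = radius * (
        1.0
        + sum(a * np.cos((m + 2) * ang + p) for m, (a, p) in enumerate(zip(amps, phases)))
    )
    return r <= rho


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Generate one phantom; identical specs give bit-identical output."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width

    noise = rng.standard_normal((h, w))
    background = gaussian_filter(noise, spec.texture_scale, mode="reflect")
    bg_sd = float(background.std())
    if bg_sd == 0.0:  # pathological texture_scale; fall back to raw noise SD
        bg_sd = 1.0

    mask = np.zeros((h, w), dtype=np.uint8)
    image = background.copy()
    for _ in range(spec.n_lesions):
        radius = rng.uniform(*spec.radius_range)
        margin = radius * (1 + _MAX_BOUNDARY_PERTURBATION) + 1
        cy = rng.uniform(margin, h - margin)
        cx = rng.uniform(margin, w - margin)
        support = _lesion_support((h, w), (cy, cx), radius, rng)
        mask[support] = 1
        bump = gaussian_filter(support.astype(float), spec.boundary_sigma)
        image += spec.contrast * bg_sd * bump

    return Phantom(image=image, mask=mask, spec=spec)


def generate_dataset(
    spec: PhantomSpec, n: int, seed: int
) -> tuple[list[Phantom], pd.DataFrame]:
    """Generate ``n`` phantoms with per-item derived seeds plus a manifest.

    The manifest records each item's id, seed, lesion count and mask area
    in pixels.  Item seeds are drawn from an independent stream keyed by
    ``seed``, so items are mutually independent and the whole collection
    is reproducible.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    spec.validate()
    rng = np.random.default_rng(seed)
    item_seeds = rng.integers(0, 2**31 - 1, size=n)
    phantoms = []
    rows = []
    for i, s in enumerate(item_seeds):
        item_spec = dataclasses.replace(spec, seed=int(s))
        ph = generate_phantom(item_spec)
        phantoms.append(ph)
        rows.append(
            {
                "id": i,
                "seed": int(s),
                "n_lesions": spec.n_lesions,
                "area_px": int(ph.mask.sum()),
            }
        )
    return phantoms, pd.DataFrame(rows)
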