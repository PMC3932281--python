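"""Synthetic phantoms and noise models for controlled segmentation tests.

The default phantom is a 128x128 image of three flat gray levels
(0, 160, 255) — well separated point masses in the histogram, so any
reasonable clustering recovers them exactly when the image is clean.
Ground-truth labels are returned alongside, and noise is applied to the
image only, which makes exact misclassification scoring possible.

Two noise models cover the usual degradation modes of acquired medical
images: impulse ("salt and pepper") noise at a given pixel-corruption
density, and additive zero-mean Gaussian noise with a given variance on
the unit gray scale.  Both are delegated to
:func:`skimage.util.random_noise` with a seeded generator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.util import random_noise

__all__ = [
    "PhantomSpec",
    "NoiseSpec",
    "make_phantom",
    "add_salt_pepper",
    "add_gaussian",
]


@dataclass
class PhantomSpec:
    """Geometry and gray levels of a synthetic phantom."""

    height: int = 128
    width: int = 128
    levels: tuple = (0, 160, 255)
    geometry: str = "bands"     # "bands" or "disk_square"
    seed: int | None = None     # reserved for randomized geometries

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError("phantom dimensions must be positive")
        lv = tuple(int(v) for v in self.levels)
        if not 2 <= len(lv) <= 8:
            raise ValueError(f"need 2..8 gray levels, got {len(lv)}")
        if any(not 0 <= v <= 255 for v in lv):
            raise ValueError("gray levels must lie in [0, 255]")
        if any(b <= a for a, b in zip(lv, lv[1:])):
            raise ValueError("gray levels must be strictly ascending")
        if self.geometry not in {"bands", "disk_square"}:
            raise ValueError(f"unknown geometry {self.geometry!r}")
        object.__setattr__(self, "levels", lv)


@dataclass
class NoiseSpec:
    """A noise condition: kind, level, and RNG seed.

    ``level`` is the corruption density for ``salt_pepper`` (fraction of
    pixels replaced, half black, half white) and the variance on the
    [0, 1] gray scale for ``gaussian``.
    """

    kind: str                   # "salt_pepper" or "gaussian"
    level: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in {"salt_pepper", "gaussian"}:
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.kind == "salt_pepper" and not 0 <= self.level <= 1:
            raise ValueError("salt_pepper density must lie in [0, 1]")
        if self.kind == "gaussian" and self.level < 0:
            raise ValueError("gaussian variance must be >= 0")

    def apply(self, image) -> np.ndarray:
        if self.kind == "salt_pepper":
            return add_salt_pepper(image, self.level, seed=self.seed)
        return add_gaussian(image, self.level, seed=self.seed)


def make_phantom(spec: PhantomSpec = PhantomSpec()):
    """Build a phantom image and its ground-truth label grid.

    ``bands``: |levels| vertical bands of equal width (within one pixel
    column).  ``disk_square``: flat background at levels[0], a centered
    disk at levels[1], and a top-left square at levels[2]; needs exactly
    three levels and a smallest dimension of at least 8.

    Returns
    -------
    (image, labels) : (uint8 ndarray, int ndarray), both height x width.
    """
    M, N = spec.height, spec.width
    k = len(spec.levels)
    if spec.geometry == "bands":
        if N < k:
            raise ValueError(f"width {N} too small for {k} bands")
        labels = np.broadcast_to(np.arange(N) * k // N, (M, N)).astype(np.intp).copy()
    else:  # disk_square
        if k != 3:
            raise ValueError("disk_square geometry needs exactly 3 gray levels")
        if min(M, N) < 8:
            raise ValueError("image too small for disk_square geometry (min dim 8)")
        labels = np.zeros((M, N), dtype=np.intp)
        r = min(M, N) // 4
        ii, jj = np.mgrid[0:M, 0:N]
        labels[(ii - M / 2) ** 2 + (jj - N / 2) ** 2 <= r ** 2] = 1
        s = min(M, N) // 4
        labels[1:1 + s, 1:1 + s] = 2
    image = np.asarray(spec.levels, dtype=np.uint8)[labels]
    return image, labels


def _as_uint8(image) -> np.ndarray:
    arr = np.asarray(image)
    if arr.ndim != 2:
        raise ValueError("image must be 2-D")
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("gray values must lie in [0, 255]")
    return arr.astype(np.uint8)


def add_salt_pepper(image, density: float, seed: int | None = None) -> np.ndarray:
    """Impulse noise: each pixel independently set to 0 or 255.

    A pixel is corrupted with probability ``density``, half of the hits
    to black and half to white; seeded and reproducible.
    """
    if not 0 <= density <= 1:
        raise ValueError("density must lie in [0, 1]")
    img = _as_uint8(image)
    if density == 0:
        return img.copy()
    noisy = random_noise(
        img, mode="s&p", amount=density, salt_vs_pepper=0.5,
        rng=np.random.default_rng(seed),
    )
    return np.rint(noisy * 255.0).astype(np.uint8)


def add_gaussian(image, variance: float, seed: int | None = None) -> np.ndarray:
    """Additive zero-mean Gaussian noise with ``variance`` on the unit scale.

    Grays are scaled to [0, 1], perturbed, clipped back to [0, 1],
    rescaled to [0, 255] and rounded; seeded and reproducible.
    """
    if variance < 0:
        raise ValueError("variance must be >= 0")
    img = _as_uint8(image)
    if variance == 0:
        return img.copy()
    noisy = random_noise(
        img, mode="gaussian", mean=0.0, var=variance, clip=True,
        rng=np.random.default_rng(seed),
    )
    return np.rint(noisy * 255.0).astype(np.uint8)
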