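"""Medium-truth-degree similarity between gray levels.

The similarity of two 8-bit gray values is scored by ratios of their
distances to two opposing anchor points just outside the gray range:
``-1`` below black and ``256`` above white.  For gray values ``f`` and
``x`` the one-sided truth degree is

.. math::

    h(f, x) = \\begin{cases}
        (f + 1)/(x + 1)       & f < x \\\\
        1                     & f = x \\\\
        (256 - f)/(256 - x)   & f > x,
    \\end{cases}

and the (symmetric) medium similarity measure is
``hh(f, x) = [h(f, x) + h(x, f)] / 2``.  ``hh`` lies in ``(0, 1]``,
equals 1 exactly when the grays are equal, and decays strictly as the
grays move apart, reaching its minimum ``1/256`` at the pair (0, 255).

Averaging ``hh`` between a pixel and its eight 3x3 neighbours yields a
per-pixel spatial weight field: close to 1 inside homogeneous regions,
low at impulse-noise pixels whose neighbourhood disagrees with them.
That field is what the clustering engine uses to decide how much a
pixel should trust its neighbourhood.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "GRAY_LEVELS",
    "medium_ratio",
    "medium_similarity",
    "similarity_table",
    "neighborhood_similarity_map",
]

#: Number of representable gray levels (8-bit images).
GRAY_LEVELS = 256

# Anchors of the "opposite" truth scales sit one step outside the gray range.
_LOW_ANCHOR = -1.0
_HIGH_ANCHOR = float(GRAY_LEVELS)

# The eight 3x3 neighbour offsets (row, col), center excluded.
_NEIGHBOR_OFFSETS = (
    (-1, -1), (-1, 0), (-1, 1),
    (0, -1), (0, 1),
    (1, -1), (1, 0), (1, 1),
)

_table_cache: np.ndarray | None = None


def _as_gray(values, name: str) -> np.ndarray:
    """Validate gray values: integral, within [0, 255]."""
    arr = np.asarray(values)
    if arr.size == 0:
        raise ValueError(f"{name}: empty gray-value input")
    if not np.issubdtype(arr.dtype, np.integer):
        if not (np.issubdtype(arr.dtype, np.floating) and np.all(np.mod(arr, 1) == 0)):
            raise ValueError(f"{name}: gray values must be integers, got dtype {arr.dtype}")
    lo, hi = int(arr.min()), int(arr.max())
    if lo < 0 or hi > GRAY_LEVELS - 1:
        raise ValueError(f"{name}: gray values must lie in [0, 255], got range [{lo}, {hi}]")
    return arr.astype(np.float64)


def medium_ratio(f, x):
    """One-sided (asymmetric) truth degree ``h(f, x)`` of "f is similar to x".

    Parameters
    ----------
    f, x : int or array-like of int
        Gray values in [0, 255]; broadcast against each other.

    Returns
    -------
    float or ndarray
        ``(f+1)/(x+1)`` if ``f < x``, ``1`` if ``f == x``,
        ``(256-f)/(256-x)`` if ``f > x``; always in (0, 1].
    """
    ff = _as_gray(f, "f")
    xx = _as_gray(x, "x")
    below = (ff - _LOW_ANCHOR) / (xx - _LOW_ANCHOR)
    above = (_HIGH_ANCHOR - ff) / (_HIGH_ANCHOR - xx)
    out = np.where(ff < xx, below, np.where(ff > xx, above, 1.0))
    if out.ndim == 0:
        return float(out)
    return out


def medium_similarity(f, x):
    """Symmetric medium similarity ``hh(f, x)`` of two gray values.

    The mean of the two one-sided ratios; symmetric, in (0, 1], and 1
    if and only if ``f == x``.
    """
    return 0.5 * (medium_ratio(f, x) + medium_ratio(x, f))


def similarity_table() -> np.ndarray:
    """Full 256x256 table ``T[a, b] = medium_similarity(a, b)`` (cached)."""
    global _table_cache
    if _table_cache is None:
        g = np.arange(GRAY_LEVELS)
        t = medium_similarity(g[:, None], g[None, :])
        t.setflags(write=False)
        _table_cache = t
    return _table_cache


def neighborhood_similarity_map(image, border_mode: str = "replicate") -> np.ndarray:
    """Mean medium similarity between each pixel and its 3x3 neighbours.

    Parameters
    ----------
    image : 2-D array of int
        Gray image with values in [0, 255].
    border_mode : {"replicate", "valid"}
        "replicate" pads the border by edge replication so every pixel
        averages over exactly 8 neighbours; "valid" averages only over
        the in-bounds neighbours (5 at edges, 3 at corners).

    Returns
    -------
    ndarray of float, same shape as ``image``
        Entries in (0, 1]; exactly 1 wherever the 3x3 window is constant.
    """
    img = _as_gray(image, "image")
    if img.ndim != 2:
        raise ValueError(f"image must be 2-D, got shape {np.shape(image)}")
    idx = img.astype(np.intp)
    lut = similarity_table()
    M, N = idx.shape

    if border_mode == "replicate":
        padded = np.pad(idx, 1, mode="edge")
        acc = np.zeros((M, N))
        for di, dj in _NEIGHBOR_OFFSETS:
            acc += lut[idx, padded[1 + di:1 + di + M, 1 + dj:1 + dj + N]]
        return acc / 8.0

    if border_mode == "valid":
        acc = np.zeros((M, N))
        cnt = np.zeros((M, N))
        for di, dj in _NEIGHBOR_OFFSETS:
            r0, r1 = max(0, -di), M - max(0, di)
            c0, c1 = max(0, -dj), N - max(0, dj)
            if r0 >= r1 or c0 >= c1:
                continue
            center = idx[r0:r1, c0:c1]
            neigh = idx[r0 + di:r1 + di, c0 + dj:c1 + dj]
            acc[r0:r1, c0:c1] += lut[center, neigh]
            cnt[r0:r1, c0:c1] += 1.0
        # a 1x1 image has no neighbours; a lone pixel is trivially uniform
        return np.where(cnt > 0, acc / np.maximum(cnt, 1.0), 1.0)

    raise ValueError(f"unknown border_mode {border_mode!r}")
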