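"""Fuzzy c-means clustering of gray images, plain and spatially regularized.

Two variants share one alternating-optimisation loop over cluster centers
``v_i`` and a c x n column-stochastic membership matrix ``u_ik`` (one column
per pixel, rasterized row-major):

* ``fcm`` — classical fuzzy c-means on the gray values alone:
  memberships from inverse distance ratios (fuzzifier ``m``), centers as
  membership^m-weighted gray means.
* ``mmtdfcm`` — before each center update the membership of every pixel
  is blended with the mean membership of its 3x3 neighbourhood, weighted
  by the pixel's medium-similarity field ``h_bar`` (computed once, before
  the loop).  With the default "sum" blend the neighbourhood term enters
  with its full |NB| = 8-fold weight and the column is renormalized:

      u'_ik  ∝  |NB| * h_bar(k) * ubar_ik  +  (1 - h_bar(k)) * u_ik

  which is a convex combination of ``u`` and ``ubar`` with effective
  neighbourhood weight ``|NB| h / (1 + (|NB|-1) h)``.  A pixel whose
  neighbourhood disagrees with it (impulse noise) is outvoted whenever
  ``h_bar > 1/(1+|NB|)``, which is what makes the variant noise-robust.
  The "mean" blend (weight ``h_bar`` directly) is available as an option.

Convergence is declared when the Chebyshev norm of the center change
drops below ``eps``; labels come from the maximum-membership rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .similarity import neighborhood_similarity_map

__all__ = [
    "FcmConfig",
    "SegmentationResult",
    "DegenerateClusterError",
    "init_centers",
    "fuzzy_membership",
    "mean_neighbor_membership",
    "medium_membership",
    "update_centers",
    "defuzzify",
    "fcm_objective",
    "segment",
    "run_fcm",
    "run_mmtdfcm",
]

logger = logging.getLogger(__name__)


class DegenerateClusterError(RuntimeError):
    """A cluster's total membership weight vanished and no fallback exists."""


@dataclass
class FcmConfig:
    """Parameters of a segmentation run.

    Attributes
    ----------
    c : number of clusters (>= 2).
    m : fuzzifier exponent (> 1); 2.0 is the customary default.
    eps : convergence threshold on the Chebyshev norm of the center step.
    max_iter : iteration cap; exceeding it yields ``converged=False``.
    init_method : "quantile" (deterministic histogram quantiles) or
        "random" (seeded draw of distinct pixel values).
    seed : RNG seed for random initialization.
    variant : "fcm" or "mmtdfcm".
    border_mode : "replicate" or "valid" 3x3 border handling.
    include_center : whether the center pixel joins its own neighbourhood.
    neighborhood_blend : "sum" (full-weight neighbourhood term, normalized)
        or "mean" (plain convex blend with weight ``h_bar``).
    """

    c: int = 3
    m: float = 2.0
    eps: float = 1e-5
    max_iter: int = 100
    init_method: str = "quantile"
    seed: int | None = None
    variant: str = "mmtdfcm"
    border_mode: str = "replicate"
    include_center: bool = False
    neighborhood_blend: str = "sum"

    def __post_init__(self) -> None:
        if self.c < 2:
            raise ValueError(f"c must be >= 2, got {self.c}")
        if not self.m > 1:
            raise ValueError(f"fuzzifier m must be > 1, got {self.m}")
        if not self.eps > 0:
            raise ValueError(f"eps must be > 0, got {self.eps}")
        if self.max_iter < 1:
            raise ValueError(f"max_iter must be >= 1, got {self.max_iter}")
        for name, value, allowed in (
            ("init_method", self.init_method, {"quantile", "random"}),
            ("variant", self.variant, {"fcm", "mmtdfcm"}),
            ("border_mode", self.border_mode, {"replicate", "valid"}),
            ("neighborhood_blend", self.neighborhood_blend, {"sum", "mean"}),
        ):
            if value not in allowed:
                raise ValueError(f"{name} must be one of {sorted(allowed)}, got {value!r}")


@dataclass
class SegmentationResult:
    """Output of one segmentation run."""

    labels: np.ndarray          # (M, N) int, values in [0, c)
    memberships: np.ndarray     # (c, n) final (blended for mmtdfcm)
    centers: np.ndarray         # (c,) gray-level centroids
    n_iter: int
    converged: bool
    center_history: list = field(default_factory=list)
    objective_history: list = field(default_factory=list)


def _check_image(image) -> np.ndarray:
    arr = np.asarray(image)
    if arr.ndim != 2:
        raise ValueError(f"image must be 2-D, got shape {arr.shape}")
    if not np.issubdtype(arr.dtype, np.integer):
        if not (np.issubdtype(arr.dtype, np.floating) and np.all(np.mod(arr, 1) == 0)):
            raise ValueError("image must contain integer gray values")
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("gray values must lie in [0, 255]")
    return arr


def _check_memberships(u) -> np.ndarray:
    u = np.asarray(u, dtype=np.float64)
    if u.ndim != 2:
        raise ValueError(f"membership matrix must be 2-D (c x n), got shape {u.shape}")
    if u.min() < -1e-12 or u.max() > 1 + 1e-12:
        raise ValueError("membership grades must lie in [0, 1]")
    return u


def init_centers(image, config: FcmConfig) -> np.ndarray:
    """Initial cluster centers for ``image`` under ``config``.

    The quantile method places the ``c`` centers at the (i + 1/2)/c
    quantiles of the gray histogram — deterministic and, for well
    separated gray masses, already close to the mass locations.  The
    random method draws ``c`` distinct pixel values with the config seed.
    """
    pixels = _check_image(image).astype(np.float64).ravel()
    if config.c > pixels.size:
        raise ValueError(f"c={config.c} exceeds pixel count {pixels.size}")
    if config.init_method == "quantile":
        q = (np.arange(config.c) + 0.5) / config.c
        return np.quantile(pixels, q)
    uniq = np.unique(pixels)
    if uniq.size < config.c:
        raise ValueError(
            f"random init needs {config.c} distinct gray values, image has {uniq.size}"
        )
    rng = np.random.default_rng(config.seed)
    return np.sort(rng.choice(uniq, size=config.c, replace=False))


def fuzzy_membership(pixels, centers, m: float) -> np.ndarray:
    """Classical FCM membership of each pixel to each center.

    ``u_ik = [ sum_j (d_ik / d_jk)^(2/(m-1)) ]^(-1)`` with ``d_ik = |x_k - v_i|``.
    A pixel at zero distance from some center gets a crisp column: grade 1
    for the first such center, 0 elsewhere.
    """
    x = np.asarray(pixels, dtype=np.float64).ravel()
    v = np.asarray(centers, dtype=np.float64).ravel()
    if not np.all(np.isfinite(v)):
        raise ValueError("cluster centers must be finite")
    if not m > 1:
        raise ValueError(f"fuzzifier m must be > 1, got {m}")
    d = np.abs(x[None, :] - v[:, None])
    expo = 2.0 / (m - 1.0)
    with np.errstate(divide="ignore", over="ignore"):
        p = d ** (-expo)
        colsum = p.sum(axis=0)
    bad = ~np.isfinite(colsum)  # some d_ik == 0 (or numerically so)
    u = np.empty_like(p)
    ok = ~bad
    u[:, ok] = p[:, ok] / colsum[ok]
    if bad.any():
        cols = np.where(bad)[0]
        winners = np.argmax(p[:, cols], axis=0)  # first maximal => lowest index
        u[:, cols] = 0.0
        u[winners, cols] = 1.0
    return u


def mean_neighbor_membership(
    memberships,
    image_shape,
    border_mode: str = "replicate",
    include_center: bool = False,
) -> np.ndarray:
    """Per-pixel mean of the membership columns over the 3x3 neighbourhood.

    Returns a matrix of the same shape; column-stochastic whenever the
    input is (the mean of stochastic columns is stochastic).
    """
    u = _check_memberships(memberships)
    M, N = image_shape
    c, n = u.shape
    if n != M * N:
        raise ValueError(f"membership columns ({n}) != pixels ({M}x{N}={M * N})")
    kernel = np.ones((3, 3))
    if not include_center:
        kernel[1, 1] = 0.0
    if border_mode == "replicate":
        mode, cval = "nearest", 0.0
        denom = kernel.sum()
    elif border_mode == "valid":
        mode, cval = "constant", 0.0
        denom = ndimage.correlate(np.ones((M, N)), kernel, mode=mode, cval=cval)
        denom = np.maximum(denom, 1.0)  # 1x1 image: no neighbours
    else:
        raise ValueError(f"unknown border_mode {border_mode!r}")
    out = np.empty_like(u)
    for i in range(c):
        sums = ndimage.correlate(u[i].reshape(M, N), kernel, mode=mode, cval=cval)
        out[i] = (sums / denom).ravel()
    return out


def medium_membership(u, u_bar, h_bar, neighborhood_size=8.0) -> np.ndarray:
    """Blend own and neighbourhood-mean memberships by the similarity field.

    Computes, per pixel k and cluster i,

        raw_ik = neighborhood_size * h_bar(k) * u_bar_ik + (1 - h_bar(k)) * u_ik

    and renormalizes each column to sum 1.  ``neighborhood_size`` is the
    weight carried by the neighbourhood term: the number of neighbours
    (scalar 8, or a per-pixel count array for "valid" borders) restores
    the neighbourhood SUM of memberships; 1 gives the plain convex blend
    ``h_bar * u_bar + (1 - h_bar) * u``.  Either way the result is a
    per-pixel convex combination of ``u`` and ``u_bar`` columns.
    """
    u = _check_memberships(u)
    ub = _check_memberships(u_bar)
    h = np.asarray(h_bar, dtype=np.float64).ravel()
    if u.shape != ub.shape:
        raise ValueError(f"shape mismatch: u {u.shape} vs u_bar {ub.shape}")
    if h.size != u.shape[1]:
        raise ValueError(f"h_bar has {h.size} entries for {u.shape[1]} pixels")
    if h.min() <= 0 or h.max() > 1:
        raise ValueError("h_bar entries must lie in (0, 1]")
    k = np.asarray(neighborhood_size, dtype=np.float64)
    if np.any(k < 1):
        raise ValueError("neighborhood_size must be >= 1")
    w = k.ravel() * h if k.ndim else k * h
    raw = w[None, :] * ub + (1.0 - h)[None, :] * u
    return raw / raw.sum(axis=0, keepdims=True)


def update_centers(memberships, pixels, m: float, prev_centers=None) -> np.ndarray:
    """Membership^m-weighted mean gray value per cluster.

    A cluster whose weights all vanish keeps its previous center (with a
    logged warning) when ``prev_centers`` is supplied, else raises
    :class:`DegenerateClusterError`.
    """
    u = _check_memberships(memberships)
    x = np.asarray(pixels, dtype=np.float64).ravel()
    w = u ** m
    den = w.sum(axis=1)
    num = w @ x
    if np.any(den == 0):
        if prev_centers is None:
            raise DegenerateClusterError(
                f"clusters {np.where(den == 0)[0].tolist()} have zero total membership"
            )
        logger.warning(
            "degenerate cluster(s) %s: keeping previous centers",
            np.where(den == 0)[0].tolist(),
        )
        prev = np.asarray(prev_centers, dtype=np.float64).ravel()
        return np.where(den > 0, num / np.where(den > 0, den, 1.0), prev)
    return num / den


def defuzzify(memberships, image_shape) -> np.ndarray:
    """Maximum-membership labels; ties go to the lowest cluster index."""
    u = _check_memberships(memberships)
    M, N = image_shape
    if u.shape[1] != M * N:
        raise ValueError("membership columns do not match image shape")
    return np.argmax(u, axis=0).reshape(M, N)


def fcm_objective(memberships, pixels, centers, m: float) -> float:
    """FCM cost ``J_m = sum_ik u_ik^m d_ik^2`` (diagnostic)."""
    u = np.asarray(memberships, dtype=np.float64)
    x = np.asarray(pixels, dtype=np.float64).ravel()
    v = np.asarray(centers, dtype=np.float64).ravel()
    d2 = (x[None, :] - v[:, None]) ** 2
    return float(np.sum(u ** m * d2))


def _neighborhood_weight(shape, border_mode: str, include_center: bool):
    """Neighbourhood size per pixel for the 'sum' blend."""
    if border_mode == "replicate":
        return 9.0 if include_center else 8.0
    kernel = np.ones((3, 3))
    if not include_center:
        kernel[1, 1] = 0.0
    counts = ndimage.correlate(np.ones(shape), kernel, mode="constant", cval=0.0)
    return np.maximum(counts, 1.0).ravel()


def segment(image, config: FcmConfig, initial_centers=None) -> SegmentationResult:
    """Run the configured variant on a gray image.

    The similarity field (mmtdfcm only) is computed once before the loop
    and held fixed.  Each iteration recomputes memberships from the
    current centers, blends them (mmtdfcm), and updates the centers;
    the loop stops when the largest center movement falls below
    ``config.eps`` or after ``config.max_iter`` iterations.  Fully
    deterministic given the config (including its seed).
    """
    img = _check_image(image)
    pixels = img.astype(np.float64).ravel()
    if initial_centers is not None:
        centers = np.asarray(initial_centers, dtype=np.float64).ravel()
        if centers.size != config.c:
            raise ValueError(f"expected {config.c} initial centers, got {centers.size}")
    else:
        centers = init_centers(img, config)
    logger.info(
        "segment: variant=%s c=%d m=%g eps=%g init=%s centers0=%s",
        config.variant, config.c, config.m, config.eps, config.init_method,
        np.round(centers, 3).tolist(),
    )

    spatial = config.variant == "mmtdfcm"
    if spatial:
        h_bar = neighborhood_similarity_map(img, config.border_mode).ravel()
        nb_weight = (
            _neighborhood_weight(img.shape, config.border_mode, config.include_center)
            if config.neighborhood_blend == "sum"
            else 1.0
        )

    history = [centers.copy()]
    objectives: list[float] = []
    converged = False
    n_iter = 0
    u = None
    for it in range(1, config.max_iter + 1):
        u = fuzzy_membership(pixels, centers, config.m)
        objectives.append(fcm_objective(u, pixels, centers, config.m))
        if spatial:
            u_bar = mean_neighbor_membership(
                u, img.shape, config.border_mode, config.include_center
            )
            u = medium_membership(u, u_bar, h_bar, nb_weight)
        new_centers = update_centers(u, pixels, config.m, prev_centers=centers)
        delta = float(np.max(np.abs(new_centers - centers)))
        centers = new_centers
        history.append(centers.copy())
        n_iter = it
        if delta < config.eps:
            converged = True
            break

    labels = defuzzify(u, img.shape)
    logger.info(
        "segment: finished after %d iteration(s), converged=%s, centers=%s",
        n_iter, converged, np.round(centers, 3).tolist(),
    )
    return SegmentationResult(
        labels=labels,
        memberships=u,
        centers=centers,
        n_iter=n_iter,
        converged=converged,
        center_history=history,
        objective_history=objectives,
    )


def run_fcm(image, config: FcmConfig | None = None, initial_centers=None, **kwargs):
    """Classical FCM on a gray image (``variant`` forced to ``"fcm"``)."""
    cfg = _with_variant(config, "fcm", kwargs)
    return segment(image, cfg, initial_centers=initial_centers)


def run_mmtdfcm(image, config: FcmConfig | None = None, initial_centers=None, **kwargs):
    """Spatially regularized variant (``variant`` forced to ``"mmtdfcm"``)."""
    cfg = _with_variant(config, "mmtdfcm", kwargs)
    return segment(image, cfg, initial_centers=initial_centers)


def _with_variant(config, variant: str, kwargs) -> FcmConfig:
    if config is None:
        return FcmConfig(variant=variant, **kwargs)
    if kwargs:
        raise TypeError("pass either a config object or keyword overrides, not both")
    from dataclasses import replace

    return replace(config, variant=variant)
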