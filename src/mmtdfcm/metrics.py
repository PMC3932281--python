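"""Segmentation quality metrics: PSNR, partition coefficient/entropy, accuracy.

PSNR compares a reference image with a processed one (for a segmentation,
the piecewise-constant reconstruction that replaces every pixel by its
cluster center).  The partition coefficient ``vpc = (1/n) sum u_ik^2``
and partition entropy ``vpe = -(1/n) sum u_ik log u_ik`` score how crisp
a fuzzy partition is: a hard partition gives (1, 0), the maximally fuzzy
one gives (1/c, log c).  Phantom experiments additionally report the
misclassification rate against the known ground truth, minimized over
all cluster relabelings.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from itertools import permutations

import numpy as np
from scipy.special import xlogy

__all__ = [
    "MetricsReport",
    "psnr",
    "partition_coefficient",
    "partition_entropy",
    "misclassification_rate",
    "reconstruction",
    "evaluate_result",
]


@dataclass
class MetricsReport:
    psnr: float                    # dB; +inf for identical images
    vpc: float                     # in [1/c, 1]
    vpe: float                     # in [0, log c]
    misclassification_rate: float | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["misclassification_rate"] is None:
            del d["misclassification_rate"]
        return {k: float(v) for k, v in d.items()}


def psnr(original, processed, peak: float | None = None) -> float:
    """Peak signal-to-noise ratio in dB.

    ``10 log10(peak^2 / MSE)``; ``peak`` defaults to the maximum gray
    level of the original image (pass 255 for fixed-peak comparability).
    Identical images give ``+inf``; an all-zero original with nonzero
    MSE gives ``-inf``.
    """
    x = np.asarray(original, dtype=np.float64)
    y = np.asarray(processed, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    mse = float(np.mean((x - y) ** 2))
    if mse == 0.0:
        return float("inf")
    xmax = float(x.max()) if peak is None else float(peak)
    if xmax == 0.0:
        return float("-inf")
    return 10.0 * np.log10(xmax ** 2 / mse)


def _check_memberships(u) -> np.ndarray:
    u = np.asarray(u, dtype=np.float64)
    if u.ndim != 2:
        raise ValueError("membership matrix must be 2-D (c x n)")
    return u


def partition_coefficient(memberships) -> float:
    """Bezdek's partition coefficient; higher = crisper, in [1/c, 1]."""
    u = _check_memberships(memberships)
    return float(np.sum(u ** 2) / u.shape[1])


def partition_entropy(memberships, base: float | None = None) -> float:
    """Bezdek's partition entropy; lower = crisper, in [0, log_base c].

    Natural log by default; ``0 log 0`` counts as 0.
    """
    u = _check_memberships(memberships)
    h = -float(np.sum(xlogy(u, u)) / u.shape[1]) + 0.0  # avoid -0.0
    if base is not None:
        h /= np.log(base)
    return h


def misclassification_rate(labels, truth, c: int) -> float:
    """Fraction of disagreeing pixels, minimized over cluster relabelings.

    Exhausts all c! permutations via the c x c contingency table, so it
    is exact; limited to c <= 8.
    """
    if c > 8:
        raise ValueError("misclassification_rate supports c <= 8 (factorial search)")
    a = np.asarray(labels).ravel()
    b = np.asarray(truth).ravel()
    if a.size != b.size:
        raise ValueError("label grids must have the same size")
    if a.min() < 0 or a.max() >= c or b.min() < 0:
        raise ValueError("labels out of range [0, c)")
    k = max(c, int(b.max()) + 1)
    contingency = np.zeros((k, k), dtype=np.int64)
    np.add.at(contingency, (a, b), 1)
    best = max(
        sum(contingency[i, perm[i]] for i in range(k))
        for perm in permutations(range(k))
    )
    return 1.0 - best / a.size


def reconstruction(labels, centers) -> np.ndarray:
    """Piecewise-constant image: every pixel replaced by its cluster center.

    Centers are rounded to the nearest integer gray level and clipped to
    [0, 255] so the result is a valid 8-bit image.
    """
    v = np.clip(np.rint(np.asarray(centers, dtype=np.float64)), 0, 255).astype(np.uint8)
    return v[np.asarray(labels)]


def evaluate_result(result, reference, truth=None, peak: float | None = None) -> MetricsReport:
    """Metrics report for a segmentation result.

    PSNR is taken between ``reference`` (normally the clean original)
    and the center reconstruction of ``result``; vpc/vpe come from the
    final membership matrix; the misclassification rate is added when a
    ground-truth label grid is given.
    """
    recon = reconstruction(result.labels, result.centers)
    mis = None
    if truth is not None:
        mis = misclassification_rate(result.labels, truth, c=result.memberships.shape[0])
    return MetricsReport(
        psnr=psnr(reference, recon, peak=peak),
        vpc=partition_coefficient(result.memberships),
        vpe=partition_entropy(result.memberships),
        misclassification_rate=mis,
    )
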