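"""Shared fixtures and independent brute-force oracles.

The oracles below deliberately use explicit Python loops and the
textbook formulas, independent of the vectorized implementation paths
they are used to check.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from mmtdfcm import FcmConfig, PhantomSpec, make_phantom

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


# ---------------------------------------------------------------- oracles

def h_oracle(f: int, x: int) -> float:
    """One-sided truth degree via direct case analysis."""
    if f < x:
        return (f + 1) / (x + 1)
    if f > x:
        return (256 - f) / (256 - x)
    return 1.0


def hh_oracle(f: int, x: int) -> float:
    return 0.5 * (h_oracle(f, x) + h_oracle(x, f))


def hbar_oracle(image: np.ndarray) -> np.ndarray:
    """Neighbourhood mean similarity with explicit loops, replicate border."""
    M, N = image.shape

    def px(i, j):
        return int(image[min(max(i, 0), M - 1), min(max(j, 0), N - 1)])

    out = np.zeros((M, N))
    for i in range(M):
        for j in range(N):
            total = 0.0
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    if di == 0 and dj == 0:
                        continue
                    total += hh_oracle(int(image[i, j]), px(i + di, j + dj))
            out[i, j] = total / 8.0
    return out


def membership_oracle(pixels, centers, m) -> np.ndarray:
    """Per-column membership with explicit loops and the degenerate rule."""
    x = [float(v) for v in pixels]
    v = [float(w) for w in centers]
    c, n = len(v), len(x)
    u = np.zeros((c, n))
    for k in range(n):
        d = [abs(x[k] - v[i]) for i in range(c)]
        if min(d) == 0.0:
            u[d.index(0.0), k] = 1.0
            continue
        for i in range(c):
            u[i, k] = 1.0 / sum((d[i] / d[j]) ** (2.0 / (m - 1.0)) for j in range(c))
    return u


def mmtd_iteration_oracle(image: np.ndarray, centers, m: float):
    """One full spatially-regularized iteration, transliterated with loops.

    Similarity field, memberships, neighbourhood SUM of memberships,
    blended membership (normalized per column), and the center update.
    Returns (u_blended, new_centers).
    """
    M, N = image.shape
    n = M * N
    x = image.astype(float).ravel()
    hbar = hbar_oracle(image).ravel()
    u = membership_oracle(x, centers, m)
    c = len(centers)

    def px_index(i, j):
        return min(max(i, 0), M - 1) * N + min(max(j, 0), N - 1)

    u_sum = np.zeros_like(u)
    for i in range(M):
        for j in range(N):
            k = i * N + j
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    if di == 0 and dj == 0:
                        continue
                    u_sum[:, k] += u[:, px_index(i + di, j + dj)]

    u_prime = np.zeros_like(u)
    for k in range(n):
        raw = hbar[k] * u_sum[:, k] + (1.0 - hbar[k]) * u[:, k]
        u_prime[:, k] = raw / raw.sum()

    new_centers = np.array([
        sum(u_prime[i, k] ** m * x[k] for k in range(n))
        / sum(u_prime[i, k] ** m for k in range(n))
        for i in range(c)
    ])
    return u_prime, new_centers


# ---------------------------------------------------------------- fixtures

@pytest.fixture(scope="session")
def phantom128():
    """The standard three-level 128x128 phantom and its ground truth."""
    return make_phantom(PhantomSpec())


@pytest.fixture()
def config3():
    return FcmConfig(c=3, m=2.0, eps=1e-5)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_stochastic(rng, c, n) -> np.ndarray:
    """Random column-stochastic membership matrix."""
    u = rng.random((c, n))
    return u / u.sum(axis=0, keepdims=True)
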