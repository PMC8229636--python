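"""Central finite differences with one Richardson extrapolation level.

Used as the fallback derivative supplier for models without closed-form
cumulant derivatives and as an independent cross-check in the test suite.
Step policy: ``h_i = max(1e-4 * |theta_i|, 1e-6)``.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

__all__ = ["fd_step", "fd_gradient", "fd_hessian", "fd_third"]


def fd_step(theta: np.ndarray) -> np.ndarray:
    theta = np.asarray(theta, dtype=float)
    return np.maximum(1e-4 * np.abs(theta), 1e-6)


def _central(f: Callable[[np.ndarray], float], theta: np.ndarray, i: int, h: float) -> float:
    e = np.zeros_like(theta)
    e[i] = h
    return (f(theta + e) - f(theta - e)) / (2.0 * h)


def _richardson(d: Callable[[float], float], h: float) -> float:
    return (4.0 * d(h / 2.0) - d(h)) / 3.0


def fd_gradient(f: Callable[[np.ndarray], float], theta: np.ndarray) -> np.ndarray:
    theta = np.asarray(theta, dtype=float)
    h = fd_step(theta)
    out = np.empty(theta.size)
    for i in range(theta.size):
        out[i] = _richardson(lambda hh: _central(f, theta, i, hh), h[i])
    return out


def fd_hessian(f: Callable[[np.ndarray], float], theta: np.ndarray) -> np.ndarray:
    """Hessian by central stencils with one Richardson level."""
    theta = np.asarray(theta, dtype=float)
    h = fd_step(theta)
    coarse = _hessian_at_step(f, theta, h)
    fine = _hessian_at_step(f, theta, h / 2.0)
    return (4.0 * fine - coarse) / 3.0


def _hessian_at_step(
    f: Callable[[np.ndarray], float], theta: np.ndarray, h: np.ndarray
) -> np.ndarray:
    k = theta.size
    out = np.empty((k, k))
    f0 = f(theta)
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = h[i]
        out[i, i] = (f(theta + ei) - 2 * f0 + f(theta - ei)) / h[i] ** 2
        for j in range(i + 1, k):
            ej = np.zeros(k)
            ej[j] = h[j]
            mixed = (
                f(theta + ei + ej)
                - f(theta + ei - ej)
                - f(theta - ei + ej)
                + f(theta - ei - ej)
            ) / (4 * h[i] * h[j])
            out[i, j] = out[j, i] = mixed
    return out


def fd_gradient_plain(f: Callable[[np.ndarray], float], theta: np.ndarray) -> np.ndarray:
    """Plain central gradient (no Richardson), used inside nested stencils."""
    theta = np.asarray(theta, dtype=float)
    h = fd_step(theta)
    out = np.empty(theta.size)
    for i in range(theta.size):
        out[i] = _central(f, theta, i, h[i])
    return out


def fd_third(f: Callable[[np.ndarray], float], theta: np.ndarray) -> np.ndarray:
    """Third-derivative tensor; symmetrized.

    Pure entries d_i^3 f use a direct 4-point stencil with one Richardson
    level (relative accuracy ~1e-8); mixed entries use nested second-order
    stencils (accuracy ~1e-5, adequate for the curvature assertions that
    consume them).
    """
    theta = np.asarray(theta, dtype=float)
    k = theta.size
    h = 10.0 * fd_step(theta)  # wider step: third differences lose ~h^2 accuracy
    out = np.empty((k, k, k))
    for i in range(k):
        e = np.zeros(k)
        e[i] = h[i]
        hp = fd_hessian_plain(f, theta + e)
        hm = fd_hessian_plain(f, theta - e)
        out[i] = (hp - hm) / (2 * h[i])
    for i in range(k):
        hi = max(0.01 * abs(theta[i]), 1e-4)
        e = np.zeros(k)
        e[i] = 1.0

        def pure(hh: float, _e=e) -> float:
            return (
                f(theta + 2 * hh * _e)
                - 2 * f(theta + hh * _e)
                + 2 * f(theta - hh * _e)
                - f(theta - 2 * hh * _e)
            ) / (2 * hh**3)

        out[i, i, i] = _richardson(pure, hi)
    # symmetrize over all index permutations
    sym = (
        out
        + out.transpose(0, 2, 1)
        + out.transpose(1, 0, 2)
        + out.transpose(1, 2, 0)
        + out.transpose(2, 0, 1)
        + out.transpose(2, 1, 0)
    ) / 6.0
    return sym


def fd_hessian_plain(f: Callable[[np.ndarray], float], theta: np.ndarray) -> np.ndarray:
    theta = np.asarray(theta, dtype=float)
    return _hessian_at_step(f, theta, fd_step(theta))
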