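"""Numerical inverse Laplace transforms on a vertical Bromwich line.

Primary method: the Fourier-series expansion of the Bromwich integral with
de Hoog-Knight-Stokes quotient-difference acceleration of the resulting
power series (a continued-fraction Pade evaluation).  The line never touches
the branch cut of S^{-alpha}, which the solvers keep on the non-positive
real axis.

Second opinion: Gaver-Stehfest, a real-node method, usable only where the
time function is smooth (away from shock arrivals).
"""

from __future__ import annotations

import math
from typing import Callable

import numpy as np

__all__ = ["dehoog", "stehfest"]

_TINY = 1e-300


def dehoog(F: Callable[[complex], np.ndarray | complex], t: float,
           M: int = 40, tol: float = 1e-12, sigma0: float = 0.0,
           T: float | None = None) -> np.ndarray | float:
    """Invert ``F`` at time ``t > 0``.

    ``F`` may return a scalar or an ndarray (vector-valued transform, e.g.
    sampled over positions); the inversion is applied elementwise.

    Parameters
    ----------
    M : half-order; 2M+1 transform evaluations are used.
    tol : target accuracy controlling the contour abscissa.
    sigma0 : lower bound for the abscissa (right of all singularities that
        are *not* removable; 0 suits every transform in this package).
    T : half-period of the Fourier expansion; default 2 t.
    """
    if not t > 0:
        raise ValueError("dehoog requires t > 0")
    if T is None:
        T = 2.0 * t
    gam = sigma0 - math.log(tol) / (2.0 * T)

    ks = np.arange(2 * M + 1)
    a = np.array([np.asarray(F(complex(gam, math.pi * k / T)), dtype=complex)
                  for k in ks])
    vec_shape = a.shape[1:]
    a = a.reshape(2 * M + 1, -1)
    a[0] *= 0.5

    # quotient-difference build of the continued-fraction coefficients d
    nv = a.shape[1]
    d = np.zeros((2 * M + 1, nv), dtype=complex)
    q_prev = a[1:] / np.where(a[:-1] == 0, _TINY, a[:-1])   # q^(1)
    e_prev = np.zeros((2 * M + 1, nv), dtype=complex)        # e^(0) = 0
    d[0] = a[0]
    d[1] = -q_prev[0]
    for r in range(1, M + 1):
        ncols = 2 * (M - r) + 1
        e_cur = q_prev[1:ncols + 1] - q_prev[:ncols] + e_prev[1:ncols + 1]
        d[2 * r] = -e_cur[0]
        if r < M:
            q_cur = q_prev[1:ncols] * e_cur[1:ncols] / \
                np.where(e_cur[:ncols - 1] == 0, _TINY, e_cur[:ncols - 1])
            d[2 * r + 1] = -q_cur[0]
            q_prev, e_prev = q_cur, e_cur
        else:
            break

    # continued fraction at z = exp(i pi t / T), with the standard remainder
    z = complex(math.cos(math.pi * t / T), math.sin(math.pi * t / T))
    A_prev2 = np.zeros(nv, dtype=complex)
    B_prev2 = np.ones(nv, dtype=complex)
    A_prev1 = d[0].copy()
    B_prev1 = np.ones(nv, dtype=complex)
    for n in range(1, 2 * M):
        A_cur = A_prev1 + d[n] * z * A_prev2
        B_cur = B_prev1 + d[n] * z * B_prev2
        A_prev2, A_prev1 = A_prev1, A_cur
        B_prev2, B_prev1 = B_prev1, B_cur
    h2m = 0.5 * (1.0 + z * (d[2 * M - 1] - d[2 * M]))
    r2m = -h2m * (1.0 - np.sqrt(1.0 + d[2 * M] * z / np.where(h2m == 0, _TINY, h2m) ** 2))
    A_fin = A_prev1 + r2m * A_prev2
    B_fin = B_prev1 + r2m * B_prev2
    vals = (np.exp(gam * t) / T) * (A_fin / np.where(B_fin == 0, _TINY, B_fin)).real
    if vec_shape == ():
        return float(vals[0])
    return vals.reshape(vec_shape)


def _stehfest_weights(N: int) -> np.ndarray:
    w = np.zeros(N)
    for k in range(1, N + 1):
        s = 0.0
        for j in range((k + 1) // 2, min(k, N // 2) + 1):
            s += (j ** (N // 2) * math.factorial(2 * j)
                  / (math.factorial(N // 2 - j) * math.factorial(j)
                     * math.factorial(j - 1) * math.factorial(k - j)
                     * math.factorial(2 * j - k)))
        w[k - 1] = (-1) ** (k + N // 2) * s
    return w


def stehfest(F: Callable[[complex], np.ndarray | complex], t: float,
             N: int = 16) -> np.ndarray | float:
    """Gaver-Stehfest inversion with N (even) real nodes k ln2 / t."""
    if not t > 0:
        raise ValueError("stehfest requires t > 0")
    if N % 2:
        raise ValueError("N must be even")
    w = _stehfest_weights(N)
    ln2t = math.log(2.0) / t
    total = None
    for k in range(1, N + 1):
        term = w[k - 1] * np.asarray(F(complex(k * ln2t, 0.0)))
        total = term if total is None else total + term
    out = np.real(total) * ln2t
    if np.ndim(out) == 0:
        return float(out)
    return out
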