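"""Prabhakar fractional integral and regularized derivative as numerical
operators on uniformly sampled functions, plus the exact Laplace-domain
multiplier of the operator.

The integral

    E^gamma_{alpha,zeta,eta} h(t) = int_0^t (t-s)^{zeta-1}
        E^gamma_{alpha,zeta}(eta (t-s)^alpha) h(s) ds

is discretized by product integration: on each subinterval the *entire*
weakly singular kernel (power times Mittag-Leffler factor) is integrated
exactly against a piecewise linear interpolant of h, using termwise-exact
running moments of the kernel series.  The only discretization error is the
linear interpolation of h, so the scheme is O(h^2) without nested adaptive
quadrature (midpoint treatment of the Mittag-Leffler factor alone would
degrade to O(h^{zeta+alpha}) at the singular end).

The regularized derivative D^gamma_{alpha,zeta,eta} h is the same integral
with (zeta, gamma) -> (m - zeta, -gamma) applied to h^(m), m = ceil(zeta);
the model only uses zeta in (0,1), so m = 1 is the production path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import rgamma

from .mlfunc import ml3

__all__ = [
    "SampledFunction",
    "prabhakar_integral",
    "prabhakar_derivative",
    "laplace_multiplier",
]


@dataclass
class SampledFunction:
    """A function sampled on a uniform grid starting at t = 0.

    ``derivative`` optionally carries samples of h' on the same grid; when it
    is absent the regularized derivative falls back to second-order finite
    differences.
    """

    times: np.ndarray
    values: np.ndarray
    derivative: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.size < 2:
            raise ValueError("need a 1-D grid with at least two samples")
        if self.times[0] != 0.0:
            raise ValueError("grid must start at t = 0")
        steps = np.diff(self.times)
        if not np.allclose(steps, steps[0], rtol=1e-10, atol=0.0) or steps[0] <= 0:
            raise ValueError("grid must be uniform and increasing")
        if self.values.shape != self.times.shape:
            raise ValueError("values and times must have equal length")
        if self.derivative is not None:
            self.derivative = np.asarray(self.derivative, dtype=float)
            if self.derivative.shape != self.times.shape:
                raise ValueError("derivative samples must match the grid")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def index_of(self, t: float) -> int:
        idx = int(round(t / self.dt))
        if idx < 0 or idx >= self.times.size or abs(self.times[idx] - t) > 1e-9 * max(1.0, abs(t)):
            raise ValueError(f"t={t} is not on the sample grid")
        return idx

    def fd_derivative(self) -> np.ndarray:
        """Second-order finite-difference estimate of h'."""
        return np.gradient(self.values, self.dt, edge_order=2)


def _kernel_moments(xs: np.ndarray, alpha: float, zeta: float, gamma: float,
                    eta: float, tol: float = 1e-15,
                    j_max: int = 200) -> tuple[np.ndarray, np.ndarray]:
    """Exact running moments of the Prabhakar kernel k(t) = t^{zeta-1} E(eta t^alpha).

    Returns (K, M1) with K(x) = int_0^x k and M1(x) = int_0^x tau k(tau) dtau,
    both by termwise integration of the kernel series (requires zeta > 0).
    """
    xs = np.asarray(xs, dtype=float)
    k0 = np.zeros_like(xs)
    m1 = np.zeros_like(xs)
    xz = xs ** zeta
    xz1 = xs ** (zeta + 1.0)
    xa = xs ** alpha
    coef = 1.0          # (gamma)_j eta^j / j!
    xpow = np.ones_like(xs)
    for j in range(j_max):
        if j > 0:
            coef *= (gamma + j - 1.0) * eta / j
            xpow = xpow * xa
            if coef == 0.0:
                break
        aj = alpha * j + zeta
        t0 = coef * xpow * rgamma(aj + 1.0)
        t1 = coef * xpow * rgamma(aj) / (aj + 1.0)
        k0 += t0
        m1 += t1
        if j > 2 and aj > 2.0 and \
                np.all(np.abs(t0) <= tol * np.maximum(np.abs(k0), 1e-300)) and \
                np.all(np.abs(t1) <= tol * np.maximum(np.abs(m1), 1e-300)):
            break
    else:
        raise ArithmeticError(
            f"kernel moment series did not converge (alpha={alpha}, "
            f"zeta={zeta}, gamma={gamma}, eta={eta}, max x={xs.max()})")
    return xz * k0, xz1 * m1


def _product_integration(samples: np.ndarray, dt: float, n: int, alpha: float,
                         zeta: float, gamma: float, eta: float) -> float:
    """sum_j int_{j dt}^{(j+1) dt} k(tau) g(t - tau) dtau

    with g piecewise linear through ``samples`` (g(t - j dt) = samples[n-j])
    and the full weakly singular kernel integrated exactly against it via
    its running zeroth and first moments (O(h^2) overall from the linear
    interpolation of g alone).
    """
    edges = np.arange(n + 1, dtype=float) * dt
    K, M1 = _kernel_moments(edges, alpha, zeta, gamma, eta)
    dK = np.diff(K)
    dM1 = np.diff(M1)
    j = np.arange(n, dtype=float)
    a = samples[n::-1][:n]             # g at tau = j dt  -> samples[n-j]
    b = samples[n - 1::-1][:n] - a     # samples[n-j-1] - samples[n-j]
    # g(t - tau) = (a - b j) + (b/dt) tau  on the j-th subinterval
    return float(np.sum((a - b * j) * dK + (b / dt) * dM1))


def prabhakar_integral(h: SampledFunction, alpha: float, zeta: float,
                       gamma: float, eta: float, t: float) -> float:
    """Prabhakar integral E^gamma_{alpha,zeta,eta} h evaluated at a grid time."""
    if not zeta > 0:
        raise ValueError("prabhakar_integral requires zeta > 0 "
                         "(kernel not integrable otherwise)")
    if not alpha > 0:
        raise ValueError("alpha must be > 0")
    n = h.index_of(t)
    if n == 0:
        return 0.0
    return _product_integration(h.values, h.dt, n, alpha, zeta, gamma, eta)


def prabhakar_derivative(h: SampledFunction, alpha: float, zeta: float,
                         gamma: float, eta: float, t: float) -> float:
    """Regularized Prabhakar derivative D^gamma_{alpha,zeta,eta} h at a grid time.

    Supports non-integer zeta > 0 with m = ceil(zeta); the production model
    only uses zeta in (0,1).  Integer zeta is rejected (never used by the
    model, and m - zeta = 0 breaks the integral form).
    """
    if not zeta > 0:
        raise ValueError("zeta must be > 0")
    m = math.ceil(zeta)
    if m == zeta:
        raise ValueError("integer zeta is unsupported (m - zeta must lie in (0,1))")
    if m > 1:
        raise NotImplementedError(
            "only zeta in (0,1) (m = 1) is required by the model")
    n = h.index_of(t)
    if n == 0:
        return 0.0
    if h.derivative is not None:
        dsamp = h.derivative
    else:
        dsamp = h.fd_derivative()
    return _product_integration(dsamp, h.dt, n, alpha, m - zeta, -gamma, eta)


def laplace_multiplier(S: complex, alpha: float, beta: float, gamma: float,
                       eta: float) -> complex:
    """Laplace-domain symbol  S^beta (1 - eta S^{-alpha})^gamma  of the operator.

    Principal-branch powers throughout; the branch cuts of S^{-alpha} and of
    (1 - eta S^{-alpha})^gamma sit on the non-positive real axis, so the
    symbol is continuous on the open right half-plane, where it is required
    (Re S > 0).  beta = gamma = 0 gives 1 (classical Fourier law).
    """
    S = complex(S)
    if not S.real > 0:
        raise ValueError(f"laplace_multiplier requires Re(S) > 0, got S={S}")
    return S ** beta * (1.0 - eta * S ** (-alpha)) ** gamma
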