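"""Three-parameter (Prabhakar) Mittag-Leffler function and its kernel.

The function

    E^gamma_{alpha, zeta}(z) = sum_n (gamma)_n z^n / (n! Gamma(alpha n + zeta))

is the kernel generator of the Prabhakar fractional operators used by the
bioheat solvers.  The series solution needs it at *negative and non-integer*
second parameter ``zeta`` and negative third parameter ``gamma``; evaluation
is defined for every real (zeta, gamma) through

* the rising-factorial (Pochhammer) form ``(gamma)_n = gamma (gamma+1) ...
  (gamma+n-1)``, so ``gamma = 0`` leaves only the n = 0 term and negative
  integer ``gamma`` truncates the series, and
* the reciprocal-gamma convention: ``1/Gamma`` vanishes at non-positive
  integers, so terms whose ``alpha n + zeta`` lands on a pole contribute 0.

Only direct summation is provided, with an adaptive term count and a hard
argument radius beyond which evaluation fails loudly; every use in this
package has a small-to-moderate argument ``wp * t**alpha`` and a wrong
asymptotic would be worse than a refusal.  When the partial sums are much
larger than the result (alternating Gamma-ratio terms at ``zeta <= 0``),
the summation escalates transparently to high-precision arithmetic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import mpmath as mp
import numpy as np
from scipy.special import rgamma

__all__ = ["MLArgs", "MLConvergenceError", "ml3", "prabhakar_kernel"]

#: hard evaluation radius for |z| (see module docstring)
Z_MAX = 50.0

#: cancellation ratio (max partial sum / result) that triggers the
#: high-precision fallback
_CANCEL_ESCALATE = 1e6

_MAX_TERMS = 600
_MP_DPS = 50


class MLConvergenceError(ArithmeticError):
    """Raised when the Mittag-Leffler series does not settle within the cap."""


@dataclass(frozen=True)
class MLArgs:
    """Argument bundle for :func:`ml3`.

    alpha : first parameter, must be > 0.
    zeta  : second parameter, any real (non-positive values arise in the
            shock-response series).
    gamma : third parameter, any real.
    z     : real or complex argument, |z| <= Z_MAX.
    """

    alpha: float
    zeta: float
    gamma: float
    z: complex

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError(f"ml3 requires alpha > 0, got alpha={self.alpha}")


def _ml3_float(alpha: float, zeta: float, gamma: float, z: complex,
               tol: float) -> tuple[complex, float, bool]:
    """Double-precision summation.

    Returns (value, max |partial sum|, converged flag).
    """
    total = 0.0 + 0.0j
    max_partial = 0.0
    poch = 1.0            # (gamma)_n
    zpow = 1.0 + 0.0j     # z^n / n!
    settled = 0
    for n in range(_MAX_TERMS):
        if n > 0:
            poch *= gamma + n - 1.0
            zpow *= z / n
            if poch == 0.0:
                # negative-integer gamma: series terminates exactly
                return total, max_partial, True
        term = poch * zpow * rgamma(alpha * n + zeta)
        total += term
        max_partial = max(max_partial, abs(total))
        # past the Gamma poles the terms decay super-geometrically; require a
        # few consecutive negligible terms before declaring convergence
        if alpha * n + zeta > 2.0 and abs(term) <= tol * max(abs(total), 1e-300):
            settled += 1
            if settled >= 4:
                return total, max_partial, True
        else:
            settled = 0
    return total, max_partial, False


def _ml3_mp(alpha: float, zeta: float, gamma: float, z: complex,
            tol: float) -> complex:
    """High-precision summation used when cancellation eats double precision."""
    with mp.workdps(_MP_DPS):
        a, zt, g = mp.mpf(alpha), mp.mpf(zeta), mp.mpf(gamma)
        zz = mp.mpmathify(z)
        total = mp.mpf(0)
        poch = mp.mpf(1)
        zpow = mp.mpf(1)
        settled = 0
        for n in range(4 * _MAX_TERMS):
            if n > 0:
                poch *= g + n - 1
                zpow *= zz / n
                if poch == 0:
                    break
            term = poch * zpow * mp.rgamma(a * n + zt)
            total += term
            if a * n + zt > 2 and abs(term) <= tol * max(abs(total), mp.mpf('1e-300')):
                settled += 1
                if settled >= 4:
                    break
            else:
                settled = 0
        else:
            raise MLConvergenceError(
                f"ml3 did not converge at high precision: alpha={alpha}, "
                f"zeta={zeta}, gamma={gamma}, z={z}")
        out = complex(total)
    return out


def ml3(alpha: float, zeta: float, gamma: float, z: complex,
        tol: float = 1e-14) -> complex | float:
    """Evaluate the three-parameter Mittag-Leffler function E^gamma_{alpha,zeta}(z).

    Parameters follow :class:`MLArgs`; a real result is returned for real
    input.  Raises :class:`MLConvergenceError` on non-convergence and
    ``ValueError`` for alpha <= 0 or |z| > Z_MAX.
    """
    if not alpha > 0:
        raise ValueError(f"ml3 requires alpha > 0, got alpha={alpha}")
    if abs(z) > Z_MAX:
        raise ValueError(
            f"|z|={abs(z):.3g} exceeds the configured radius Z_MAX={Z_MAX}; "
            "direct summation is unreliable there and no asymptotic branch "
            "is provided")
    value, max_partial, ok = _ml3_float(alpha, zeta, gamma, complex(z), tol)
    scale = max(abs(value), 1e-300)
    if not ok or max_partial > _CANCEL_ESCALATE * scale:
        value = _ml3_mp(alpha, zeta, gamma, complex(z), tol)
        if not ok and value != 0.0 and abs(value) < 1e-250:
            raise MLConvergenceError(
                f"ml3 non-convergent: alpha={alpha}, zeta={zeta}, "
                f"gamma={gamma}, z={z}")
    if isinstance(z, complex) and z.imag != 0.0:
        return value
    return value.real


def ml3_args(args: MLArgs, tol: float = 1e-14) -> complex | float:
    """:func:`ml3` on an :class:`MLArgs` bundle."""
    return ml3(args.alpha, args.zeta, args.gamma, args.z, tol=tol)


def prabhakar_kernel(t: float, alpha: float, zeta: float, gamma: float,
                     eta: float) -> float:
    """Prabhakar kernel  t^{zeta-1} E^gamma_{alpha,zeta}(eta t^alpha).

    Defined pointwise for t > 0 only; for zeta < 1 the kernel is singular as
    t -> 0+ but finite at every positive t.
    """
    if not t > 0:
        raise ValueError(f"prabhakar_kernel needs t > 0, got t={t}")
    return t ** (zeta - 1.0) * ml3(alpha, zeta, gamma, eta * t ** alpha)


def prabhakar_kernel_antiderivative(x: float, alpha: float, zeta: float,
                                    gamma: float, eta: float) -> float:
    """Exact running integral of the kernel: int_0^x k = x^zeta E^gamma_{alpha,zeta+1}(eta x^alpha).

    Requires zeta > 0 (integrable singularity); used by the convolution
    quadratures of the time-domain solver.
    """
    if x == 0.0:
        return 0.0
    if not x > 0:
        raise ValueError("antiderivative defined for x >= 0")
    if not zeta > 0:
        raise ValueError("kernel integrable only for zeta > 0")
    return x ** zeta * ml3(alpha, zeta + 1.0, gamma, eta * x ** alpha)
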