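"""Shared independent oracles for the test suite.

These deliberately avoid the production code paths they check: the
finite-difference collocation oracle solves the Laplace-domain boundary value
problem on a dense mesh, and the quadrature transform computes Laplace
transforms of kernels by direct numerical integration.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import quad
from scipy.linalg import solve_banded


def fd_collocation(phi_eval: float, S: complex, p, n: int = 4096) -> complex:
    """Solve d2Tb/dphi2 = A^2 Tb - f/W on a dense mesh, Neumann ends.

    Second-order central differences with mirror-ghost closure; complex
    tridiagonal solve.  Independent of the closed-form solution path.
    """
    from prabheat.laplace_solver import characteristic_root
    from prabheat.prabhakar_ops import laplace_multiplier

    A2 = characteristic_root(S, p) ** 2
    W = laplace_multiplier(S, p.alpha, p.beta, p.gamma, p.wp)
    h = 1.0 / n
    x = np.linspace(0.0, 1.0, n + 1)
    f = (p.Q0 * np.exp(-p.b0 * x * S) + p.Qm / S) / W
    ab = np.zeros((3, n + 1), dtype=complex)
    ab[1, :] = -2.0 / h ** 2 - A2
    ab[0, 1:] = 1.0 / h ** 2
    ab[2, :-1] = 1.0 / h ** 2
    ab[0, 1] = 2.0 / h ** 2
    ab[2, -2] = 2.0 / h ** 2
    T = solve_banded((1, 1), ab, -f)
    return complex(np.interp(phi_eval, x, T.real) + 1j * np.interp(phi_eval, x, T.imag))


def laplace_by_quadrature(fn, S: float, T: float = 40.0) -> float:
    """int_0^T e^{-S t} fn(t) dt by adaptive quadrature (real S > 0).

    T is chosen so the truncated tail is negligible for the decaying
    integrands used in the tests.
    """
    val, _ = quad(lambda t: np.exp(-S * t) * fn(t), 0.0, T,
                  limit=400, epsabs=1e-13, epsrel=1e-11)
    return val
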