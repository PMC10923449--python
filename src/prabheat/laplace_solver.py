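"""Exact Laplace-domain solution of the fractional bioheat boundary-value
problem and its numerical inversion to T(phi, t).  This is the production
solution path.

Model (dimensionless): on phi in [0,1], t > 0,

    dT/dt = -dq/dphi - a0 T + Q0 delta(t - b0 phi) + Qm,
    q     = -D^gamma_{alpha,beta,wp} dT/dphi       (generalized Fourier law),

with T(phi,0) = 0 and insulated ends dT/dphi = 0 at phi = 0, 1.  In the
Laplace domain the temperature satisfies

    d2Tb/dphi2 = A(S)^2 Tb - [Q0 e^{-b0 phi S} + Qm/S] / W(S),

with W(S) = S^beta (1 - wp S^-alpha)^gamma and A(S) = sqrt((S+a0)/W(S)).
The closed form is

    Tb = e1 e^{-phi A} + e2 e^{phi A} + Q0 e^{-b0 phi S}/Den(S) + Qm/(S(S+a0)),
    Den(S) = (S + a0) - b0^2 S^{beta+2} W(S) / S^beta ... (see ``denominator``),

with (e1, e2) solved exactly from the two Neumann conditions.  All
exponentials are assembled from e^{-c A} factors with c >= 0 so nothing
overflows on the inversion contour (Re A grows like sqrt|S|).
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from ._inversion import dehoog, stehfest
from .prabhakar_ops import laplace_multiplier

__all__ = [
    "ModelParams",
    "DimensionalParams",
    "TemperatureField",
    "nondimensionalize",
    "characteristic_root",
    "denominator",
    "laplace_temperature",
    "laplace_gradient",
    "residual_check",
    "invert",
    "solve",
    "den_real_zeros",
]


@dataclass(frozen=True)
class ModelParams:
    """Dimensionless parameter bundle shared by all three solvers.

    alpha : Prabhakar kernel order, in (0, 1].
    beta  : flux memory exponent, >= 0 (beta = gamma = 0 is classical).
    gamma : kernel power, >= 0.
    wp    : Prabhakar kernel parameter (curly-p), default range [0, 1).
    a0    : blood perfusion coefficient, > 0.
    b0    : inverse shock speed, > 0 (shock line t = b0 phi).
    Q0    : thermal shock strength, >= 0.
    Qm    : metabolic source, >= 0 (steady state Qm/a0).
    """

    alpha: float = 0.8
    beta: float = 0.4
    gamma: float = 0.6
    wp: float = 0.2
    a0: float = 1.0
    b0: float = 0.5
    Q0: float = 1.0
    Qm: float = 1.2

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError("alpha must lie in (0, 1]")
        if self.beta < 0 or self.gamma < 0:
            raise ValueError("beta and gamma must be >= 0")
        if not self.a0 > 0:
            raise ValueError("a0 must be > 0 (steady state Qm/a0)")
        if not self.b0 > 0:
            raise ValueError("b0 must be > 0")
        if self.Q0 < 0 or self.Qm < 0:
            raise ValueError("source strengths must be >= 0")

    @property
    def classical(self) -> bool:
        """True when the flux law reduces to the classical Fourier law."""
        return self.beta == 0.0 and self.gamma == 0.0


@dataclass(frozen=True)
class DimensionalParams:
    """Dimensional tissue/blood properties (SI units).

    rho_t, C_t, k_t : tissue density, specific heat, conductivity.
    rho_b, C_b, w_b : blood density, specific heat, perfusion rate.
    Ta : arterial (reference) temperature; upsilon : shock speed;
    L : tissue slab length; Q0_dim, Qm_dim : dimensional source strengths.
    """

    rho_t: float
    C_t: float
    k_t: float
    rho_b: float
    C_b: float
    w_b: float
    Ta: float
    upsilon: float
    L: float
    Q0_dim: float = 0.0
    Qm_dim: float = 0.0

    def __post_init__(self) -> None:
        for name in ("rho_t", "C_t", "k_t", "rho_b", "C_b", "Ta",
                     "upsilon", "L"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.w_b < 0:
            raise ValueError("w_b must be >= 0")

    @property
    def eta_t(self) -> float:
        """Tissue thermal diffusivity k_t / (C_t rho_t)."""
        return self.k_t / (self.C_t * self.rho_t)


def nondimensionalize(d: DimensionalParams, *, alpha: float = 1.0,
                      beta: float = 0.0, gamma: float = 0.0,
                      wp: float = 0.0) -> tuple[ModelParams, dict]:
    """Map dimensional properties to the dimensionless bundle.

    The fractional orders and kernel parameter are dimensionless by nature
    and are passed through.  Returns (params, scale report); the report holds
    every scale factor needed to round-trip dimensional fields:
    t = t* L^2/eta_t, phi = phi* L, T = Ta (1 + T*), q = q* Ta k_t / L.
    """
    eta = d.eta_t
    a0 = d.w_b * d.C_b * d.rho_b * d.L ** 2 / (eta * d.C_t * d.rho_t)
    b0 = eta / (d.L * d.upsilon)
    if not a0 > 0:
        raise ValueError(
            f"perfusion coefficient a0={a0} violates a0 > 0 (w_b={d.w_b}); "
            "the model needs nonzero blood perfusion")
    scales = {
        "t_scale": d.L ** 2 / eta,           # dimensional time per unit t*
        "phi_scale": d.L,
        "T_ref": d.Ta,                        # T = Ta (1 + T*)
        "q_scale": d.Ta * d.k_t / d.L,
        "Q0_scale": d.upsilon * d.rho_t * d.C_t * d.Ta,
        "Qm_scale": d.Ta * d.k_t / d.L ** 2,
        "eta_t": eta,
    }
    p = ModelParams(alpha=alpha, beta=beta, gamma=gamma, wp=wp,
                    a0=a0, b0=b0,
                    Q0=d.Q0_dim / scales["Q0_scale"],
                    Qm=d.Qm_dim / scales["Qm_scale"])
    return p, scales


@dataclass
class TemperatureField:
    """T(phi, t) sampled on a rectangular grid; values shape (n_phi, n_t)."""

    phi_grid: np.ndarray
    t_grid: np.ndarray
    values: np.ndarray
    provenance: str = "laplace"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.phi_grid = np.asarray(self.phi_grid, dtype=float)
        self.t_grid = np.asarray(self.t_grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.phi_grid.size, self.t_grid.size):
            raise ValueError("values must have shape (n_phi, n_t)")


def _symbol(S: complex, p: ModelParams) -> complex:
    """Flux symbol W(S) = S^beta (1 - wp S^-alpha)^gamma."""
    return laplace_multiplier(S, p.alpha, p.beta, p.gamma, p.wp)


def denominator(S: complex, p: ModelParams) -> complex:
    """Den(S) = (S + a0) - b0^2 S^{beta+2} (1 - wp S^-alpha)^gamma.

    Pole candidate of the shock particular solution (removable in the
    assembled temperature; see ``den_real_zeros``).
    """
    S = complex(S)
    return (S + p.a0) - p.b0 ** 2 * S ** 2 * _symbol(S, p)


def characteristic_root(S: complex, p: ModelParams) -> complex:
    """A(S) = sqrt((S + a0) / W(S)), principal root with Re A >= 0."""
    A = cmath.sqrt((complex(S) + p.a0) / _symbol(S, p))
    if A.real < 0:
        A = -A
    return A


def _pieces(phi: np.ndarray, S: complex, p: ModelParams):
    """Common sub-expressions of the closed form, overflow-safe."""
    S = complex(S)
    A = characteristic_root(S, p)
    den = denominator(S, p)
    W = _symbol(S, p)
    G = p.b0 * S * p.Q0 / (A * den)
    em2A = cmath.exp(-2.0 * A)
    geom = 1.0 - em2A
    return A, den, W, G, geom


def laplace_temperature(phi, S: complex, p: ModelParams,
                        bracket_variant: bool = False):
    """Transformed temperature Tb(phi, S); phi scalar or array, Re S > 0.

    The production path solves the two Neumann boundary conditions exactly
    for the homogeneous constants: with G = b0 S Q0 / (A Den),

        e1 = G (e^{-b0 S} - e^{A}) / (e^{A} - e^{-A}),
        e2 = G (e^{-b0 S} - e^{-A}) / (e^{A} - e^{-A}),

    assembled purely from decaying exponentials.  ``bracket_variant`` switches
    to the bracket form of the solution, in which the "constants" are
    written with e^{+-phi A} inside the brackets.  Those brackets collapse
    algebraically (for phi != 0) to a phi-independent homogeneous part
    -E(S) e^{-b0 S}, which cannot satisfy the Neumann conditions; the
    variant is kept only as a diagnostic.
    """
    phi_arr = np.atleast_1d(np.asarray(phi, dtype=float))
    if np.any(phi_arr < 0) or np.any(phi_arr > 1):
        raise ValueError("phi must lie in [0, 1]")
    S = complex(S)
    if not S.real > 0:
        raise ValueError("laplace_temperature requires Re(S) > 0")
    A, den, W, G, geom = _pieces(phi_arr, S, p)
    eb = cmath.exp(-p.b0 * S)
    part = p.Q0 * np.exp(-p.b0 * phi_arr * S) / den
    unif = p.Qm / (S * (S + p.a0))
    if not bracket_variant:
        # e1 e^{-phi A} + e2 e^{phi A}, divided through by e^{A}
        homog = G * ((eb * np.exp(-(1.0 + phi_arr) * A) - np.exp(-phi_arr * A))
                     + (eb * np.exp(-(1.0 - phi_arr) * A)
                        - np.exp(-(2.0 - phi_arr) * A))) / geom
    else:
        # phi-dependent brackets; their exact algebraic sum
        homog = np.full_like(phi_arr, -G * eb, dtype=complex)
    out = homog + part + unif
    if np.ndim(phi) == 0:
        return complex(out[0])
    return out


def laplace_gradient(phi, S: complex, p: ModelParams):
    """d Tb / d phi of the production closed form (analytic)."""
    phi_arr = np.atleast_1d(np.asarray(phi, dtype=float))
    S = complex(S)
    A, den, W, G, geom = _pieces(phi_arr, S, p)
    eb = cmath.exp(-p.b0 * S)
    dpart = -p.b0 * S * p.Q0 * np.exp(-p.b0 * phi_arr * S) / den
    dhomog = G * A * (-(eb * np.exp(-(1.0 + phi_arr) * A) - np.exp(-phi_arr * A))
                      + (eb * np.exp(-(1.0 - phi_arr) * A)
                         - np.exp(-(2.0 - phi_arr) * A))) / geom
    out = dhomog + dpart
    if np.ndim(phi) == 0:
        return complex(out[0])
    return out


def _second_derivative(phi, S: complex, p: ModelParams):
    phi_arr = np.atleast_1d(np.asarray(phi, dtype=float))
    S = complex(S)
    A, den, W, G, geom = _pieces(phi_arr, S, p)
    eb = cmath.exp(-p.b0 * S)
    d2part = (p.b0 * S) ** 2 * p.Q0 * np.exp(-p.b0 * phi_arr * S) / den
    d2homog = G * A ** 2 * ((eb * np.exp(-(1.0 + phi_arr) * A) - np.exp(-phi_arr * A))
                            + (eb * np.exp(-(1.0 - phi_arr) * A)
                               - np.exp(-(2.0 - phi_arr) * A))) / geom
    return d2homog + d2part


def residual_check(phi: float, S: complex, p: ModelParams,
                   bracket_variant: bool = False) -> tuple[float, float, float]:
    """Relative residuals of (ODE, Neumann at 0, Neumann at 1).

    The ODE residual uses the analytic second derivative of the closed form;
    all three vanish to rounding for the BC-solved constants.  With
    ``bracket_variant`` the boundary residuals of the bracket form
    are reported instead (diagnostic; expected nonzero).
    """
    S = complex(S)
    W = _symbol(S, p)
    A = characteristic_root(S, p)
    den = denominator(S, p)
    Tb = laplace_temperature(phi, S, p, bracket_variant=bracket_variant)
    forcing = (p.Q0 * cmath.exp(-p.b0 * phi * S) + p.Qm / S) / W
    if bracket_variant:
        # the bracket-variant homogeneous part is constant in phi
        d2 = (p.b0 * S) ** 2 * p.Q0 * cmath.exp(-p.b0 * phi * S) / den
        gpart = -p.b0 * S * p.Q0 / den
        g0 = gpart
        g1 = gpart * cmath.exp(-p.b0 * S)
        scale = max(abs(A ** 2 * Tb), abs(forcing), 1e-30)
        ode = abs(d2 - (A ** 2 * complex(np.atleast_1d(Tb)[0]) - forcing)) / scale
        gscale = max(abs(gpart), 1e-30)
        return ode, abs(g0) / gscale, abs(g1) / gscale
    d2 = complex(np.atleast_1d(_second_derivative(phi, S, p))[0])
    g0 = complex(laplace_gradient(0.0, S, p))
    g1 = complex(laplace_gradient(1.0, S, p))
    scale = max(abs(A ** 2 * Tb), abs(forcing), 1e-30)
    ode = abs(d2 - (A ** 2 * Tb - forcing)) / scale
    gscale = max(abs(p.b0 * S * p.Q0 / den), abs(A * Tb), 1e-30)
    return ode, abs(g0) / gscale, abs(g1) / gscale


def den_real_zeros(p: ModelParams, s_max: float = 200.0) -> list[float]:
    """Real positive zeros of Den(S) located by a sign-change scan + bisection.

    Den is real on the real axis only where 1 - wp S^-alpha > 0, i.e.
    S > wp^(1/alpha); the scan starts there.  These zeros are removable
    singularities of the assembled temperature (homogeneous and particular
    parts blow up individually and cancel), so the inversion contour need
    not move right of them -- it only avoids placing the abscissa close to
    one (cancellation noise).
    """
    s_lo = max(1e-6, (p.wp ** (1.0 / p.alpha)) * (1.0 + 1e-9) if p.wp > 0 else 1e-6)
    grid = np.geomspace(s_lo + 1e-9, s_max, 400)
    vals = np.array([denominator(s, p).real for s in grid])
    zeros: list[float] = []
    for i in range(len(grid) - 1):
        if vals[i] == 0.0:
            zeros.append(float(grid[i]))
        elif vals[i] * vals[i + 1] < 0:
            lo, hi = grid[i], grid[i + 1]
            for _ in range(80):
                mid = 0.5 * (lo + hi)
                if denominator(mid, p).real * denominator(lo, p).real <= 0:
                    hi = mid
                else:
                    lo = mid
            zeros.append(0.5 * (lo + hi))
    return zeros


def invert(field: Callable[[np.ndarray, complex], np.ndarray],
           phi_grid, t_grid, p: ModelParams | None = None,
           method: str = "dehoog", M: int = 40,
           tol: float = 1e-12) -> TemperatureField:
    """Invert a Laplace field (map (phi, S) -> Tb) onto a (phi, t) grid.

    ``field(phi_grid, S)`` must return the transformed values at all
    positions for one complex frequency.  When ``p`` is given, the contour
    abscissa is nudged away from any real zero of Den(S) before inversion.
    """
    phi_grid = np.asarray(phi_grid, dtype=float)
    t_grid = np.asarray(t_grid, dtype=float)
    if np.any(t_grid <= 0):
        raise ValueError("t_grid must be strictly positive")
    zeros = den_real_zeros(p) if (p is not None and p.Q0 != 0) else []
    vals = np.empty((phi_grid.size, t_grid.size))
    for j, t in enumerate(t_grid):
        T = 2.0 * t
        gam = -math.log(tol) / (2.0 * T)
        sigma0 = 0.0
        for z in zeros:
            if abs(gam + sigma0 - z) < 0.25:
                sigma0 = z + 0.3 - gam
        if method == "dehoog":
            ft = dehoog(lambda S: field(phi_grid, S), t, M=M, tol=tol,
                        sigma0=max(0.0, sigma0))
        elif method == "stehfest":
            ft = stehfest(lambda S: field(phi_grid, S), t)
        else:
            raise ValueError(f"unknown inversion method: {method}")
        out = np.atleast_1d(np.asarray(ft, dtype=float))
        if not np.all(np.isfinite(out)):
            bad = phi_grid[~np.isfinite(out)]
            raise ArithmeticError(
                f"inversion failed to converge at t={t}, phi={bad[:3]}...")
        vals[:, j] = out
    return TemperatureField(phi_grid, t_grid, vals, provenance="laplace",
                            meta={"method": method, "M": M, "tol": tol})


def solve(p: ModelParams, phi_grid, t_grid, method: str = "dehoog",
          M: int = 40, tol: float = 1e-12) -> TemperatureField:
    """Temperature field of the model by closed form + numerical inversion."""
    return invert(lambda phi, S: laplace_temperature(phi, S, p),
                  phi_grid, t_grid, p=p, method=method, M=M, tol=tol)
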