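"""Laplace-domain closed form: nondimensionalization, boundary-condition
residuals, agreement with a dense finite-difference collocation oracle, and
the numerical inversion accuracy targets."""

import cmath
import math

import numpy as np
import pytest

from _helpers import fd_collocation
from prabheat import (DimensionalParams, ModelParams, laplace_temperature,
                      nondimensionalize, residual_check, solve)
from prabheat.laplace_solver import (characteristic_root, den_real_zeros,
                                     denominator, invert, laplace_gradient)
from prabheat.mlfunc import prabhakar_kernel


class TestNondimensionalize:
    def test_unit_scales(self):
        d = DimensionalParams(rho_t=1, C_t=1, k_t=1, rho_b=1, C_b=1, w_b=1,
                              Ta=1, upsilon=1, L=1, Qm_dim=1)
        p, scales = nondimensionalize(d)
        assert p.b0 == 1.0 and p.a0 == 1.0
        assert scales["t_scale"] == 1.0 and scales["eta_t"] == 1.0

    def test_hand_checked_set(self):
        d = DimensionalParams(rho_t=1, C_t=1, k_t=1, rho_b=1, C_b=1, w_b=0.5,
                              Ta=1, upsilon=0.25, L=2, Qm_dim=1)
        p, _ = nondimensionalize(d)
        assert p.a0 == pytest.approx(2.0)
        assert p.b0 == pytest.approx(2.0)

    def test_zero_perfusion_rejected(self):
        d = DimensionalParams(rho_t=1, C_t=1, k_t=1, rho_b=1, C_b=1, w_b=0.0,
                              Ta=1, upsilon=1, L=1)
        with pytest.raises(ValueError, match="a0"):
            nondimensionalize(d)

    def test_positivity_enforced(self):
        with pytest.raises(ValueError):
            DimensionalParams(rho_t=-1, C_t=1, k_t=1, rho_b=1, C_b=1, w_b=1,
                              Ta=1, upsilon=1, L=1)


class TestCharacteristicRoot:
    def test_classical_sqrt(self):
        p = ModelParams(alpha=1.0, beta=0.0, gamma=0.0, wp=0.0, a0=1e-12)
        assert characteristic_root(4.0, p) == pytest.approx(2.0, rel=1e-6)

    def test_classical_with_perfusion(self):
        p = ModelParams(alpha=1.0, beta=0.0, gamma=0.0, wp=0.0, a0=3.0)
        assert characteristic_root(1.0, p) == pytest.approx(2.0, rel=1e-14)

    def test_complex_oracle(self):
        p = ModelParams(alpha=0.9, beta=0.3, gamma=0.5, wp=0.2, a0=1.0)
        val = characteristic_root(complex(2.0, 1.0), p)
        assert val == pytest.approx(
            complex(1.607462553408868117948, 0.1297749386046942665864),
            rel=1e-14)

    def test_decaying_branch(self, rng):
        p = ModelParams()
        for _ in range(20):
            S = complex(rng.uniform(0.1, 20), rng.uniform(-20, 20))
            assert characteristic_root(S, p).real >= 0.0


class TestClosedForm:
    def test_no_shock_is_uniform(self, default_params):
        import dataclasses
        p = dataclasses.replace(default_params, Q0=0.0)
        S = complex(2.0, 0.7)
        vals = laplace_temperature(np.array([0.0, 0.3, 1.0]), S, p)
        expect = p.Qm / (S * (S + p.a0))
        assert np.allclose(vals, expect, rtol=1e-14)

    def test_zero_sources_zero_field(self):
        p = ModelParams(Q0=0.0, Qm=0.0)
        assert laplace_temperature(0.5, complex(3.0, 1.0), p) == 0.0

    @pytest.mark.parametrize("pset", [
        dict(),                                        # default fractional set
        dict(alpha=0.9, beta=0.2, gamma=0.3, wp=0.1, a0=2.0, b0=0.3),
        dict(alpha=1.0, beta=0.0, gamma=0.0, wp=0.0),  # classical
    ])
    def test_matches_fd_collocation(self, pset):
        p = ModelParams(**pset)
        S = complex(3.0, 0.0)
        closed = laplace_temperature(0.5, S, p)
        dense = fd_collocation(0.5, S, p, n=4096)
        assert abs(closed - dense) / abs(dense) < 1e-4

    def test_residuals_random_points(self, rng):
        """ODE + both Neumann residuals < 1e-10 at random (phi, S) samples
        for several parameter sets."""
        for _ in range(5):
            p = ModelParams(alpha=rng.uniform(0.5, 1.0),
                            beta=rng.uniform(0.1, 0.8),
                            gamma=rng.uniform(0.1, 0.9),
                            wp=rng.uniform(0.0, 0.5),
                            a0=rng.uniform(0.3, 3.0),
                            b0=rng.uniform(0.2, 1.0))
            for _ in range(20):
                phi = rng.uniform(0.0, 1.0)
                S = complex(rng.uniform(0.5, 20.0), rng.uniform(-10.0, 10.0))
                ode, bc0, bc1 = residual_check(phi, S, p)
                assert max(ode, bc0, bc1) < 1e-10

    def test_bracket_variant_violates_neumann(self, default_params):
        """The phi-dependent bracket variant is kept as a diagnostic: its
        boundary residuals are O(1), unlike the BC-solved production form."""
        ode, bc0, bc1 = residual_check(0.3, complex(2.0, 0.7), default_params,
                                       bracket_variant=True)
        assert bc0 > 1e-3 and bc1 > 1e-3

    def test_gradient_vanishes_at_ends(self, default_params):
        for S in (complex(1.5, 0.0), complex(4.0, 2.0)):
            g0 = laplace_gradient(0.0, S, default_params)
            g1 = laplace_gradient(1.0, S, default_params)
            assert abs(g0) < 1e-12 and abs(g1) < 1e-12


class TestInversion:
    def test_unit_step(self):
        fld = invert(lambda phi, S: np.full(len(phi), 1.0 / S),
                     [0.0, 0.5], [0.3, 1.0, 3.0])
        assert np.allclose(fld.values, 1.0, atol=1e-9)

    def test_exact_uniform_subsolution(self):
        """Qm/(S(S+a0)) inverts to (Qm/a0)(1 - e^{-a0 t}) within 1e-8."""
        Qm, a0 = 1.2, 0.5
        ts = np.linspace(0.01, 5.0, 40)
        fld = invert(lambda phi, S: np.full(len(phi), Qm / (S * (S + a0))),
                     [0.0], ts)
        exact = (Qm / a0) * (1.0 - np.exp(-a0 * ts))
        assert np.max(np.abs(fld.values[0] - exact)) < 1e-8

    def test_prabhakar_pair_identity(self):
        """Inverting S^{alpha gamma - beta}(S^alpha - wp)^{-gamma} returns
        the Prabhakar kernel (closing transform pair)."""
        a, b, g, wp = 0.8, 0.9, 0.7, 0.3
        fld = invert(lambda phi, S: np.full(
            len(phi), S ** (a * g - b) * (S ** a - wp) ** (-g)),
            [0.0], [0.5, 1.0, 2.0])
        for j, t in enumerate(fld.t_grid):
            assert fld.values[0, j] == pytest.approx(
                prabhakar_kernel(t, a, b, g, wp), rel=1e-9)

    def test_rejects_nonpositive_times(self, default_params):
        with pytest.raises(ValueError):
            solve(default_params, [0.5], [0.0, 1.0])


class TestFieldBehaviour:
    def test_long_time_steady_state(self):
        p = ModelParams(Q0=0.0, a0=1.0, Qm=1.2)
        fld = solve(p, np.linspace(0, 1, 5), [5.0])
        exact = (p.Qm / p.a0) * (1.0 - math.exp(-5.0))
        assert np.max(np.abs(fld.values - exact)) < 1e-6

    def test_initial_condition_metabolic(self):
        """Without the shock, T(phi, t -> 0+) ramps as Qm t, uniformly."""
        p = ModelParams(Q0=0.0)
        fld = solve(p, np.linspace(0.0, 1.0, 5), [1e-3])
        bound = 1.01e-3 * p.Qm / p.a0
        assert np.max(np.abs(fld.values)) < bound

    def test_initial_condition_full(self, default_params, classical_params):
        """T -> 0 as t -> 0+.  Ahead of the shock the classical branch is
        clean to the ringing level; the fractional kernel adds an algebraic
        (memory-flux) precursor that still vanishes with t."""
        fld = solve(classical_params, np.linspace(0.2, 1.0, 5), [1e-3])
        bound = 1e-3 * classical_params.Qm / classical_params.a0 + 1e-4
        assert np.max(np.abs(fld.values)) < bound
        fld = solve(default_params, np.linspace(0.2, 1.0, 5), [1e-3])
        assert np.max(np.abs(fld.values)) < 6e-3

    def test_den_zero_is_removable(self, default_params):
        """|Tb| stays bounded approaching the Den(S) = 0 point, confirming
        the contour does not need to move right of it."""
        z = den_real_zeros(default_params)[0]
        vals = [abs(laplace_temperature(0.3, z + eps, default_params))
                for eps in (1e-2, 1e-4, 1e-6)]
        assert abs(denominator(z, default_params)) < 1e-8
        assert max(vals) < 10.0 * min(vals)
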