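"""Mittag-Leffler series solution: exact sub-terms, reduction oracles,
certificate honesty (uncertainty budgets bound the true miss) and agreement
with the Laplace solver inside the certified window."""

import dataclasses
import math

import numpy as np
import pytest

from prabheat import ModelParams, solve
from prabheat.laplace_solver import den_real_zeros, denominator
from prabheat._inversion import dehoog
from prabheat.series_solution import (SeriesTruncation, _edge_sum_pointwise,
                                      _inv_power_kernel, assemble, term_D,
                                      term_E, term_N, term_Omega, term_R)

CERT_PARAMS = ModelParams(a0=4.0, b0=0.25)   # inside the convergent window at t ~ 3


class TestTermD:
    def test_exact_values(self):
        p = ModelParams(Qm=1.2, a0=0.5)
        assert term_D(0.0, p) == 0.0
        assert term_D(1.0, p) == pytest.approx(2.4 * (1 - math.exp(-0.5)),
                                               rel=1e-15)

    def test_monotone_to_steady_state(self):
        p = ModelParams(Qm=1.2, a0=1.0)
        ts = np.linspace(0.0, 40.0, 200)
        vals = [term_D(t, p) for t in ts]
        assert np.all(np.diff(vals) >= 0)
        assert vals[-1] == pytest.approx(1.2, rel=1e-12)

    def test_matches_inversion_of_uniform_transform(self):
        p = ModelParams(Qm=1.2, a0=1.0)
        for t in (0.2, 1.0, 3.0):
            ref = dehoog(lambda S: p.Qm / (S * (S + p.a0)), t)
            assert term_D(t, p) == pytest.approx(ref, abs=1e-8)


class TestCanonicalPair:
    @pytest.mark.parametrize("t", [0.5, 1.0, 2.0])
    def test_against_bromwich_inversion(self, t):
        """The closed-form pointwise inverse of S^p (1-wp S^-a)^g (S+a0)^-b
        matches direct numerical inversion for a decaying transform."""
        val = _inv_power_kernel(t, 1.2, 0.3, 1.5, 0.8, 0.2, 1.0)
        ref = dehoog(lambda S: S ** 1.2 * (1 - 0.2 * S ** -0.8) ** 0.3
                     / (S + 1.0) ** 1.5, t)
        assert val == pytest.approx(ref, rel=1e-8)

    def test_plain_exponential(self):
        # p=0, g=0, b=1 is 1/(S+a0) -> e^{-a0 t}
        for t in (0.3, 1.7):
            assert _inv_power_kernel(t, 0.0, 0.0, 1.0, 0.8, 0.0, 2.0) == \
                pytest.approx(math.exp(-2.0 * t), rel=1e-12)


class TestReflectionSeries:
    @pytest.mark.parametrize("c", [0.5, 1.0, 2.0])
    @pytest.mark.parametrize("t", [0.5, 1.0])
    def test_diffusion_kernel_reduction(self, c, t):
        """With no memory and no perfusion each reflection series resums the
        classical point-source kernel c/(2 sqrt(pi) t^{3/2}) e^{-c^2/4t}."""
        v, rep = _edge_sum_pointwise(t, np.array([c]), 0.8, 0.0, 0.0, 0.0,
                                     0.0, SeriesTruncation(N=60, tol=1e-6))
        exact = c / (2 * math.sqrt(math.pi) * t ** 1.5) * math.exp(-c * c / (4 * t))
        assert v == pytest.approx(exact, rel=1e-10)
        assert rep.converged

    def test_shifted_parts_causal(self, default_params):
        """The u(t - b0)-shifted reflection parts contribute nothing before
        the boundary echo time."""
        t = 0.8 * default_params.b0
        n_val, _ = term_N(t, 0.4, default_params)
        dists = np.array([2 * k + 0.4 for k in range(6)])
        unshifted, _ = _edge_sum_pointwise(
            t, dists, default_params.alpha, default_params.beta,
            default_params.gamma, default_params.wp, default_params.a0,
            SeriesTruncation())
        assert n_val == pytest.approx(-unshifted, rel=1e-12)

    def test_mirror_symmetry_of_image_charges(self, default_params):
        """The image-charge distances mirror under phi -> 1 - phi (N families
        map onto R families); the temperature itself is not mirror-symmetric
        because the shock travels from phi = 0."""
        from prabheat.series_solution import _reflection_distances
        dn = _reflection_distances(0.3, 5)
        dr = _reflection_distances(0.7, 5)
        assert np.allclose(dn["N1"], dr["R2"]) and np.allclose(dn["N2"], dr["R1"])
        # and the four families tile the image line with spacing 2
        all_d = np.sort(np.concatenate(list(dn.values())))
        assert np.allclose(np.diff(all_d)[::2], np.diff(all_d)[::2][0])


class TestTermEOmega:
    def test_no_shock_vanishes(self, default_params):
        p = dataclasses.replace(default_params, Q0=0.0)
        assert term_E(1.0, p)[0] == 0.0
        assert term_Omega(1.0, 0.5, p)[0] == 0.0

    def test_omega_zero_before_arrival(self, default_params):
        v, rep = term_Omega(0.9 * default_params.b0 * 0.8, 0.8, default_params)
        assert v == 0.0 and rep.converged

    def test_omega_leading_shell_is_exponential(self):
        """The k = 0 shell transform is 1/(S+a0): Omega reduces to
        Q0 e^{-a0 (t - b0 phi)} when only that shell is kept."""
        p = ModelParams(Q0=1.0, a0=1.0, b0=0.5)
        tau = 1.0
        v, _ = term_Omega(tau + p.b0 * 0.5, 0.5, p, SeriesTruncation(M=1))
        assert v == pytest.approx(math.exp(-1.0), rel=1e-10)

    def test_omega_tracks_pole_corrected_inversion(self, default_params):
        """Against inversion of Q0 e^{-b0 phi S}/Den with the (removable in
        the full solution, genuine here) real pole subtracted analytically;
        agreement within the reported uncertainty budget."""
        p = default_params
        S_star = den_real_zeros(p)[0]
        h = 1e-6
        dden = (denominator(S_star + h, p) - denominator(S_star - h, p)).real / (2 * h)
        phi = 0.5
        res = p.Q0 * math.exp(-p.b0 * phi * S_star) / dden
        for t in (1.0, 2.0):
            ref = dehoog(lambda S: p.Q0 * np.exp(-p.b0 * phi * S)
                         / denominator(S, p) - res / (S - S_star), t, M=60)
            v, rep = term_Omega(t, phi, p, SeriesTruncation(M=10, tol=1e-2))
            assert abs(v - ref) <= 2.0 * rep.budget + 1e-3


class TestAssembly:
    def test_no_shock_reduces_to_metabolic(self, default_params):
        p = dataclasses.replace(default_params, Q0=0.0)
        for t in (0.5, 2.0):
            r = assemble(0.3, t, p)
            assert r.value == pytest.approx(term_D(t, p), rel=1e-14)
            assert r.certified

    def test_budgets_bound_the_miss(self, default_params):
        """The assembled value may be far from the truth outside the
        convergence region, but never silently: the summed uncertainty
        budgets bound the discrepancy against the Laplace solver."""
        pts = [(0.25, 0.5), (0.5, 1.0), (0.75, 2.0)]
        lap = solve(default_params, [p[0] for p in pts], [0.5, 1.0, 2.0])
        for i, (ph, t) in enumerate(pts):
            r = assemble(ph, t, default_params)
            ref = lap.values[i, i]
            budget = sum(rep.budget for rep in r.reports.values())
            assert abs(r.value - ref) <= 1.5 * budget + 1e-6

    def test_certified_window_agrees_with_laplace(self):
        """Where the certificates pass, the series matches the inversion
        to better than 1e-2 relative."""
        trunc = SeriesTruncation(tol=1e-2)
        lap = solve(CERT_PARAMS, [0.25, 0.75], [3.0])
        n_cert = 0
        for i, ph in enumerate((0.25, 0.75)):
            r = assemble(ph, 3.0, CERT_PARAMS, trunc)
            if r.certified:
                n_cert += 1
                assert abs(r.value - lap.values[i, 0]) <= 1e-2 * abs(lap.values[i, 0])
        assert n_cert >= 1

    def test_doubling_caps_is_stable_when_certified(self):
        """Doubling (K, N, M) moves a certified value by less than tol."""
        base = SeriesTruncation(K=4, N=30, M=6, tol=1e-2)
        double = SeriesTruncation(K=8, N=60, M=12, tol=1e-2)
        r1 = assemble(0.5, 3.0, CERT_PARAMS, base)
        r2 = assemble(0.5, 3.0, CERT_PARAMS, double)
        assert r1.certified
        assert abs(r1.value - r2.value) <= base.tol * abs(r1.value)

    def test_flagged_terms_propagate(self, default_params):
        """A non-convergent region never yields a silently certified value."""
        r = assemble(0.5, 0.6, default_params, SeriesTruncation(tol=1e-3))
        assert not r.certified
        assert any(rep.flags for rep in r.reports.values())


def test_truncation_validation():
    with pytest.raises(ValueError):
        SeriesTruncation(K=0)
    with pytest.raises(ValueError):
        SeriesTruncation(tol=0.0)
    with pytest.raises(ValueError):
        SeriesTruncation(conv_grid=np.array([0.5, 1.0]))
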