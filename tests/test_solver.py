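"""Conservative-form thin-film solver: fluxes, velocity, stepping, audits."""

import math

import numpy as np
import pytest

import gelfilm as g
from gelfilm.equilibria import PerturbationSpec
from gelfilm.potentials import GelParameters
from gelfilm.solver import (
    BreakdownError,
    FilmState,
    _d1,
    flux_V1,
    masses,
    source_V2,
)

P075 = GelParameters(chi=0.75)


def uniform_state(theta=0.6, n=0.0, h=1.0, M=41):
    X = g.make_grid(M)
    return FilmState(X=X, Q=np.full(M, theta * h), W=np.full(M, (1 - theta) * h),
                     n=np.full(M, n), L=1.0, T=0.0)


def cosine_state(M=41, theta0=0.55, a_th=0.03, n0=1.0, a_n=0.02, h0=1.0,
                 a_h=0.04):
    """Smooth manufactured film satisfying the end conditions."""
    X = g.make_grid(M)
    cos = np.cos(math.pi * X)
    theta = theta0 + a_th * cos
    h = h0 + a_h * cos
    return FilmState(X=X, Q=theta * h, W=(1 - theta) * h, n=n0 + a_n * cos,
                     L=1.1, T=0.0)


class TestFluxAndSource:
    def test_V2_is_equilibrium_residual_over_R(self):
        """The conservative-variable source V2(Q, W, n) equals
        (1/R) * (mu_s - mu_s^e + theta_p G) pointwise (cross-module
        identity; mu_s0 = 0)."""
        s = cosine_state()
        for R in (1.0, 4.0):
            p = P075.with_(R=R)
            V2 = source_V2(s.Q, s.W, s.n, p)
            expected = g.equilibrium_residual(s.theta_p, s.n, p) / R
            np.testing.assert_allclose(V2, expected, rtol=1e-13)

    def test_V1_vanishes_on_uniform_film(self):
        s = uniform_state(n=1.0)
        np.testing.assert_array_equal(
            flux_V1(s.Q, s.W, s.n, s.dX, P075), 0.0)

    def test_V1_traction_free_is_pure_osmotic(self):
        s = cosine_state()
        p0 = P075.with_(tau0=0.0)
        V1 = flux_V1(s.Q, s.W, s.n, s.dX, p0)
        h = s.Q + s.W
        coeff = (2 * p0.chi * s.W - h - (s.W / p0.N) * (1 + s.W / s.Q)) / p0.xi
        dtheta = _d1(s.theta_p, s.dX)
        dtheta[0] = dtheta[-1] = 0.0  # no-flux end values
        np.testing.assert_allclose(V1, coeff * dtheta, rtol=1e-13)

    def test_V1_matches_linearised_seed_velocity(self):
        """For a small cosine perturbation of a uniform equilibrium, the
        solved velocity equals eps * v01 from the short-time analysis up
        to O(eps^2)."""
        p = P075.with_(tau0=0.0, D=0.0)
        theta_star = g.find_equilibria(0.6, 0.0, p)[-1].theta_star
        errs = []
        for eps in (0.01, 0.005):
            spec = PerturbationSpec(Z=1, eps=eps, delta=eps / 10)
            X = g.make_grid(161)
            cos = np.cos(math.pi * X)
            theta = theta_star + eps * cos
            h = 1.0 - eps * cos
            s = FilmState(X=X, Q=theta * h, W=(1 - theta) * h,
                          n=np.zeros_like(X), L=1.0, T=0.0)
            v, _ = g.solve_velocity(s, p)
            v_lin = g.small_time_solution(X, 0.0, spec, theta_star, p)["v_p"]
            errs.append(np.max(np.abs(v - v_lin)))
        # halving eps reduces the defect ~4x (it is O(eps^2) + tiny O(dX^2))
        assert errs[1] < errs[0] / 3.0
        assert errs[0] < 5.0 * 0.01**2


class TestSolveVelocity:
    def test_uniform_velocity_is_linear_with_reduced_model_slope(self):
        """For a uniform film v_p = (x/h) dh/dt: linear in X with slope
        -V2 L / (2h)."""
        s = uniform_state(theta=0.6, n=1.0)
        v, Ldot = g.solve_velocity(s, P075)
        V2 = source_V2(s.Q, s.W, s.n, P075)[0]
        slope = -V2 * s.L / (2.0 * s.h[0])
        np.testing.assert_allclose(v, slope * s.X, rtol=1e-12, atol=1e-15)
        assert Ldot == pytest.approx(slope)

    def test_equilibrium_film_is_motionless(self):
        theta_star = g.find_equilibria(0.6, 0.0, P075)[-1].theta_star
        s = uniform_state(theta=theta_star, h=1.3)
        v, Ldot = g.solve_velocity(s, P075)
        assert np.max(np.abs(v)) < 1e-13
        assert abs(Ldot) < 1e-13

    def test_grid_convergence_is_second_order(self):
        """Richardson refinement 41 -> 81 -> 161 against a fine reference
        shows observed order >= 2 in the max norm."""
        ref = cosine_state(M=1281)
        v_ref, _ = g.solve_velocity(ref, P075)
        errs = []
        for M in (41, 81, 161):
            s = cosine_state(M=M)
            v, _ = g.solve_velocity(s, P075)
            stride = (1281 - 1) // (M - 1)
            errs.append(np.max(np.abs(v - v_ref[::stride])))
        orders = np.log2(np.array(errs[:-1]) / np.array(errs[1:]))
        assert np.all(orders >= 1.8)


class TestStep:
    def test_uniform_film_stays_uniform_and_tracks_reduced_model(self):
        params, _ = g.preset("fig3a")
        s = uniform_state(theta=0.6, n=1.0)
        res = g.advance(s, params, T_end=0.05, dT=1e-4)
        f = res.final
        assert g.amplitude(f.theta_p) < 1e-14
        assert g.amplitude(f.h) < 1e-14
        traj = g.integrate_uniform(0.6, 1.0, params)
        assert abs(f.h[0] - float(traj.h_at(f.T))) < 2e-7  # O(dT^2)
        np.testing.assert_allclose(f.L, f.h[0], rtol=1e-12)

    def test_equilibrium_state_is_fixed_point(self):
        theta_star = g.find_equilibria(0.6, 0.0, P075)[-1].theta_star
        s = uniform_state(theta=theta_star)
        new = g.step(s, 1e-3, P075.with_(D=0.0))
        np.testing.assert_allclose(new.Q, s.Q, rtol=1e-12)
        np.testing.assert_allclose(new.L, s.L, rtol=1e-12)

    def test_single_step_conserves_polymer_mass(self):
        params, init = g.preset("fig5")
        s = g.make_initial_state(init, g.make_grid(41))
        mp0, mc0 = masses(s)
        new = g.step(s, 1e-5, params)
        mp1, mc1 = masses(new)
        assert abs(mp1 - mp0) / mp0 <= 1e-10
        assert abs(mc1 - mc0) / mc0 <= 1e-10

    def test_rejects_nonpositive_dt(self):
        with pytest.raises(ValueError):
            g.step(uniform_state(), 0.0, P075)

    def test_breakdown_halts_with_state_dump(self):
        """Fast contraction without diffusion drives theta_p toward 1; the
        run halts loudly with the offending state attached (never clips)."""
        params, init = g.preset("fig7_high_drag")
        s = g.make_initial_state(init, g.make_grid(41))
        with pytest.raises(BreakdownError) as exc_info:
            g.advance(s, params.with_(D=0.0), T_end=1.0, dT=1e-4,
                      allow_zero_diffusion=True)
        assert exc_info.value.state is not None
        assert exc_info.value.state.T < 1.0

    def test_zero_diffusion_needs_acknowledgment(self):
        params, init = g.preset("fig9_zeroD")
        s = g.make_initial_state(init, g.make_grid(41))
        with pytest.raises(ValueError, match="allow_zero_diffusion"):
            g.advance(s, params, T_end=0.01, dT=1e-4)


class TestSmallTimeOracle:
    """The PDE solution tracks the closed-form short-time profiles around
    a perturbed uniform equilibrium."""

    def _run(self, params, theta_star, spec, n_on, products):
        X = g.make_grid(41)
        cos = np.cos(math.pi * X)
        theta = theta_star + spec.eps * cos
        h = 1.0 - spec.eps * spec.H01 * cos
        n = (1.0 + spec.eps * spec.N01 * cos) if n_on else np.zeros_like(X)
        s = FilmState(X=X, Q=theta * h, W=(1 - theta) * h, n=n, L=1.0, T=0.0)
        res = g.advance(s, params, T_end=products[-1], dT=1e-5,
                        snapshot_times=list(products),
                        allow_zero_diffusion=True)
        errs = []
        for T in products:
            snap = min(res.snapshots, key=lambda q: abs(q.T - T))
            ana = g.small_time_solution(X, T / spec.delta, spec, theta_star,
                                        params)
            e = np.max(np.abs(snap.theta_p - ana["theta_p"]))
            e = max(e, np.max(np.abs(snap.h - ana["h"])))
            if n_on:
                e = max(e, np.max(np.abs(snap.n - ana["n"])))
            errs.append(e)
        return np.asarray(errs)

    @staticmethod
    def _observed_order(products, errs):
        # remove the O(eps^2 * T) linear component using the smallest time
        corrected = errs[1:] - errs[0] * (np.asarray(products[1:]) / products[0])
        corrected = np.abs(corrected)
        slopes = np.diff(np.log(corrected)) / np.diff(np.log(products[1:]))
        return slopes

    def test_cell_free_profiles_and_order(self):
        p = P075.with_(tau0=0.0, D=0.0)
        theta_star = g.find_equilibria(0.6, 0.0, p)[-1].theta_star
        spec = PerturbationSpec(Z=1, eps=0.01, delta=5e-3, H01=1.0)
        products = (0.005, 0.01, 0.02, 0.04)
        errs = self._run(p, theta_star, spec, n_on=False, products=products)
        assert errs[-1] < 5e-4  # bounded by C (delta^2 + eps^2)
        assert np.all(self._observed_order(products, errs) >= 1.8)

    def test_cell_seeded_profiles_with_diffusion(self):
        """Equilibrium manufactured to sit at n* = 1 (tau0 chosen so the
        residual vanishes at theta* = 0.5); the cell mode feels diffusion
        with the damping sign."""
        theta_star = 0.5
        tau0 = -2.0 * g.mu_s(theta_star, P075) / theta_star
        p = P075.with_(tau0=tau0, D=1.0)
        assert abs(g.equilibrium_residual(theta_star, 1.0, p)) < 1e-14
        spec = PerturbationSpec(Z=1, eps=0.01, delta=2.5e-3, N01=1.0, H01=1.0)
        # shorter window: the diffusive cell mode decays fast (rate ~12),
        # and the closed form is linear in time
        products = (0.0025, 0.005, 0.01, 0.02)
        errs = self._run(p, theta_star, spec, n_on=True, products=products)
        assert errs[-1] < 1e-3
        assert np.all(self._observed_order(products, errs) >= 1.8)


class TestSteadyStates:
    def test_drag_slows_spatial_smoothing(self, fig7_amplitudes):
        """At T = 0.8 the polymer-fraction amplitude under high drag
        (xi = 4) exceeds the low-drag (xi = 0.2) amplitude: internal
        friction preserves the initial spatial structure."""
        assert fig7_amplitudes["high"] > fig7_amplitudes["low"]
        assert fig7_amplitudes["low"] < 1e-3

    def test_equilibrium_conditions_at_convergence(self, fig5_fine_result):
        """At a converged D > 0 steady state theta_p and n are flat and
        the trans-boundary residual has vanished; h may stay non-uniform."""
        f = fig5_fine_result.final
        assert fig5_fine_result.converged
        assert np.max(np.abs(_d1(f.theta_p, f.dX))) <= 1e-6
        assert np.max(np.abs(_d1(f.n, f.dX))) <= 1e-6
        resid = g.equilibrium_residual(float(np.mean(f.theta_p)),
                                       float(np.mean(f.n)), P075)
        assert abs(resid) <= 1e-8
        assert g.amplitude(f.h) > 1e-3  # the height stays non-uniform

    def test_length_equals_mean_height_at_equilibrium(self, fig4_result):
        f = fig4_result.final
        assert round(f.L, 2) == round(float(np.mean(f.h)), 2)


def test_amplitude_of_reference_profiles():
    X = g.make_grid(41)
    assert g.amplitude(np.full(41, 3.7)) == 0.0
    assert g.amplitude(1.5 + 0.25 * np.cos(math.pi * X)) == pytest.approx(0.25)
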