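import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nanocap import (
    CapGeometry,
    EnvelopeParams,
    effective_adhesion,
    free_energy,
    maximal_cover_state,
    minimize_free_energy,
    solve_lambda,
    tensions,
)
from nanocap.mechanics import CollapseError

from conftest import brute_force_lambda


class TestEffectiveAdhesion:
    def test_limits(self):
        env = EnvelopeParams(k=100.0, eps=0.5, kappa=0.0)
        assert effective_adhesion(env, 40.0).eps_prime == 0.5
        env_b = EnvelopeParams(k=100.0, eps=0.5, kappa=1e-19)
        assert effective_adhesion(env_b, 1e9).eps_prime == pytest.approx(0.5)

    def test_marginal_adhesion(self):
        # eps exactly equal to the bending cost 2*kappa/R^2
        R = 40.0
        kappa = 1e-19
        eps = (2 * kappa / (R * 1e-9) ** 2) * 1e3
        result = effective_adhesion(EnvelopeParams(k=100.0, eps=eps, kappa=kappa), R)
        assert result.eps_prime == pytest.approx(0.0, abs=1e-12)
        assert not result.adhesive

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        eps=st.floats(0.0, 5.0),
        kappa=st.floats(0.0, 1e-18),
        R=st.floats(5.0, 500.0),
    )
    def test_bending_only_reduces_adhesion(self, eps, kappa, R):
        env = EnvelopeParams(k=100.0, eps=eps, kappa=kappa)
        assert effective_adhesion(env, R).eps_prime <= eps


class TestSolveLambda:
    def test_flat_reference_state(self, cs_geometry):
        assert solve_lambda(cs_geometry, 0.1, theta=0.0) == pytest.approx(0.0)

    def test_closed_form_quarter_area(self, cs_geometry):
        # only the suspended term survives at theta=0: (lam+1)^2 = d^2/S0
        lam = solve_lambda(cs_geometry, 0.1, theta=0.0, S0=cs_geometry.d**2 / 4)
        assert lam == pytest.approx(1.0)

    def test_against_bisection_oracle(self):
        geom = CapGeometry(R=1.2 * 45.0, rho=45.0, d=90.0)
        theta = 0.5
        lam = solve_lambda(geom, 0.1, theta=theta)
        r = geom.R / geom.d
        a_cap = 2 * math.pi * r**2 * (1 - math.cos(theta))
        a_sus = 1 - math.pi * r**2 * math.sin(theta) ** 2
        oracle = brute_force_lambda(a_cap, a_sus, 0.1)
        assert lam == pytest.approx(float(oracle), abs=1e-10)
        residual = a_cap / (lam + 0.9) ** 2 + a_sus / (lam + 1) ** 2 - 1.0
        assert abs(residual) < 1e-12

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        e=st.floats(1e-5, 1.0),
        r_scale=st.floats(1.0, 10.0),
        rho_frac=st.floats(0.1, 0.5),
        theta_frac=st.floats(0.0, 1.0),
    )
    def test_constraint_residual_property(self, e, r_scale, rho_frac, theta_frac):
        rho = rho_frac * 90.0
        geom = CapGeometry(R=r_scale * rho, rho=rho, d=90.0)
        theta = theta_frac * geom.theta_max
        lam = solve_lambda(geom, e, theta)
        r = geom.R / geom.d
        a_cap = 2 * math.pi * r**2 * (1 - math.cos(theta))
        a_sus = 1 - math.pi * r**2 * math.sin(theta) ** 2
        cap = a_cap / (lam + 1 - e) ** 2 if a_cap > 0 else 0.0
        assert abs(cap + a_sus / (lam + 1) ** 2 - 1.0) <= 1e-9
        # collapse bound: both denominators stay positive
        assert lam + 1 > 0 and lam + 1 - e > 0


class TestFreeEnergy:
    def test_reference_state_is_zero(self, cs_geometry):
        assert free_energy(cs_geometry, 0.1, theta=0.0, lam=0.0) == pytest.approx(0.0)

    def test_deformation_without_adhesion_costs_energy(self, cs_geometry):
        for theta in np.linspace(0.05, cs_geometry.theta_max, 10):
            lam = solve_lambda(cs_geometry, 0.0, theta)
            assert free_energy(cs_geometry, 0.0, theta, lam) > 0

    def test_symbolic_spot_check(self):
        # theta=pi/2, R=rho=d/2, e=1, lam=1:
        # F/(k d^2) = (pi/2)*(-1)/1 + (1 - pi/4)/4, evaluated independently
        geom = CapGeometry(R=1.0, rho=1.0, d=2.0)
        expected = (math.pi / 2) * (-1.0) + (1 - math.pi / 4) / 4
        assert free_energy(geom, 1.0, math.pi / 2, 1.0) == pytest.approx(expected)

    def test_collapse_bound_violation_raises(self, cs_geometry):
        with pytest.raises(CollapseError):
            free_energy(cs_geometry, 0.5, theta=0.3, lam=-1.2)


class TestTensions:
    @pytest.mark.parametrize(
        "lam, k, eps_prime, expected",
        [
            (0.0, 100.0, 0.0, (0.0, 0.0)),
            (1.1, 1.0, 1.0, (1.1, 0.1)),  # optimal-design row at eps'/k = 1
        ],
    )
    def test_values(self, lam, k, eps_prime, expected):
        assert tensions(lam, k, eps_prime) == pytest.approx(expected)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        lam=st.floats(-0.5, 3.0),
        k=st.floats(1.0, 3000.0),
        eps_prime=st.floats(0.0, 10.0),
    )
    def test_difference_is_effective_adhesion(self, lam, k, eps_prime):
        tau_b, tau_a = tensions(lam, k, eps_prime)
        assert tau_b - tau_a == pytest.approx(eps_prime, rel=1e-12, abs=1e-12)


class TestMinimizeFreeEnergy:
    def test_non_adhesive_returns_trivial_state(self, cs_geometry):
        env = EnvelopeParams(k=300.0, eps=0.01, kappa=1e-19)  # eps' < 0
        state = minimize_free_energy(cs_geometry, env)
        assert state.theta == 0.0
        assert state.lam == pytest.approx(0.0)
        assert state.tau_suspended == pytest.approx(0.0)
        assert state.free_energy == pytest.approx(0.0)

    def test_theta_and_tension_nondecreasing_in_adhesion(self, cs_geometry):
        thetas, taus = [], []
        for eps in np.geomspace(0.01, 10.0, 8):
            state = minimize_free_energy(
                cs_geometry, EnvelopeParams(k=300.0, eps=eps, kappa=0.0)
            )
            thetas.append(state.theta)
            taus.append(state.tau_suspended)
        assert all(b >= a - 1e-9 for a, b in zip(thetas, thetas[1:]))
        assert all(b >= a - 1e-9 for a, b in zip(taus, taus[1:]))

    def test_solved_state_is_self_consistent(self, cs_geometry, soft_envelope):
        state = minimize_free_energy(cs_geometry, soft_envelope)
        assert state.constraint_residual <= 1e-9
        eps_prime = effective_adhesion(soft_envelope, cs_geometry.R).eps_prime
        assert state.tau_suspended == pytest.approx(soft_envelope.k * state.lam)
        assert state.tau_suspended - state.tau_adhering == pytest.approx(eps_prime)
        assert state.area_adhered == pytest.approx(
            2 * math.pi * cs_geometry.R**2 * (1 - math.cos(state.theta))
        )

    def test_flat_limit_adhesion_release_plateau(self):
        # rho/R -> 0 at fixed rho: the geometric stretch vanishes but
        # adhesion still compresses the contact disc and releases area,
        # so tau_B decays to the plateau eps' * pi*(rho/d)^2 rather than 0
        env = EnvelopeParams(k=300.0, eps=0.5)
        taus = [
            minimize_free_energy(CapGeometry(R=R, rho=17.5, d=90.0), env).tau_suspended
            for R in (500.0, 5e3, 5e4)
        ]
        assert taus[0] > taus[1] > taus[2] > 0
        plateau = 0.5 * math.pi * (17.5 / 90.0) ** 2
        assert taus[2] == pytest.approx(plateau, rel=0.02)


class TestMaximalCoverState:
    def test_theta_is_exactly_theta_max(self, cs_geometry, soft_envelope):
        state = maximal_cover_state(cs_geometry, soft_envelope)
        assert state.theta == cs_geometry.theta_max

    def test_dominates_free_energy_minimum(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            rho = rng.uniform(10.0, 44.0)
            geom = CapGeometry(R=rho * rng.uniform(1.0, 6.0), rho=rho, d=90.0)
            env = EnvelopeParams(k=300.0, eps=10 ** rng.uniform(-2, 1), kappa=0.0)
            tau_min = minimize_free_energy(geom, env).tau_suspended
            tau_cover = maximal_cover_state(geom, env).tau_suspended
            assert tau_cover >= tau_min - 1e-9

    def test_pure_geometric_stretch_without_adhesion_gain(self, hemispheres):
        # eps' = 0 at full cover still stretches the envelope: F > 0
        from nanocap.mechanics import _free_energy, _solve_lambda

        r = hemispheres.R / hemispheres.d
        lam = _solve_lambda(r, 0.0, hemispheres.theta_max, 1.0)
        assert lam > 0
        assert _free_energy(r, 0.0, hemispheres.theta_max, lam) > 0
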