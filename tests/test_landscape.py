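import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import dblquad

from catchbond import (
    DegenerateGeometryError,
    InvalidParametersError,
    LandscapeState,
    ModelParameters,
    PhysicalEnvironment,
    alpha_from_theta,
    angular_potential,
    energies_from_stiffness,
    equilibrium_small_angle_probability,
    potential_energy,
    spring_constant,
    stiffness_from_energies,
    theta_from_alpha,
)
from catchbond.landscape import radial_bounds, reduced_potential


@pytest.mark.parametrize(
    "alpha,phi,expected",
    [(48.0, 0.0, 132.0), (169.0, 0.0, 11.0), (90.0, 5.0, 85.0)],
)
def test_angle_conversion_examples(alpha, phi, expected):
    assert theta_from_alpha(alpha, phi) == pytest.approx(expected)


@settings(deadline=None, derandomize=True)
@given(
    alpha=st.floats(1.0, 179.0),
    phi=st.floats(-20.0, 20.0),
)
def test_angle_conversion_roundtrip(alpha, phi):
    assert alpha_from_theta(theta_from_alpha(alpha, phi), phi) == pytest.approx(
        alpha, abs=1e-10
    )


def test_angle_conversion_rejects_out_of_range():
    with pytest.raises(InvalidParametersError):
        theta_from_alpha(181.0, 0.0)
    with pytest.raises(InvalidParametersError):
        theta_from_alpha(0.0, 0.0)


class TestStiffnessConversion:
    def test_wild_type_values(self, table1):
        params, _ = table1
        k0, k1 = stiffness_from_energies(21.8, 5.8, 0.56, 11.0, 132.0)
        assert k0 == pytest.approx(131.6, abs=0.1)
        assert k1 == pytest.approx(22.4, abs=0.1)
        # algebraic oracle: conversion must invert exactly
        E0, E1 = energies_from_stiffness(k0, k1, 0.56, 11.0, 132.0)
        assert E0 == pytest.approx(21.8, rel=1e-10)
        assert E1 == pytest.approx(5.8, rel=1e-10)
        assert (params.k0, params.k1) == pytest.approx((k0, k1))

    def test_zero_e1_forces_zero_k1(self):
        k0, k1 = stiffness_from_energies(10.0, 0.0, 0.5, 20.0, 150.0)
        assert k1 == 0.0
        assert k0 == pytest.approx(2 * 10.0 / 0.25)

    def test_zero_energies(self):
        assert stiffness_from_energies(0.0, 0.0, 0.5, 20.0, 150.0) == (0.0, 0.0)

    def test_negative_k0_rejected(self):
        with pytest.raises(InvalidParametersError):
            stiffness_from_energies(1.0, 50.0, 0.5, 20.0, 150.0)

    def test_degenerate_geometry_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            stiffness_from_energies(10.0, 5.0, 0.5, 90.0, 90.0)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(
        E0=st.floats(1.0, 40.0),
        E1=st.floats(0.0, 10.0),
        d=st.floats(0.1, 2.0),
    )
    def test_roundtrip_property(self, E0, E1, d):
        k0, k1 = stiffness_from_energies(E0, E1, d, 11.0, 132.0)
        back = energies_from_stiffness(k0, k1, d, 11.0, 132.0)
        assert back == pytest.approx((E0, E1), rel=1e-10, abs=1e-12)


class TestHamiltonian:
    def test_spring_constant_values(self, table1):
        params, _ = table1
        assert spring_constant(90.0, params) == pytest.approx(params.k0 + params.k1)
        # energy identities k(theta_max) d^2/2 = E0, k(theta_min) d^2/2 = E0+E1
        assert spring_constant(params.theta_max, params) == pytest.approx(
            2 * params.E0 / params.d**2, rel=1e-10
        )
        assert spring_constant(params.theta_min, params) == pytest.approx(
            2 * (params.E0 + params.E1) / params.d**2, rel=1e-10
        )

    def test_angular_potential_anchors(self, table1):
        params, _ = table1
        assert angular_potential(params.theta_max, params) == pytest.approx(0.0, abs=1e-12)
        assert angular_potential(params.theta_min, params) == pytest.approx(params.G)
        eps = 1e-7
        below = angular_potential(params.theta_c - eps, params)
        above = angular_potential(params.theta_c + eps, params)
        assert below == pytest.approx(params.H, abs=1e-4)
        assert above == pytest.approx(params.H, abs=1e-4)

    def test_cusp_continuity_over_r(self, table1):
        params, env = table1
        tc = math.radians(params.theta_c)
        for r in np.linspace(1.3, params.r0 + params.d, 7):
            lo = reduced_potential(r, tc - 1e-12, 4.0, params, env)
            hi = reduced_potential(r, tc + 1e-12, 4.0, params, env)
            assert abs(lo - hi) < 1e-9

    @pytest.mark.parametrize(
        "r_off,theta_attr,expected_attr",
        [
            (0.0, "theta_max", lambda p: 0.0),
            ("d", "theta_max", lambda p: p.E0),
            ("d", "theta_min", lambda p: p.E0 + p.E1 + p.G),
        ],
    )
    def test_potential_energy_anchors(self, table1, r_off, theta_attr, expected_attr):
        params, env = table1
        r = params.r0 + (params.d if r_off == "d" else 0.0)
        state = LandscapeState(r=r, theta=getattr(params, theta_attr), force=0.0)
        assert potential_energy(state, params, env) == pytest.approx(
            expected_attr(params), abs=1e-10
        )

    def test_force_tilt_is_minus_r_cos_theta(self, table1):
        params, env = table1
        kT = env.thermal_energy
        for theta in (30.0, 90.0, 130.0):
            state_lo = LandscapeState(r=1.8, theta=theta, force=5.0)
            state_hi = LandscapeState(r=1.8, theta=theta, force=5.001)
            dU_dF = (
                potential_energy(state_hi, params, env)
                - potential_energy(state_lo, params, env)
            ) / 0.001
            assert dU_dF == pytest.approx(
                -1.8 * math.cos(math.radians(theta)) / kT, rel=1e-4
            )


class TestEnvironment:
    def test_thermal_energy_and_diffusivity(self, table1):
        params, env = table1
        # room-temperature thermal energy, 4 significant figures
        assert env.thermal_energy == pytest.approx(4.114, abs=5e-4)
        assert env.thermal_energy == pytest.approx(0.01380649 * env.temperature_K)
        eta = env.viscosity_Pa_s * 1e-6
        assert env.diffusivity(params.r0) == pytest.approx(
            env.thermal_energy / (6 * math.pi * eta * params.r0)
        )

    def test_invalid_measure_rejected(self):
        with pytest.raises(InvalidParametersError):
            PhysicalEnvironment(measure="cylindrical")


class TestEquilibriumProbability:
    def test_against_direct_2d_quadrature(self, table1):
        """Independent oracle: adaptive 2-d quadrature of the Boltzmann weight."""
        params, env = table1
        r_lo, r_hi = radial_bounds(params)
        tmin, tc, tmax = (
            math.radians(params.theta_min),
            math.radians(params.theta_c),
            math.radians(params.theta_max),
        )

        def weight(r, th):
            return math.exp(-reduced_potential(r, th, 0.0, params, env))

        ZS, _ = dblquad(weight, tc, tmax, r_lo, r_hi, epsrel=1e-9)
        ZL, _ = dblquad(weight, tmin, tc, r_lo, r_hi, epsrel=1e-9)
        p_direct = ZS / (ZS + ZL)
        p = equilibrium_small_angle_probability(0.0, params, env)
        assert p == pytest.approx(p_direct, rel=1e-6)

    def test_monotone_nonincreasing_in_force(self, table1):
        params, env = table1
        forces = np.linspace(0.0, 35.0, 15)
        ps = [equilibrium_small_angle_probability(F, params, env) for F in forces]
        assert all(a >= b - 1e-12 for a, b in zip(ps, ps[1:]))
        assert 0.0 < ps[-1] < ps[0] < 1.0

    def test_small_basin_fills_range_when_alpha_c_near_max(self, table1):
        params, env = table1
        wide = params.replace(alpha_c=168.0)
        assert equilibrium_small_angle_probability(0.0, wide, env) > 0.999

    def test_measure_variants_ordered(self, table1):
        """The 3-d sin(theta) weight suppresses the small-theta (large-alpha)
        basin, so the spherical measure must give the largest p_S0."""
        params, env = table1
        vals = {
            m: equilibrium_small_angle_probability(
                0.0, params, PhysicalEnvironment(measure=m)
            )
            for m in ("flat", "polar", "spherical")
        }
        assert vals["spherical"] > vals["polar"] == pytest.approx(vals["flat"], abs=5e-3)
        assert all(0 < v < 1 for v in vals.values())

    def test_negative_force_rejected(self, table1):
        params, env = table1
        with pytest.raises(InvalidParametersError):
            equilibrium_small_angle_probability(-1.0, params, env)


def test_parameter_validation_messages():
    good = dict(E0=21.8, E1=5.8, H=25.0, G=5.0, d=0.56, r0=1.7,
                alpha_min=48.0, alpha_c=53.0, alpha_max=169.0, phi=0.0)
    ModelParameters(**good)
    for bad in (
        dict(alpha_c=40.0),      # ordering
        dict(alpha_max=190.0),
        dict(E0=-1.0),
        dict(d=0.0),
        dict(phi=30.0),          # theta_min would go negative
    ):
        with pytest.raises(InvalidParametersError):
            ModelParameters(**{**good, **bad})
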