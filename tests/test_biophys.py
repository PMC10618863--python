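"""Ellipsoid heat balance: geometry, conservation, and an independent
full-nonlinear (Stefan-Boltzmann) root-finder oracle."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq

from stresstherm import biophys as bp


def nonlinear_oracle(body: bp.BodyModel, env: bp.Environment,
                     core_temp: float) -> float:
    """Independent solver: full fourth-power radiation, no linearization,
    solved for the surface temperature with a bracketing root-finder."""
    r_cond, area, char_out = bp._conduction_resistance(body)
    t_rad_k = env.t_radiant + 273.15
    eps = body.emissivity

    def balance(t_s: float) -> float:
        h_c = bp._convection_coefficient(t_s, env, char_out)
        q_rad = area * eps * bp.STEFAN_BOLTZMANN * (
            (t_s + 273.15) ** 4 - t_rad_k**4
        )
        q_conv = area * h_c * (t_s - env.air_temp)
        return (core_temp - t_s) / r_cond - q_rad - q_conv

    lo = min(core_temp, env.air_temp) - 60.0
    hi = max(core_temp, env.air_temp) + 60.0
    t_s = brentq(balance, lo, hi, xtol=1e-10)
    return (core_temp - t_s) / r_cond


class TestGeometry:
    def test_insulation_rule_10_and_100_g(self):
        assert bp.insulation_depth_from_mass(10.0) == pytest.approx(0.01)
        assert bp.insulation_depth_from_mass(100.0) == pytest.approx(0.02)

    def test_insulation_floor_for_tiny_masses(self):
        assert bp.insulation_depth_from_mass(1.0) == pytest.approx(0.001)

    def test_volume_equals_mass_in_cm3(self):
        g = bp.ellipsoid_geometry(1000.0, "mammal")
        assert g["volume"] == pytest.approx(1e-3)

    def test_axis_ratio_and_area_quadrature(self):
        g = bp.ellipsoid_geometry(1000.0, "mammal")
        assert g["a"] / g["b"] == pytest.approx(1.3)
        # numeric surface-of-revolution integral as area oracle
        a, b = g["a"], g["b"]
        ts = np.linspace(0.0, math.pi, 200_001)
        x = a * np.cos(ts)
        r = b * np.sin(ts)
        ds = np.sqrt(np.diff(x) ** 2 + np.diff(r) ** 2)
        area_num = float(np.sum(2 * math.pi * 0.5 * (r[1:] + r[:-1]) * ds))
        assert g["area"] == pytest.approx(area_num, rel=1e-3)

    def test_sphere_limit(self):
        r = 0.05
        area = bp._prolate_area(r, r)
        assert area == pytest.approx(4 * math.pi * r**2, rel=1e-9)


class TestHeatBalance:
    def test_no_gradient_no_heat(self):
        body = bp.BodyModel(mass=100.0, taxon_class="mammal")
        env = bp.Environment(air_temp=38.0)
        res = bp.required_heat_production(body, env, 38.0)
        assert res.q_gen == pytest.approx(0.0, abs=1e-9)
        assert res.converged

    def test_energy_conservation(self):
        body = bp.BodyModel(mass=250.0, taxon_class="bird")
        env = bp.Environment(air_temp=-5.0)
        res = bp.required_heat_production(body, env, 40.0)
        assert abs(res.q_gen - (res.radiative + res.convective)) < 1e-6

    def test_monotone_decreasing_in_air_temperature(self):
        body = bp.BodyModel(mass=100.0, taxon_class="mammal")
        qs = [
            bp.required_heat_production(
                body, bp.Environment(air_temp=ta), 38.0
            ).q_gen
            for ta in np.linspace(-20.0, 35.0, 12)
        ]
        assert all(a > b for a, b in zip(qs, qs[1:]))

    def test_removing_insulation_increases_load(self):
        env = bp.Environment(air_temp=0.0)
        thick = bp.BodyModel(mass=100.0, taxon_class="mammal")
        thin = bp.BodyModel(mass=100.0, taxon_class="mammal",
                            insulation_depth=1e-4)
        q_thick = bp.required_heat_production(thick, env, 38.0).q_gen
        q_thin = bp.required_heat_production(thin, env, 38.0).q_gen
        assert q_thin > q_thick

    def test_mass_specific_output_declines_with_mass(self):
        env = bp.Environment(air_temp=10.0)
        per_gram = [
            bp.required_heat_production(
                bp.BodyModel(mass=m, taxon_class="mammal"), env, 38.0
            ).q_gen
            / m
            for m in (5.0, 50.0, 500.0, 5000.0)
        ]
        assert all(a > b for a, b in zip(per_gram, per_gram[1:]))

    def test_dissipation_regime_not_clamped(self):
        body = bp.BodyModel(mass=100.0, taxon_class="mammal")
        res = bp.required_heat_production(
            body, bp.Environment(air_temp=45.0), 38.0
        )
        assert res.q_gen < 0
        assert res.dissipation_regime

    def test_agrees_with_nonlinear_oracle(self):
        body = bp.BodyModel(mass=100.0, taxon_class="mammal")
        env = bp.Environment(air_temp=10.0)
        got = bp.required_heat_production(body, env, 38.0).q_gen
        want = nonlinear_oracle(body, env, 38.0)
        assert got == pytest.approx(want, rel=0.02)

    def test_linearization_error_within_2pct_over_wide_gradients(self):
        body = bp.BodyModel(mass=60.0, taxon_class="bird")
        for ta in (-2.0, 18.0, 34.0):
            got = bp.required_heat_production(
                body, bp.Environment(air_temp=ta), 38.0
            ).q_gen
            want = nonlinear_oracle(body, bp.Environment(air_temp=ta), 38.0)
            assert got == pytest.approx(want, rel=0.02)

    def test_max_mix_rule_differs_but_close(self):
        body = bp.BodyModel(mass=100.0, taxon_class="mammal")
        env = bp.Environment(air_temp=5.0)
        q_cube = bp.required_heat_production(body, env, 38.0).q_gen
        q_max = bp.required_heat_production(
            body, env, 38.0, mix_rule="max"
        ).q_gen
        assert q_max <= q_cube
        assert q_max == pytest.approx(q_cube, rel=0.2)


class TestEnergySaving:
    def test_no_shift_no_saving(self):
        body = bp.BodyModel(mass=100.0, taxon_class="mammal")
        env = bp.Environment(air_temp=10.0)
        assert bp.energy_saving(body, env, 38.0, 38.0) == 0.0

    def test_cold_hypothermia_saves(self):
        body = bp.BodyModel(mass=20.0, taxon_class="bird")
        env = bp.Environment(air_temp=5.0)
        assert bp.energy_saving(body, env, 39.0, 38.5) > 0.0

    def test_cold_hyperthermia_costs(self):
        body = bp.BodyModel(mass=20.0, taxon_class="bird")
        env = bp.Environment(air_temp=5.0)
        assert bp.energy_saving(body, env, 39.0, 39.5) < 0.0

    def test_matches_oracle_to_tenth_of_point(self):
        body = bp.BodyModel(mass=20.0, taxon_class="bird")
        env = bp.Environment(air_temp=5.0)
        got = bp.energy_saving(body, env, 39.0, 38.5)
        q0 = nonlinear_oracle(body, env, 39.0)
        q1 = nonlinear_oracle(body, env, 38.5)
        want = 100.0 * (q0 - q1) / q0
        assert got == pytest.approx(want, abs=0.1)

    def test_undefined_at_zero_baseline(self):
        body = bp.BodyModel(mass=100.0, taxon_class="mammal")
        env = bp.Environment(air_temp=38.0)
        assert math.isnan(bp.energy_saving(body, env, 38.0, 37.5))
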