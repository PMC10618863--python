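"""Ellipsoid heat-balance model for resting metabolic heat production.

An endotherm is modelled as a prolate spheroid of flesh (volume set by
mass at 1000 kg m-3; semi-major axis 1.2x (birds) or 1.3x (mammals) the
semi-minor axes) wrapped in a uniform insulation layer of pelage or
plumage whose depth in centimetres equals log10(mass in grams).  At
steady state the metabolic heat generated in the core flows through two
series conduction resistances (distributed-generation flesh resistance,
then the insulation shell) and leaves the outer surface by thermal
radiation (linearized about the film temperature) and by mixed free and
forced convection (sphere correlations, blended by the cube-root of the
sum of cubes).  Conduction to the substrate and evaporation are
excluded.

``required_heat_production`` solves for the outer-surface temperature by
fixed-point iteration and returns the wattage an animal must generate to
hold a given core temperature in a given environment.  ``energy_saving``
compares that wattage at baseline and stress-shifted core temperatures
and reports the difference as a percentage of the baseline — the resting
expenditure liberated (or incurred) by the stress-induced thermal
response.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

__all__ = [
    "BodyModel",
    "Environment",
    "HeatBalanceResult",
    "insulation_depth_from_mass",
    "ellipsoid_geometry",
    "required_heat_production",
    "energy_saving",
]

STEFAN_BOLTZMANN = 5.670374419e-8  # W m-2 K-4
_GRAVITY = 9.80665  # m s-2
_AIR_CP = 1005.7  # J kg-1 K-1
_AIR_GAS_CONSTANT = 287.04  # J kg-1 K-1
_KELVIN = 273.15

#: Axis ratios (semi-major / semi-minor) by taxonomic class.
AXIS_RATIO = {"bird": 1.2, "mammal": 1.3}

#: Minimum insulation depth (m); the log10 rule is floored here (0.1 cm).
MIN_INSULATION_DEPTH_M = 1e-3


def insulation_depth_from_mass(mass_g: float) -> float:
    """Pelage/plumage depth (m): log10(mass in g) centimetres, floored.

    A 10 g animal carries 1 cm of insulation and a 100 g animal 2 cm;
    below ~1.26 g the rule would go non-positive, so depth is floored at
    0.1 cm.
    """
    if mass_g <= 0:
        raise ValueError("mass must be positive")
    return max(math.log10(mass_g) / 100.0, MIN_INSULATION_DEPTH_M)


def _prolate_area(a: float, b: float) -> float:
    """Closed-form surface area of a prolate spheroid (a >= b)."""
    if a <= b * (1 + 1e-12):
        return 4.0 * math.pi * a * b  # sphere limit
    e = math.sqrt(1.0 - (b / a) ** 2)
    return 2.0 * math.pi * b**2 * (1.0 + (a / (b * e)) * math.asin(e))


def ellipsoid_geometry(
    mass_g: float,
    taxon_class: Literal["bird", "mammal"],
    density: float = 1000.0,
) -> dict[str, float]:
    """Prolate-spheroid dimensions for a body of the given mass.

    Returns semi-axes ``a`` (major) and ``b`` (minor, = c), surface
    ``area`` and ``char_length`` — the diameter of the volume-equivalent
    sphere — all in SI units.
    """
    if mass_g <= 0:
        raise ValueError("mass must be positive")
    ratio = AXIS_RATIO[taxon_class]
    volume = (mass_g / 1000.0) / density  # m^3; 1 g occupies 1 cm^3
    b = (3.0 * volume / (4.0 * math.pi * ratio)) ** (1.0 / 3.0)
    a = ratio * b
    r_eq = (3.0 * volume / (4.0 * math.pi)) ** (1.0 / 3.0)
    return {
        "a": a,
        "b": b,
        "area": _prolate_area(a, b),
        "char_length": 2.0 * r_eq,
        "volume": volume,
    }


@dataclass(frozen=True)
class BodyModel:
    """Geometry, insulation and tissue properties of a model endotherm."""

    mass: float  # grams
    taxon_class: Literal["bird", "mammal"]
    density: float = 1000.0  # kg m-3
    insulation_depth: float | None = None  # m; None -> log10(mass) cm rule
    insulation_conductivity: float = 0.0272  # W m-1 degC-1
    flesh_conductivity: float = 0.5  # W m-1 degC-1
    emissivity: float = 0.95

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError("mass must be positive")
        depth = self.depth
        if depth <= 0:
            raise ValueError("insulation depth must be positive")

    @property
    def depth(self) -> float:
        if self.insulation_depth is not None:
            return self.insulation_depth
        return insulation_depth_from_mass(self.mass)

    @property
    def axis_ratio(self) -> float:
        return AXIS_RATIO[self.taxon_class]

    def geometry(self) -> dict[str, float]:
        return ellipsoid_geometry(self.mass, self.taxon_class, self.density)


@dataclass(frozen=True)
class Environment:
    """Ambient conditions around the animal."""

    air_temp: float  # deg C
    wind_speed: float = 0.1  # m s-1; near-still air during sampling
    radiant_temp: float | None = None  # deg C; defaults to air temperature
    air_pressure: float = 101_325.0  # Pa

    def __post_init__(self) -> None:
        if self.wind_speed < 0:
            raise ValueError("wind speed must be non-negative")

    @property
    def t_radiant(self) -> float:
        return self.air_temp if self.radiant_temp is None else self.radiant_temp


@dataclass
class HeatBalanceResult:
    """Solved steady-state heat budget."""

    q_gen: float  # W, required metabolic heat production
    surface_temp: float  # deg C, outer insulation surface
    radiative: float  # W
    convective: float  # W
    converged: bool
    iterations: int
    dissipation_regime: bool = False  # core colder than surroundings
    diagnostics: dict = field(default_factory=dict)


class ConvergenceError(RuntimeError):
    def __init__(self, msg: str, last: HeatBalanceResult):
        super().__init__(msg)
        self.last = last


def _air_properties(t_film_c: float, pressure: float) -> dict[str, float]:
    """Dry-air transport properties at the film temperature (Sutherland)."""
    t_k = t_film_c + _KELVIN
    mu = 1.8325e-5 * (416.16 / (t_k + 120.0)) * (t_k / 296.16) ** 1.5
    rho = pressure / (_AIR_GAS_CONSTANT * t_k)
    k = 0.02425 + 7.038e-5 * t_film_c
    nu = mu / rho
    alpha = k / (rho * _AIR_CP)
    return {"k": k, "nu": nu, "alpha": alpha, "pr": nu / alpha,
            "beta": 1.0 / t_k}


def _convection_coefficient(
    t_surface: float,
    env: Environment,
    char_length: float,
    *,
    mix_rule: Literal["cube", "max"] = "cube",
) -> float:
    """Mixed free/forced convection coefficient h_c (W m-2 degC-1)."""
    t_film = 0.5 * (t_surface + env.air_temp)
    p = _air_properties(t_film, env.air_pressure)
    d = char_length
    # free convection: Rayleigh-number sphere correlation
    ra = (
        _GRAVITY * p["beta"] * abs(t_surface - env.air_temp) * d**3
        / (p["nu"] * p["alpha"])
    )
    nu_free = 2.0 + 0.6 * ra**0.25
    # forced convection: Nu = 2 + 0.6 Re^1/2 Pr^1/3 (sphere)
    re = env.wind_speed * d / p["nu"]
    nu_forced = 2.0 + 0.6 * math.sqrt(re) * p["pr"] ** (1.0 / 3.0)
    if mix_rule == "cube":
        nu = (nu_free**3 + nu_forced**3) ** (1.0 / 3.0)
    elif mix_rule == "max":
        nu = max(nu_free, nu_forced)
    else:
        raise ValueError(f"unknown convection mix rule: {mix_rule!r}")
    return nu * p["k"] / d


def _radiation_coefficient(t_surface: float, t_radiant: float,
                           emissivity: float) -> float:
    """Linearized radiation coefficient 4*eps*sigma*Tbar^3 at the film."""
    t_bar = 0.5 * (t_surface + t_radiant) + _KELVIN
    return 4.0 * emissivity * STEFAN_BOLTZMANN * t_bar**3


def _conduction_resistance(body: BodyModel) -> tuple[float, float, float]:
    """(total series resistance, outer area, outer char length)."""
    g = body.geometry()
    d = body.depth
    # distributed-generation flesh resistance of the volume-equivalent sphere
    r_core = g["char_length"] / 2.0
    r_flesh = 1.0 / (8.0 * math.pi * body.flesh_conductivity * r_core)
    # uniform insulation shell: conduction over the mean of inner/outer areas
    area_out = _prolate_area(g["a"] + d, g["b"] + d)
    area_mean = 0.5 * (g["area"] + area_out)
    r_ins = d / (body.insulation_conductivity * area_mean)
    char_out = g["char_length"] + 2.0 * d
    return r_flesh + r_ins, area_out, char_out


def required_heat_production(
    body: BodyModel,
    env: Environment,
    core_temp: float,
    *,
    tol: float = 1e-6,
    max_iter: int = 100,
    mix_rule: Literal["cube", "max"] = "cube",
) -> HeatBalanceResult:
    """Metabolic heat production (W) needed to hold ``core_temp``.

    Solves the series network core -> flesh -> insulation -> surface,
    with surface losses by linearized radiation plus mixed convection,
    by fixed-point iteration on the surface temperature (tolerance
    ``tol`` deg C).  A negative q_gen (core colder than surroundings,
    heat-dissipation regime) is reported, not clamped.
    """
    if not (math.isfinite(core_temp) and math.isfinite(env.air_temp)):
        raise ValueError("temperatures must be finite")
    r_cond, area, char_out = _conduction_resistance(body)
    t_rad = env.t_radiant
    t_s = 0.5 * (core_temp + env.air_temp)  # initial guess
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        h_r = _radiation_coefficient(t_s, t_rad, body.emissivity)
        h_c = _convection_coefficient(t_s, env, char_out, mix_rule=mix_rule)
        t_new = (
            core_temp / r_cond + area * (h_r * t_rad + h_c * env.air_temp)
        ) / (1.0 / r_cond + area * (h_r + h_c))
        if abs(t_new - t_s) < tol:
            t_s = t_new
            converged = True
            break
        t_s = t_new
    # final consistent solve so generation equals losses to rounding
    h_r = _radiation_coefficient(t_s, t_rad, body.emissivity)
    h_c = _convection_coefficient(t_s, env, char_out, mix_rule=mix_rule)
    t_s = (
        core_temp / r_cond + area * (h_r * t_rad + h_c * env.air_temp)
    ) / (1.0 / r_cond + area * (h_r + h_c))
    q_gen = (core_temp - t_s) / r_cond
    result = HeatBalanceResult(
        q_gen=q_gen,
        surface_temp=t_s,
        radiative=area * h_r * (t_s - t_rad),
        convective=area * h_c * (t_s - env.air_temp),
        converged=converged,
        iterations=iterations,
        dissipation_regime=q_gen < 0,
        diagnostics={"h_r": h_r, "h_c": h_c, "area": area,
                     "r_cond": r_cond, "char_length": char_out},
    )
    if not converged:
        raise ConvergenceError(
            f"surface temperature did not converge in {max_iter} iterations",
            result,
        )
    return result


def energy_saving(
    body: BodyModel,
    env: Environment,
    tb_baseline: float,
    tb_stress: float,
    **solver_kwargs,
) -> float:
    """Percent of baseline resting expenditure liberated by a temperature
    shift from ``tb_baseline`` to ``tb_stress`` (positive = saving).

    Undefined when the baseline budget is zero (core at ambient); NaN is
    returned so per-record pipelines can report it as such.
    """
    q_base = required_heat_production(body, env, tb_baseline, **solver_kwargs)
    q_stress = required_heat_production(body, env, tb_stress, **solver_kwargs)
    if q_base.q_gen == 0.0:
        return math.nan
    return 100.0 * (q_base.q_gen - q_stress.q_gen) / q_base.q_gen
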