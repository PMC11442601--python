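"""Closed-form electrophysical calculators for a parallel-plate PEF chamber.

Everything here is desk arithmetic: homogeneous field between plates, ohmic
conduction, electromigration of the protein toward the anode, Faraday
coulometry, adiabatic Joule heating, and an indirect thermometer based on the
temperature dependence of the solution conductivity (Walden rule: conductivity
scales with the reciprocal water viscosity).

Units are SI throughout unless a function name says otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy.optimize import brentq

from .constants import (
    AVOGADRO,
    FARADAY,
    VISCOSITY_T_MAX_C,
    VISCOSITY_T_MIN_C,
    WATER_DENSITY,
    WATER_HEAT_CAPACITY,
    water_viscosity,
)


class GeometryError(ValueError):
    """Raised for inconsistent or non-positive chamber dimensions."""


@dataclass(frozen=True)
class ChamberGeometry:
    """Parallel-plate treatment chamber.

    Parameters
    ----------
    electrode_gap : float
        Anode-cathode distance d (m).
    electrode_diameter : float
        Diameter of the circular electrodes (m).
    cross_section_area : float, optional
        Sample cross-section A (m^2). Derived from the diameter when omitted.
    volume : float, optional
        Chamber volume (m^3). Derived as A*d when omitted.
    electrode_layer_thickness : float
        Thickness delta of the thin reaction layer adjacent to each electrode
        (m); a model parameter, not a machined dimension.
    """

    electrode_gap: float
    electrode_diameter: float
    cross_section_area: float = 0.0
    volume: float = 0.0
    electrode_layer_thickness: float = 100e-9

    def __post_init__(self) -> None:
        if self.electrode_gap <= 0:
            raise GeometryError("electrode gap must be positive")
        if self.electrode_diameter <= 0:
            raise GeometryError("electrode diameter must be positive")
        area = math.pi * (self.electrode_diameter / 2.0) ** 2
        if self.cross_section_area == 0.0:
            object.__setattr__(self, "cross_section_area", area)
        elif abs(self.cross_section_area - area) / area > 0.005:
            raise GeometryError(
                "cross_section_area inconsistent with diameter (>0.5%)"
            )
        vol = self.cross_section_area * self.electrode_gap
        if self.volume == 0.0:
            object.__setattr__(self, "volume", vol)
        elif abs(self.volume - vol) / vol > 0.005:
            raise GeometryError("volume inconsistent with area*gap (>0.5%)")
        if not (0 < self.electrode_layer_thickness < 0.1 * self.electrode_gap):
            raise GeometryError(
                "electrode layer thickness must be positive and << gap"
            )


@dataclass(frozen=True)
class PulseProtocol:
    """Train of rectangular unipolar voltage pulses."""

    n_pulses: int
    pulse_width: float  # s
    period: float       # s
    amplitude: float    # V

    def __post_init__(self) -> None:
        if self.n_pulses < 0:
            raise ValueError("n_pulses must be >= 0")
        if self.n_pulses >= 1 and not (0 < self.pulse_width < self.period):
            raise ValueError("need 0 < pulse_width < period")

    @property
    def total_on_time(self) -> float:
        """Cumulative time (s) the field is on."""
        return self.n_pulses * self.pulse_width


@dataclass(frozen=True)
class SampleProperties:
    """Bulk properties of the treated solution."""

    conductivity: float = 0.033          # S m^-1
    ph: float = 7.2
    bsa_concentration: float = 0.6       # mol m^-3 (0.6 mM)
    bsa_mobility: float = 1.4e-8         # m^2 s^-1 V^-1
    bsa_diffusion_coeff: float = 6.3e-11  # m^2 s^-1
    bsa_diameter: float = 7.0e-9         # m
    density: float = WATER_DENSITY       # kg m^-3
    heat_capacity: float = WATER_HEAT_CAPACITY  # J kg^-1 K^-1
    initial_temperature: float = 22.0    # degC

    def __post_init__(self) -> None:
        for name in (
            "conductivity",
            "bsa_diffusion_coeff",
            "bsa_diameter",
            "density",
            "heat_capacity",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


# -- stock-chamber factory objects -------------------------------------------

def default_geometry() -> ChamberGeometry:
    """The 2.00 mm gap / 26 mm diameter chamber."""
    return ChamberGeometry(electrode_gap=2.00e-3, electrode_diameter=26e-3)


def default_protocol() -> PulseProtocol:
    """30 pulses, 100 us wide, 1 Hz, 1470 V."""
    return PulseProtocol(n_pulses=30, pulse_width=100e-6, period=1.0,
                         amplitude=1470.0)


# -- calculators -------------------------------------------------------------

def field_strength(protocol: PulseProtocol, geometry: ChamberGeometry) -> float:
    """Homogeneous field E = U/d between parallel plates (V m^-1)."""
    if geometry.electrode_gap <= 0:
        raise GeometryError("electrode gap must be positive")
    return protocol.amplitude / geometry.electrode_gap


def theoretical_current(sample: SampleProperties, geometry: ChamberGeometry,
                        protocol: PulseProtocol) -> float:
    """Ohmic pulse current I = sigma*A*U/d (A)."""
    return (sample.conductivity * geometry.cross_section_area
            * protocol.amplitude / geometry.electrode_gap)


def electromigration_displacement(sample: SampleProperties,
                                  protocol: PulseProtocol,
                                  geometry: ChamberGeometry) -> float:
    """Distance BSA migrates over the whole pulse train, mu*E*t_on (m).

    Capped at the electrode gap: molecules reaching the anode stop there.
    """
    if sample.bsa_mobility < 0:
        raise ValueError("mobility must be >= 0")
    e_field = field_strength(protocol, geometry)
    d_mig = sample.bsa_mobility * e_field * protocol.total_on_time
    return min(d_mig, geometry.electrode_gap)


def accumulated_surface_amount(concentration: float,
                               displacement: float) -> float:
    """Swept-volume surface accumulation Gamma = c * d_mig (mol m^-2).

    ``concentration`` in mol m^-3, ``displacement`` in m.
    """
    if concentration < 0 or displacement < 0:
        raise ValueError("inputs must be >= 0")
    return concentration * displacement


def monolayer_coverage(molecule_diameter: float) -> float:
    """Hexagonally close-packed monolayer surface density (mol m^-2).

    One sphere per hexagonal unit cell of area (sqrt(3)/2) d^2:
    Gamma_mono = 2 / (sqrt(3) d^2 N_A).
    """
    if molecule_diameter <= 0:
        raise ValueError("diameter must be positive")
    return 2.0 / (math.sqrt(3.0) * molecule_diameter ** 2 * AVOGADRO)


def layer_count(surface_amount: float, monolayer: float) -> float:
    """Number of molecular layers Gamma / Gamma_mono (dimensionless)."""
    if monolayer <= 0:
        raise ZeroDivisionError("monolayer coverage must be positive")
    return surface_amount / monolayer


def joule_heating_adiabatic(protocol: PulseProtocol, current: float,
                            geometry: ChamberGeometry,
                            sample: SampleProperties) -> float:
    """Temperature rise (K) if all electrical energy stays in the sample.

    dT = U * I * t_on / (rho * V * c_p); no heat loss through the electrodes.
    """
    mass = sample.density * geometry.volume
    energy = protocol.amplitude * current * protocol.total_on_time
    return energy / (mass * sample.heat_capacity)


def current_ratio_from_temperature(t0_c: float, t_c: float) -> float:
    """Forward map of the current-rise thermometer: I(T)/I(T0) = eta(T0)/eta(T)."""
    return water_viscosity(t0_c) / water_viscosity(t_c)


def temperature_from_current_rise(current_ratio: float, t0_c: float) -> float:
    """Invert the Walden-type conductivity-viscosity relation (returns T - T0, K).

    The pulse current through an ohmic sample grows as the solution warms
    because ionic mobilities scale with 1/viscosity; the observed fractional
    current rise therefore encodes the temperature rise.
    """
    if current_ratio < 1.0:
        raise ValueError("current_ratio must be >= 1")
    if not (VISCOSITY_T_MIN_C <= t0_c <= VISCOSITY_T_MAX_C):
        raise ValueError("T0 outside viscosity correlation range")
    if current_ratio == 1.0:
        return 0.0
    target = water_viscosity(t0_c) / current_ratio
    if target < water_viscosity(VISCOSITY_T_MAX_C):
        raise ValueError("current_ratio outside correlation range (T > 60 degC)")

    def f(t_c: float) -> float:
        return water_viscosity(t_c) - target

    t_final = brentq(f, t0_c, VISCOSITY_T_MAX_C)
    return t_final - t0_c


def faraday_amount(charge: float, electrons_per_event: int) -> float:
    """Moles transformed by ``charge`` coulombs at z electrons per event."""
    if charge < 0:
        raise ValueError("charge must be >= 0")
    if electrons_per_event < 1:
        raise ValueError("electrons_per_event must be >= 1")
    return charge / (electrons_per_event * FARADAY)


def faraday_ratio(observed_amount: float, charge: float,
                  electrons_per_event: int) -> float:
    """Observed amount as a fraction of the Faraday-law prediction."""
    predicted = faraday_amount(charge, electrons_per_event)
    if predicted == 0:
        raise ZeroDivisionError("zero predicted amount")
    return observed_amount / predicted


def diffusion_length(diffusion_coeff: float, lifetime: float) -> float:
    """Diffusional length scale L = sqrt(D * tau) (m)."""
    if diffusion_coeff < 0 or lifetime < 0:
        raise ValueError("inputs must be >= 0")
    return math.sqrt(diffusion_coeff * lifetime)


def iron_content_molar(ppm_by_mass: float, protein_mg_per_ml: float,
                       molar_mass_g_per_mol: float = 55.845) -> float:
    """Convert a trace-metal mass fraction of the solid protein to solution molarity.

    ``ppm_by_mass`` grams of metal per 1e6 g protein, dissolved at
    ``protein_mg_per_ml``; returns mol L^-1.
    """
    if ppm_by_mass < 0 or protein_mg_per_ml < 0:
        raise ValueError("inputs must be >= 0")
    grams_metal_per_l = ppm_by_mass * 1e-6 * protein_mg_per_ml
    return grams_metal_per_l / molar_mass_g_per_mol


def physics_report(sample: SampleProperties | None = None,
                   geometry: ChamberGeometry | None = None,
                   protocol: PulseProtocol | None = None,
                   observed_current: float = 12.5) -> list[dict]:
    """Tabulate every chamber/protocol quantity the calculators derive.

    Returns a list of rows ``{quantity, value, units, formula}`` suitable for
    aligned-text or TSV printing (see the ``physics`` CLI subcommand).
    """
    sample = sample or SampleProperties()
    geometry = geometry or default_geometry()
    protocol = protocol or default_protocol()
    e_field = field_strength(protocol, geometry)
    i_theory = theoretical_current(sample, geometry, protocol)
    d_mig = electromigration_displacement(sample, protocol, geometry)
    gamma = accumulated_surface_amount(sample.bsa_concentration, d_mig)
    gamma_mono = monolayer_coverage(sample.bsa_diameter)
    rows = [
        ("field strength", e_field, "V m^-1", "U/d"),
        ("theoretical current", i_theory, "A", "sigma*A*U/d"),
        ("total on-time", protocol.total_on_time, "s", "n*t_pulse"),
        ("total charge (observed I)",
         observed_current * protocol.total_on_time, "C", "I*n*t_pulse"),
        ("migration displacement", d_mig, "m", "mu*E*t_on"),
        ("accumulated BSA", gamma, "mol m^-2", "c*d_mig"),
        ("monolayer coverage", gamma_mono, "mol m^-2", "2/(sqrt3*d^2*N_A)"),
        ("layer count", layer_count(gamma, gamma_mono), "-", "Gamma/Gamma_mono"),
        ("chamber area", geometry.cross_section_area, "m^2", "pi*(D/2)^2"),
        ("chamber volume", geometry.volume, "m^3", "A*gap"),
        ("adiabatic Joule heating",
         joule_heating_adiabatic(protocol, observed_current, geometry, sample),
         "K", "U*I*t_on/(rho*V*cp)"),
    ]
    return [
        {"quantity": q, "value": v, "units": u, "formula": f}
        for q, v, u, f in rows
    ]
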