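"""Moist-air property calculations.

Saturation vapour density via the Magnus form of the saturation vapour
pressure curve (Alduchov & Eskridge coefficients) with ideal-gas conversion,
absolute humidity, and temperature-dependent dry-air transport properties
(ideal-gas density, Sutherland viscosity, polynomial conductivity, Massman
vapour diffusivity).

All temperatures are in degrees Celsius, concentrations in kg of water per
cubic metre of (moist) air, pressures in Pa.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AmbientAir",
    "AirProperties",
    "saturation_vapour_pressure",
    "saturation_vapour_density",
    "absolute_humidity",
    "air_transport_properties",
    "TEMP_MIN_C",
    "TEMP_MAX_C",
]

#: validity range of the correlations used here, °C
TEMP_MIN_C = -20.0
TEMP_MAX_C = 50.0

#: specific gas constant of water vapour, J/(kg·K)
R_WATER_VAPOUR = 461.5
#: specific gas constant of dry air, J/(kg·K)
R_DRY_AIR = 287.05
#: standard barometric pressure, Pa
P_STANDARD = 101325.0

# Magnus saturation-pressure coefficients (Alduchov & Eskridge, over water)
_MAGNUS_A = 610.94   # Pa
_MAGNUS_B = 17.625
_MAGNUS_C = 243.04   # °C

_KELVIN = 273.15


def _check_temperature(t_c) -> None:
    t = np.asarray(t_c, dtype=float)
    if np.any(t < TEMP_MIN_C) or np.any(t > TEMP_MAX_C):
        raise ValueError(
            f"temperature {t_c!r} °C outside correlation validity range "
            f"[{TEMP_MIN_C}, {TEMP_MAX_C}] °C"
        )


def saturation_vapour_pressure(t_c):
    """Saturation vapour pressure over liquid water, Pa (Magnus form)."""
    _check_temperature(t_c)
    t = np.asarray(t_c, dtype=float)
    p = _MAGNUS_A * np.exp(_MAGNUS_B * t / (t + _MAGNUS_C))
    return float(p) if np.isscalar(t_c) else p


def saturation_vapour_density(t_c):
    """Water-vapour density of saturated air at ``t_c`` °C, kg/m³.

    Ideal-gas conversion of the Magnus saturation pressure using the water
    vapour gas constant (461.5 J/(kg·K)). Strictly increasing in ``t_c``.
    """
    p_sat = saturation_vapour_pressure(t_c)
    t_k = np.asarray(t_c, dtype=float) + _KELVIN
    rho = p_sat / (R_WATER_VAPOUR * t_k)
    return float(rho) if np.isscalar(t_c) else rho


def absolute_humidity(t_c, relative_humidity):
    """Water-vapour mass concentration of air at ``t_c`` °C and the given
    relative humidity (fraction in [0, 1]), kg/m³."""
    rh = np.asarray(relative_humidity, dtype=float)
    if np.any(rh < 0.0) or np.any(rh > 1.0):
        raise ValueError(
            f"relative humidity {relative_humidity!r} outside [0, 1]"
        )
    out = rh * saturation_vapour_density(t_c)
    scalar = np.isscalar(t_c) and np.isscalar(relative_humidity)
    return float(out) if scalar else out


@dataclass(frozen=True)
class AmbientAir:
    """Ambient (inlet) air condition.

    Parameters
    ----------
    temperature_c : float
        Dry-bulb temperature, °C. Must lie in the correlation validity range.
    relative_humidity : float
        Fraction in [0, 1].
    pressure_pa : float
        Barometric pressure, Pa.
    """

    temperature_c: float
    relative_humidity: float
    pressure_pa: float = P_STANDARD

    def __post_init__(self) -> None:
        _check_temperature(self.temperature_c)
        if not 0.0 <= self.relative_humidity <= 1.0:
            raise ValueError(
                f"relative humidity {self.relative_humidity} outside [0, 1]"
            )
        if self.pressure_pa <= 0:
            raise ValueError("pressure must be positive")

    @property
    def absolute_humidity(self) -> float:
        """Vapour concentration, kg/m³."""
        return absolute_humidity(self.temperature_c, self.relative_humidity)


@dataclass(frozen=True)
class AirProperties:
    """Dry-air transport properties at one temperature and pressure."""

    density: float                # kg/m³
    dynamic_viscosity: float      # Pa·s
    thermal_conductivity: float   # W/(m·K)
    specific_heat: float          # J/(kg·K)
    vapour_diffusivity: float     # m²/s
    temperature_c: float = field(default=float("nan"), compare=False)
    pressure_pa: float = field(default=P_STANDARD, compare=False)

    @property
    def thermal_diffusivity(self) -> float:
        """k / (ρ·cp), m²/s."""
        return self.thermal_conductivity / (self.density * self.specific_heat)

    @property
    def lewis_number(self) -> float:
        """Le = thermal diffusivity / vapour diffusivity."""
        return self.thermal_diffusivity / self.vapour_diffusivity


def air_transport_properties(t_c: float, pressure_pa: float = P_STANDARD) -> AirProperties:
    """Dry-air properties at ``t_c`` °C and ``pressure_pa``.

    Density from the ideal gas law; viscosity from Sutherland's law;
    conductivity from a polynomial fit in absolute temperature; specific heat
    taken constant at 1006 J/(kg·K) (variation < 0.1% over the range);
    water-vapour diffusivity from the Massman power law, pressure-corrected.
    """
    _check_temperature(t_c)
    if pressure_pa <= 0:
        raise ValueError("pressure must be positive")
    t_k = t_c + _KELVIN

    density = pressure_pa / (R_DRY_AIR * t_k)
    # Sutherland: mu_ref = 1.716e-5 Pa·s at 273.15 K, S = 110.4 K
    mu = 1.716e-5 * (t_k / _KELVIN) ** 1.5 * (_KELVIN + 110.4) / (t_k + 110.4)
    k = 1.5207e-11 * t_k**3 - 4.8574e-8 * t_k**2 + 1.0184e-4 * t_k - 3.9333e-4
    cp = 1006.0
    d_v = 2.178e-5 * (t_k / _KELVIN) ** 1.81 * (P_STANDARD / pressure_pa)

    return AirProperties(
        density=density,
        dynamic_viscosity=mu,
        thermal_conductivity=k,
        specific_heat=cp,
        vapour_diffusivity=d_v,
        temperature_c=t_c,
        pressure_pa=pressure_pa,
    )
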