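"""Potential evapotranspiration from temperature: Oudin PET with terrain heat loading.

PET is computed with the Oudin temperature formulation,

    PET (mm/day) = Ra / (lambda * rho) * (T + offset) / 100   for T + offset > 0,
    PET = 0 otherwise,

where Ra is daily extraterrestrial (top-of-atmosphere) radiation in MJ m^-2
day^-1, lambda = 2.45 MJ kg^-1 the latent heat of vaporisation, rho = 1 Mg
m^-3 the density of water (so Ra/lambda is an evaporative-equivalent depth in
mm/day), and offset = 5 degC.  Ra follows the standard FAO-56 closed form with
solar declination recomputed for every day of the year.  The terrain
adjustment is a McCune–Keon-style heat-load multiplier built from latitude,
slope, and aspect folded about the southwest axis, normalised so a flat cell
has index 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PetParams", "RadiationContext", "solar_declination",
    "extraterrestrial_radiation", "oudin_pet", "heat_load_index", "daily_pet",
]

SOLAR_CONSTANT = 0.0820  # MJ m^-2 min^-1 (FAO-56)
LATENT_HEAT = 2.45       # MJ kg^-1


@dataclass
class PetParams:
    """Tunables of the Oudin equation (exposed for sensitivity tests)."""

    latent_heat: float = LATENT_HEAT  # MJ kg^-1
    temp_offset: float = 5.0          # degC; PET is zero at/below -offset


@dataclass
class RadiationContext:
    """Solar geometry for one cell-day (mainly a debugging/inspection aid)."""

    latitude: float   # radians
    day_of_year: int
    declination: float               # radians
    extraterrestrial_radiation: float  # MJ m^-2 day^-1


def solar_declination(day_of_year):
    """Solar declination (radians) for a 1-based day of year.

    delta = 0.409 * sin(2*pi*J/365 - 1.39); smooth and annual-periodic.
    """
    j = np.asarray(day_of_year)
    if np.any(j < 1) or np.any(j > 366):
        raise ValueError("day_of_year must be in 1..366")
    return 0.409 * np.sin(2.0 * np.pi * j / 365.0 - 1.39)


def extraterrestrial_radiation(latitude, day_of_year):
    """Daily top-of-atmosphere radiation Ra (MJ m^-2 day^-1), FAO-56 closed form.

    ``latitude`` is in decimal degrees.  The sunset hour angle is clamped so
    polar night returns exactly 0 and polar day integrates over 24 h.
    """
    lat = np.radians(np.asarray(latitude, dtype=float))
    if np.any(np.abs(lat) > np.pi / 2 + 1e-12):
        raise ValueError("latitude outside [-90, 90] degrees")
    j = np.asarray(day_of_year)
    decl = solar_declination(j)
    dr = 1.0 + 0.033 * np.cos(2.0 * np.pi * j / 365.0)
    # cos(omega_s) clamped to [-1, 1]: +1 -> polar night (Ra = 0), -1 -> polar day
    cos_ws = np.clip(-np.tan(lat) * np.tan(decl), -1.0, 1.0)
    ws = np.arccos(cos_ws)
    ra = (24.0 * 60.0 / np.pi) * SOLAR_CONSTANT * dr * (
        ws * np.sin(lat) * np.sin(decl) + np.cos(lat) * np.cos(decl) * np.sin(ws))
    return np.maximum(ra, 0.0)


def oudin_pet(ra, tmean, params: PetParams = PetParams()):
    """Oudin PET (mm/day) from extraterrestrial radiation and daily mean temperature."""
    ra = np.asarray(ra, dtype=float)
    t = np.asarray(tmean, dtype=float)
    pet = ra / params.latent_heat * (t + params.temp_offset) / 100.0
    return np.where(t + params.temp_offset > 0.0, np.maximum(pet, 0.0), 0.0)


def heat_load_index(latitude, slope, aspect):
    """Unitless terrain heat-load multiplier (flat cell = 1).

    McCune–Keon-style equation on folded aspect, ``folded = |180 - |aspect -
    225||`` degrees, so southwest-facing slopes (aspect 225) receive the
    maximum load and northeast-facing the minimum at a given slope and
    latitude.  The published fit covers 0–60 N; latitudes outside that range
    are clamped with a warning (southern-hemisphere cells are treated by
    absolute latitude).
    """
    lat = np.asarray(latitude, dtype=float)
    slope = np.asarray(slope, dtype=float)
    aspect = np.asarray(aspect, dtype=float)
    if np.any(slope < 0) or np.any(slope > 90):
        raise ValueError("slope outside [0, 90] degrees")
    if np.any(aspect < 0) or np.any(aspect >= 360):
        raise ValueError("aspect outside [0, 360) degrees")
    abslat = np.abs(lat)
    if np.any(abslat > 60):
        warnings.warn("latitude outside the 0-60 deg validity range of the "
                      "heat-load equation; clamping", stacklevel=2)
        abslat = np.clip(abslat, 0.0, 60.0)
    lat_r = np.radians(abslat)
    slope_r = np.radians(slope)
    folded_r = np.radians(np.abs(180.0 - np.abs(aspect - 225.0)))
    ln_hl = (0.339 + 0.808 * np.cos(lat_r) * np.cos(slope_r)
             - 0.196 * np.sin(lat_r) * np.sin(slope_r)
             - 0.482 * np.cos(folded_r) * np.sin(slope_r))
    ln_flat = 0.339 + 0.808 * np.cos(lat_r)  # same cell with slope 0
    return np.exp(ln_hl - ln_flat)


def daily_pet(tmean, cell, day_of_year, params: PetParams = PetParams()):
    """Terrain-adjusted daily PET (mm) for a cell: Oudin PET x heat-load index.

    The heat load multiplies the finished Oudin PET, so the temperature cutoff
    (PET = 0 at tmean <= -offset) is terrain-independent.
    """
    ra = extraterrestrial_radiation(cell.latitude, day_of_year)
    hl = heat_load_index(cell.latitude, cell.slope, cell.aspect)
    return oudin_pet(ra, tmean, params) * hl
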