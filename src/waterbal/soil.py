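"""Soil-bucket water accounting: interception, NDVI-scaled demand, AET, CWD, runoff.

Liquid water reaching the ground (rain + snowmelt) first meets the day's
evaporative demand; any surplus recharges a single soil bucket of capacity WHC
and spills as same-day runoff once the bucket is full.  On days when supply
falls short of demand, the bucket is drawn down along the Thornthwaite–Mather
exponential drying curve, so AET declines smoothly as soil water is depleted.
Reported AET is the soil-derived AET plus same-day canopy interception loss;
CWD = PET − AET.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pet import PetParams, daily_pet
from .snow import SnowParams, step_snow

__all__ = [
    "SoilParams", "ModelParams", "WaterState", "DailyFluxes",
    "intercept", "ndvi_aet_scalar", "step_soil", "step_water", "step_cell",
]

FLUX_NAMES = ("pet", "aet", "cwd", "rain", "snowfall", "melt", "runoff",
              "interception_loss", "soil_water", "swe")


@dataclass
class SoilParams:
    """Soil and vegetation parameters.

    whc : soil water holding capacity of the top meter, mm (scalar default;
        gridded runs take WHC from the attribute grid).
    interception_fraction : fraction of precipitation intercepted by the
        canopy and evaporated the same day (default 0: feature is opt-in).
    aet_scalar_bounds : (min, max) multiplier that NDVI maps onto; the scalar
        multiplies the PET demand presented to the soil.
    """

    whc: float | np.ndarray = 150.0
    interception_fraction: float = 0.0
    aet_scalar_bounds: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self):
        if np.any(np.asarray(self.whc) <= 0):
            raise ValueError("whc must be > 0 mm")
        if not 0.0 <= self.interception_fraction < 1.0:
            raise ValueError("interception_fraction must be in [0, 1)")
        lo, hi = self.aet_scalar_bounds
        if lo > hi:
            raise ValueError("aet_scalar_bounds must be (min, max) with min <= max")


@dataclass
class ModelParams:
    """All tunables of the daily water-balance step."""

    snow: SnowParams = field(default_factory=SnowParams)
    soil: SoilParams = field(default_factory=SoilParams)
    pet: PetParams = field(default_factory=PetParams)


@dataclass
class WaterState:
    """Prognostic storages (mm); scalars for a site, 2-D arrays for a grid."""

    swe: np.ndarray | float = 0.0
    soil: np.ndarray | float = 0.0

    def copy(self) -> "WaterState":
        return WaterState(np.copy(self.swe), np.copy(self.soil))

    def total(self):
        return np.asarray(self.swe, dtype=float) + np.asarray(self.soil, dtype=float)


@dataclass
class DailyFluxes:
    """Diagnostic outputs of one model day (all mm; states are end-of-day)."""

    pet: np.ndarray | float
    aet: np.ndarray | float
    cwd: np.ndarray | float
    rain: np.ndarray | float
    snowfall: np.ndarray | float
    melt: np.ndarray | float
    runoff: np.ndarray | float
    interception_loss: np.ndarray | float
    soil_water: np.ndarray | float
    swe: np.ndarray | float


def intercept(precip, params: SoilParams = SoilParams()):
    """Split incoming precipitation into (throughfall, interception_loss)."""
    p = np.asarray(precip, dtype=float)
    loss = params.interception_fraction * p
    return p - loss, loss


def ndvi_aet_scalar(ndvi, bounds=(0.0, 1.0)):
    """Map NDVI in [-1, 1] to an AET-demand multiplier in [min, max].

    Linear between NDVI 0 and 1; NDVI <= 0 clamps to the lower bound.
    """
    lo, hi = bounds
    n = np.clip(np.asarray(ndvi, dtype=float), 0.0, 1.0)
    return lo + (hi - lo) * n


def step_soil(soil_prev, water_in, pet_demand, params: SoilParams):
    """Advance the soil bucket one day; returns (soil_new, aet_from_soil, runoff).

    Supply >= demand: demand is met in full, the surplus recharges the bucket,
    and anything beyond WHC runs off the same day.  Supply < demand: the
    unmet demand extracts ``soil * (1 - exp(-unmet / whc))`` from storage
    (Thornthwaite–Mather drying curve); no runoff.
    """
    s = np.asarray(soil_prev, dtype=float)
    win = np.asarray(water_in, dtype=float)
    dem = np.asarray(pet_demand, dtype=float)
    whc = np.asarray(params.whc, dtype=float)
    if np.any(win[np.isfinite(win)] < 0) or np.any(dem[np.isfinite(dem)] < 0):
        raise ValueError("water_in and pet_demand must be non-negative")
    if np.any(s[np.isfinite(s)] < -1e-9):
        raise ValueError("soil_prev must be non-negative")

    surplus_day = win >= dem
    # wet branch
    recharge = win - dem
    filled = s + recharge
    runoff_wet = np.maximum(filled - whc, 0.0)
    soil_wet = np.minimum(filled, whc)
    # dry branch
    unmet = dem - win
    extraction = s * -np.expm1(-unmet / whc)
    soil_dry = s - extraction
    aet_dry = win + extraction

    soil_new = np.where(surplus_day, soil_wet, soil_dry)
    aet = np.where(surplus_day, dem, aet_dry)
    runoff = np.where(surplus_day, runoff_wet, 0.0)
    return soil_new, aet, runoff


def step_water(state: WaterState, tmean, precip, pet, ndvi_scalar,
               params: ModelParams, snow_t50=None):
    """One day of the full hydrology given precomputed PET.

    Order of operations: canopy interception → rain/snow partition and snow
    step → NDVI scaling of the PET demand → soil bucket.  Reported AET is the
    soil AET plus interception loss; CWD = PET − AET, clamped at ≥ 0.

    Returns (new_state, DailyFluxes).  All arguments broadcast.
    """
    snow_params = params.snow
    if snow_t50 is not None:
        snow_params = SnowParams(snow_t50, params.snow.partition_width,
                                 params.snow.melt_factor, params.snow.melt_threshold,
                                 params.snow.partition)
    throughfall, icept = intercept(precip, params.soil)
    swe_new, rain, snowfall, melted = step_snow(state.swe, throughfall, tmean,
                                                snow_params)
    demand = np.asarray(pet, dtype=float) * np.asarray(ndvi_scalar, dtype=float)
    soil_new, aet_soil, runoff = step_soil(state.soil, rain + melted, demand,
                                           params.soil)
    aet = aet_soil + icept
    pet_arr = np.asarray(pet, dtype=float)
    cwd = np.maximum(pet_arr - aet, 0.0)
    fluxes = DailyFluxes(pet=pet_arr, aet=aet, cwd=cwd, rain=rain,
                         snowfall=snowfall, melt=melted, runoff=runoff,
                         interception_loss=icept, soil_water=soil_new, swe=swe_new)
    return WaterState(swe_new, soil_new), fluxes


def step_cell(state: WaterState, tmean, precip, cell, day_of_year,
              params: ModelParams = None):
    """One model day for a cell described by :class:`CellAttributes`.

    Composes terrain-adjusted Oudin PET with :func:`step_water`; the NDVI
    climatology entry for ``day_of_year`` scales the demand.  WHC is taken
    from the cell attributes.
    """
    if params is None:
        params = ModelParams()
    pet = daily_pet(tmean, cell, day_of_year, params.pet)
    # Day 366 (Gregorian Dec 31 of a leap year) reuses the last climatology entry.
    clim_idx = np.minimum(np.asarray(day_of_year) - 1, 364)
    ndvi = cell.ndvi_climatology[clim_idx]
    scalar = ndvi_aet_scalar(ndvi, params.soil.aet_scalar_bounds)
    soil_params = params.soil
    if cell.whc is not None:
        soil_params = SoilParams(cell.whc, params.soil.interception_fraction,
                                 params.soil.aet_scalar_bounds)
    cell_params = ModelParams(params.snow, soil_params, params.pet)
    return step_water(state, tmean, precip, pet, scalar, cell_params,
                      snow_t50=cell.snow_t50)
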