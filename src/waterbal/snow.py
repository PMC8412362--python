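"""Temperature-index snow accounting: rain/snow partition, SWE storage, degree-day melt.

Daily precipitation is split into rain and snowfall by a temperature ramp
centred on a (possibly spatially varying) 50 % partition temperature ``t50``;
accumulated SWE melts at a degree-day rate above a melt threshold.  All
functions broadcast over numpy arrays, so the same code serves single-site and
gridded runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SnowParams", "snow_fraction", "partition_precip", "melt", "step_snow"]


@dataclass
class SnowParams:
    """Parameters of the rain–snow partition and degree-day melt.

    t50 : °C at which precipitation falls half as snow (may be a per-cell grid).
    partition_width : half-width (°C) of the rain–snow transition; all snow at
        or below t50 − width, all rain at or above t50 + width.
    melt_factor : degree-day melt rate, mm per °C per day.
    melt_threshold : °C above which melt occurs.
    partition : "linear" (clamped ramp) or "logistic" (clamped, renormalised
        sigmoid) transition shape; both hit 1/0.5/0 at t50−width/t50/t50+width.
    """

    t50: float | np.ndarray = 1.0
    partition_width: float = 3.0
    melt_factor: float = 4.0
    melt_threshold: float = 0.0
    partition: str = "linear"

    def __post_init__(self):
        if np.any(np.asarray(self.partition_width) <= 0):
            raise ValueError("partition_width must be > 0")
        if np.any(np.asarray(self.melt_factor) < 0):
            raise ValueError("melt_factor must be >= 0")
        if self.partition not in ("linear", "logistic"):
            raise ValueError(f"unknown partition {self.partition!r}")


def snow_fraction(tmean, params: SnowParams = SnowParams()):
    """Fraction of precipitation falling as snow at daily mean temperature ``tmean``.

    Monotone non-increasing in temperature; exactly 1 at/below ``t50 - width``,
    0.5 at ``t50``, 0 at/above ``t50 + width``.
    """
    t = np.asarray(tmean, dtype=float)
    w = params.partition_width
    if params.partition == "linear":
        return np.clip((params.t50 + w - t) / (2.0 * w), 0.0, 1.0)
    # Logistic: sigmoid rescaled so the clamp points are met exactly.
    k = np.log(99.0) / w  # raw sigmoid reaches 0.99 one width below t50
    z = np.clip(t - params.t50, -w, w)
    g = 1.0 / (1.0 + np.exp(k * z))
    g_hi = 1.0 / (1.0 + np.exp(-k * w))   # value at t50 - w (0.99)
    g_lo = 1.0 - g_hi
    return np.clip((g - g_lo) / (g_hi - g_lo), 0.0, 1.0)


def partition_precip(precip, tmean, params: SnowParams = SnowParams()):
    """Split precipitation (mm) into (rain, snowfall); the two sum to precip exactly."""
    p = np.asarray(precip, dtype=float)
    if np.any(p[np.isfinite(p)] < 0):
        raise ValueError("precipitation must be non-negative")
    snowfall = p * snow_fraction(tmean, params)
    rain = p - snowfall
    return rain, snowfall


def melt(swe, tmean, params: SnowParams = SnowParams()):
    """Degree-day melt (mm) from a pack of ``swe`` mm at ``tmean`` °C, capped by SWE."""
    s = np.asarray(swe, dtype=float)
    t = np.asarray(tmean, dtype=float)
    potential = params.melt_factor * np.maximum(t - params.melt_threshold, 0.0)
    return np.minimum(s, potential)


def step_snow(state_swe, precip, tmean, params: SnowParams = SnowParams()):
    """Advance the snowpack one day.

    Same-day snowfall joins the pack before melt is computed.  Returns
    ``(new_swe, rain, snowfall, melt)``; the liquid water reaching the soil
    layer this day is ``rain + melt``.
    """
    rain, snowfall = partition_precip(precip, tmean, params)
    pack = np.asarray(state_swe, dtype=float) + snowfall
    m = melt(pack, tmean, params)
    return pack - m, rain, snowfall, m
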