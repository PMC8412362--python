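"""Independent scalar oracles, coded separately from the package.

Everything here is written with the stdlib ``math`` module and explicit
per-day Python loops so it shares no code path with the vectorised
implementation it checks.
"""

import math


def declination_ref(doy: int) -> float:
    return 0.409 * math.sin(2.0 * math.pi * doy / 365.0 - 1.39)


def ra_closed_form_ref(lat_deg: float, doy: int) -> float:
    """FAO-56 closed form, scalar math re-derivation."""
    lat = math.radians(lat_deg)
    decl = declination_ref(doy)
    dr = 1.0 + 0.033 * math.cos(2.0 * math.pi * doy / 365.0)
    cos_ws = max(-1.0, min(1.0, -math.tan(lat) * math.tan(decl)))
    ws = math.acos(cos_ws)
    ra = (24.0 * 60.0 / math.pi) * 0.0820 * dr * (
        ws * math.sin(lat) * math.sin(decl)
        + math.cos(lat) * math.cos(decl) * math.sin(ws))
    return max(ra, 0.0)


def ra_numeric_ref(lat_deg: float, doy: int, n: int = 200_000) -> float:
    """Daily top-of-atmosphere radiation by brute-force time integration.

    Integrates the instantaneous horizontal extraterrestrial irradiance
    Gsc * dr * cos(theta_z) over the day (trapezoid over hour angle), clamping
    the night side to zero.  MJ m^-2 day^-1.
    """
    lat = math.radians(lat_deg)
    decl = declination_ref(doy)
    dr = 1.0 + 0.033 * math.cos(2.0 * math.pi * doy / 365.0)
    gsc = 0.0820  # MJ m^-2 min^-1
    minutes_per_radian = 24.0 * 60.0 / (2.0 * math.pi)
    total = 0.0
    dw = 2.0 * math.pi / n
    prev = None
    for i in range(n + 1):
        w = -math.pi + i * dw
        cz = (math.sin(lat) * math.sin(decl)
              + math.cos(lat) * math.cos(decl) * math.cos(w))
        g = gsc * dr * max(cz, 0.0)
        if prev is not None:
            total += 0.5 * (g + prev) * dw * minutes_per_radian
        prev = g
    return total


def oudin_pet_ref(ra: float, tmean: float) -> float:
    if tmean + 5.0 <= 0.0:
        return 0.0
    return max(ra / 2.45 * (tmean + 5.0) / 100.0, 0.0)


def heat_load_ref(lat_deg: float, slope_deg: float, aspect_deg: float) -> float:
    """McCune–Keon-style heat load, folded aspect, normalised to flat = 1."""
    lat = math.radians(min(abs(lat_deg), 60.0))
    slope = math.radians(slope_deg)
    folded = math.radians(abs(180.0 - abs(aspect_deg - 225.0)))
    ln_hl = (0.339 + 0.808 * math.cos(lat) * math.cos(slope)
             - 0.196 * math.sin(lat) * math.sin(slope)
             - 0.482 * math.cos(folded) * math.sin(slope))
    ln_flat = 0.339 + 0.808 * math.cos(lat)
    return math.exp(ln_hl - ln_flat)


def tm_bucket_ref(tmins, tmaxs, precips, doys, lat_deg, whc,
                  soil0=None):
    """Scalar Thornthwaite–Mather bucket with Oudin PET, no snow, no canopy.

    Daily sequence: PET from temperature; supply (all precipitation as rain)
    meets demand first; surplus recharges the bucket up to WHC and spills as
    runoff; shortfall draws the bucket down the exponential drying curve.

    Returns dict of per-day lists: pet, aet, cwd, soil, runoff.
    """
    soil = whc if soil0 is None else soil0
    out = {k: [] for k in ("pet", "aet", "cwd", "soil", "runoff")}
    for tmn, tmx, p, j in zip(tmins, tmaxs, precips, doys):
        tmean = (tmn + tmx) / 2.0
        pet = oudin_pet_ref(ra_closed_form_ref(lat_deg, j), tmean)
        if p >= pet:
            aet = pet
            recharge = p - pet
            filled = soil + recharge
            runoff = max(filled - whc, 0.0)
            soil = min(filled, whc)
        else:
            unmet = pet - p
            extraction = soil * -math.expm1(-unmet / whc)
            aet = p + extraction
            soil = soil - extraction
            runoff = 0.0
        out["pet"].append(pet)
        out["aet"].append(aet)
        out["cwd"].append(max(pet - aet, 0.0))
        out["soil"].append(soil)
        out["runoff"].append(runoff)
    return out


def ols_ref(xs, ys):
    """Slope/intercept by explicit normal equations (sums form)."""
    n = len(xs)
    sx = sum(xs)
    sy = sum(ys)
    sxx = sum(x * x for x in xs)
    sxy = sum(x * y for x, y in zip(xs, ys))
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    return slope, intercept
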