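import numpy as np
import pytest

import waterbal as wb


def make_site_forcing(n_days, start=(2000, 1, 1), calendar="noleap",
                      tmean=10.0, amp=10.0, precip=None, seed=0):
    """Small helper: sinusoidal single-site forcing with optional fixed precip."""
    idx = wb.DailyIndex.date_range(start, n_days, calendar)
    doy = idx.day_of_year
    t = tmean + amp * np.cos(2 * np.pi * (doy - 200) / 365.0)
    if precip is None:
        rng = np.random.default_rng(seed)
        precip = (rng.random(n_days) < 0.3) * rng.gamma(0.8, 6.0, n_days)
    else:
        precip = np.broadcast_to(np.asarray(precip, float), (n_days,)).copy()
    return wb.ForcingSeries(idx, t - 5.0, t + 5.0, precip)


def series_to_stacks(series: wb.ForcingSeries):
    n = len(series)
    idx = series.index
    return {
        "tmin": wb.GridStack("tmin", series.tmin.reshape(n, 1, 1), idx, units="degC"),
        "tmax": wb.GridStack("tmax", series.tmax.reshape(n, 1, 1), idx, units="degC"),
        "prcp": wb.GridStack("prcp", series.precip.reshape(n, 1, 1), idx, units="mm"),
    }


@pytest.fixture(scope="session")
def scenario_runs():
    """One seeded 40-year run of each named scenario, shared across tests."""
    out = {}
    for name in wb.SCENARIOS:
        bundle = wb.make_scenario(name, seed=1)
        result = wb.run(bundle.forcing, bundle.attributes, bundle.params,
                        variables=("pet", "aet", "cwd", "soil_water", "swe",
                                   "runoff"))
        annual = wb.annual_totals(
            {k: result.outputs[k] for k in ("aet", "cwd", "runoff")})
        out[name] = (bundle, result, annual)
    return out
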