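import numpy as np
import pytest

from ecoclimex import (GridSpec, default_fornicatus_params,
                       generate_synthetic_region, run_suitability)

STUDY_SEED = 20170419
STUDY_SPEC = GridSpec(lon_origin=97.0, lat_origin=18.0, cell_size=0.5,
                      n_cols=50, n_rows=50)


@pytest.fixture(scope="session")
def params():
    return default_fornicatus_params()


@pytest.fixture(scope="session")
def study_spec():
    return STUDY_SPEC


@pytest.fixture(scope="session")
def current_grid():
    return generate_synthetic_region(STUDY_SPEC, STUDY_SEED, "current")


@pytest.fixture(scope="session")
def future_grid():
    return generate_synthetic_region(STUDY_SPEC, STUDY_SEED, "future")


@pytest.fixture(scope="session")
def current_suitability(current_grid, params):
    return run_suitability(current_grid, params)


@pytest.fixture(scope="session")
def future_suitability(future_grid, params):
    return run_suitability(future_grid, params)


def balanced_constant_climate(tavg, diurnal=10.0, rh=75.0):
    """Constant climate whose weekly rain exactly offsets evaporative demand,
    so the soil bucket holds its optimal initial level all year."""
    from ecoclimex.engine import DEFAULT_EVAP_K, DAYS_PER_WEEK, MonthlyClimate
    evap_week = max(0.0, DEFAULT_EVAP_K * tavg) * (1 - rh / 100.0) * DAYS_PER_WEEK
    precip_month = evap_week * 52.0 / 12.0
    return MonthlyClimate(tmax=[tavg + diurnal / 2] * 12,
                          tmin=[tavg - diurnal / 2] * 12,
                          precip=[precip_month] * 12,
                          rh09=[rh] * 12, rh15=[rh] * 12)
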