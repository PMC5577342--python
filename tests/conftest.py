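import datetime as dt

import pandas as pd
import pytest

import rhinocast as rc


@pytest.fixture(scope="session")
def study_spec():
    return rc.study_window_spec()


@pytest.fixture(scope="session")
def study_dataset(study_spec):
    """One seeded 4-year synthetic dataset: (meteo, visits, biweekly+cmp)."""
    meteo, visits = rc.generate_study_dataset(seed=0)
    biweekly = rc.build_biweekly(visits, meteo, study_spec)
    biweekly["cmp"] = rc.cmp_series(biweekly)
    return meteo, visits, biweekly


@pytest.fixture()
def constant_meteo():
    """Zero-noise, zero-amplitude meteorology: every variable constant."""
    params = rc.MeteoSimParams(
        n_days=92 * 14, tmin_annual_mean=0.0, tmin_annual_amplitude=0.0,
        vapour_mean=10.0, vapour_amplitude=0.0,
        slp_mean=1000.0, slp_amplitude=0.0,
        noise_sd={"tmin": 0.0, "vapour": 0.0, "slp": 0.0}, seed=0)
    return rc.generate_meteorology(params)


def make_visits(rows):
    return pd.DataFrame(rows, columns=["date", "group"])
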