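import numpy as np
import pandas as pd
import pytest

from mortcost import EconomicParams, MortalitySpec, PanelSpec
from mortcost.synthetic import generate_mortality_dataset, generate_population_panel


@pytest.fixture(scope="session")
def small_deaths() -> pd.DataFrame:
    """300 synthetic 2003 cancer deaths with published default marginals."""
    return generate_mortality_dataset(MortalitySpec(n_deaths=300, seed=101))


@pytest.fixture(scope="session")
def small_panel() -> pd.DataFrame:
    """2,000-person life-course panel, 2003-2030, default labour structure."""
    return generate_population_panel(PanelSpec(n_persons=2000, seed=202))


@pytest.fixture(scope="session")
def params() -> EconomicParams:
    return EconomicParams()


def brute_force_outcomes(death_year, traj, params):
    """Independent per-person-year enumeration of yll, FTE working years
    and PVLI for one matched trajectory (plain Python loops; the oracle
    against which the vectorised pipeline is checked)."""
    rows = sorted(traj.to_dict("records"), key=lambda r: r["year"])
    cf_year = None
    for r in rows:
        if not r["alive"]:
            cf_year = r["year"]
            break
    end = params.horizon if cf_year is None else min(cf_year, params.horizon)
    yll = max(0, end - death_year)

    wy = 0.0
    pv = 0.0
    net = (1.0 + params.wage_growth) / (1.0 + params.discount_rate)
    for r in rows:
        y = r["year"]
        if y < death_year or y > params.horizon:
            continue
        if cf_year is not None and y >= cf_year:
            continue
        wy += r["weekly_hours"] * params.weeks_per_year / params.standard_annual_hours
        pv += r["annual_income_real"] * net ** (y - params.base_year)
    return yll, wy, pv * params.cpi_factor
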