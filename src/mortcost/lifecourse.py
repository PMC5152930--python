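"""Counterfactual life-course accumulation for matched decedents.

Under the human capital approach, each premature decedent is credited with
the life their matched panel person actually lives in the simulation: the
years of life lost (YLL) run from the death year to the matched person's
own (counterfactual) death year or the projection horizon, whichever
comes first; full-time-equivalent (FTE) working years accumulate the
matched person's weekly hours; and the annual real income stream feeds the
present-value calculation.

Conventions (documented, configurable where numeric):

* The death year itself counts as a full counterfactual year of potential
  work and income — matching happens at the start of the year.
* Income and hours in the matched person's *own* death year count as zero
  (death at the start of that year); the generated panel already encodes
  this, and the accumulation enforces it for user-supplied panels.
* An FTE working year is ``weekly_hours x weeks_per_year / H_std`` with
  ``weeks_per_year = 52`` and a standard working year of ``H_std = 1976``
  hours (38-hour standard week) by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError

__all__ = [
    "EconomicParams",
    "counterfactual_death_year",
    "counterfactual_yll",
    "working_years",
    "income_stream",
]


@dataclass(frozen=True)
class EconomicParams:
    """Economic parameters of the costing.

    wage_growth
        Real wage growth per annum (above inflation); default 1%.
    discount_rate
        Annual discount rate applied to future income; default 3%.
    base_year, horizon
        Present values are expressed at ``base_year`` prices/time (2003);
        nothing beyond ``horizon`` (2030) is counted.
    standard_annual_hours
        Hours in a standard full-time working year (1976 = 38 h x 52 wk).
    weeks_per_year
        Weeks used to annualise weekly hours.
    cpi_factor
        Multiplier taking base-year dollars to reporting-year dollars
        (1.0 for synthetic runs; user-supplied for real CPI series).
    """

    wage_growth: float = 0.01
    discount_rate: float = 0.03
    base_year: int = 2003
    horizon: int = 2030
    standard_annual_hours: float = 1976.0
    weeks_per_year: float = 52.0
    cpi_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.discount_rate <= -1 or self.wage_growth <= -1:
            raise ConfigurationError("rates must exceed -100%")
        if self.standard_annual_hours <= 0:
            raise ConfigurationError("standard_annual_hours must be > 0")
        if self.horizon < self.base_year:
            raise ConfigurationError("horizon must be >= base_year")
        if self.cpi_factor <= 0:
            raise ConfigurationError("cpi_factor must be > 0")


def _check_coverage(traj: pd.DataFrame, from_year: int, horizon: int) -> None:
    years = set(traj["year"])
    missing = [y for y in range(from_year, horizon + 1) if y not in years]
    if missing:
        raise DataError(
            f"trajectory does not cover years {missing[0]}..{missing[-1]}"
        )


def counterfactual_death_year(traj: pd.DataFrame) -> int | None:
    """First year the trajectory's alive flag is false; None if it never is."""
    dead = traj.loc[traj["alive"] == 0, "year"]
    return int(dead.min()) if len(dead) else None


def counterfactual_yll(death_year: int, traj: pd.DataFrame, horizon: int) -> float:
    """Years of life lost: min(counterfactual death year, horizon) - death year.

    A matched person surviving past the horizon contributes
    ``horizon - death_year``; one already dead in the death year
    contributes 0.
    """
    _check_coverage(traj, death_year, horizon)
    cf = counterfactual_death_year(traj)
    end = horizon if cf is None else min(cf, horizon)
    return float(max(0, end - death_year))


def _in_scope(traj: pd.DataFrame, from_year: int, horizon: int) -> pd.DataFrame:
    """Rows within [from_year, horizon] and before the counterfactual death
    year, i.e. the person-years that count towards the counterfactual."""
    cf = counterfactual_death_year(traj)
    end = horizon if cf is None else min(cf - 1, horizon)
    return traj[(traj["year"] >= from_year) & (traj["year"] <= end)]


def working_years(
    traj: pd.DataFrame,
    from_year: int,
    horizon: int,
    standard_annual_hours: float = 1976.0,
    weeks_per_year: float = 52.0,
) -> float:
    """FTE working years: accumulated hours / hours in a standard year."""
    if standard_annual_hours <= 0:
        raise ConfigurationError("standard_annual_hours must be > 0")
    scope = _in_scope(traj, from_year, horizon)
    total_hours = (scope["weekly_hours"] * weeks_per_year).sum()
    return float(total_hours / standard_annual_hours)


def income_stream(traj: pd.DataFrame, from_year: int, horizon: int) -> dict[int, float]:
    """Annual real income by year, zero in and after the counterfactual
    death year, truncated at the horizon."""
    _check_coverage(traj, from_year, horizon)
    scope = _in_scope(traj, from_year, horizon)
    return {int(y): float(v) for y, v in zip(scope["year"], scope["annual_income_real"])}
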