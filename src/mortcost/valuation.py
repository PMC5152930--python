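"""Present-value calculation for real income streams.

The present value of lifetime income (PVLI) applies real wage growth g to
the modelled real income stream and discounts at rate r, i.e. year t
(counted from the base year, exponent 0 for the base year itself)
contributes ``income_t * ((1+g)/(1+r))**t``. Growth composes on the real
stream and discounting on the grown stream — the conventional order; with
g = r the PVLI equals the plain sum of the real stream.

Inflation to reporting-year dollars is a single scalar CPI factor applied
after present-valuing.
"""

from __future__ import annotations

from .errors import ConfigurationError, DataError
from .lifecourse import EconomicParams

__all__ = ["present_value", "inflate_to_reporting", "net_discount_factor"]


def net_discount_factor(params: EconomicParams, years_ahead: int) -> float:
    """((1+g)/(1+r)) ** years_ahead."""
    return ((1.0 + params.wage_growth) / (1.0 + params.discount_rate)) ** years_ahead


def present_value(stream: dict[int, float], params: EconomicParams) -> float:
    """Present value at the base year of an annual real income stream.

    ``stream`` maps calendar year to real income at base-year prices.
    Years before the base year are a domain error; the base year itself
    enters undiscounted (exponent zero, end-of-period convention).
    """
    total = 0.0
    for year, value in stream.items():
        if year < params.base_year:
            raise DataError(
                f"stream year {year} precedes base year {params.base_year}"
            )
        total += value * net_discount_factor(params, year - params.base_year)
    return total


def inflate_to_reporting(value: float, cpi_factor: float) -> float:
    """Scale a base-year-dollar value to reporting-year dollars."""
    if cpi_factor <= 0:
        raise ConfigurationError("cpi_factor must be > 0")
    return value * cpi_factor
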