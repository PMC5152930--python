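"""YAML run configuration.

A run config is a mapping with up to three sections — ``mortality``,
``panel`` and ``economics`` — whose keys mirror the corresponding spec
dataclass fields (scalar fields only; full weight tables are set through
the Python API). All seeds are explicit in the config. Example::

    mortality:
      n_deaths: 2000
      year: 2003
      seed: 11
    panel:
      n_persons: 20000
      seed: 12
      wage_growth: 0.01
    economics:
      discount_rate: 0.03
      cpi_factor: 1.0
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .errors import ConfigurationError
from .lifecourse import EconomicParams
from .synthetic import MortalitySpec, PanelSpec

_MORTALITY_KEYS = {"n_deaths", "year", "ses_distribution", "seed"}
_PANEL_KEYS = {
    "n_persons",
    "start_year",
    "end_year",
    "initial_age_range",
    "part_time_share_by_sex",
    "part_time_hours",
    "full_time_hours",
    "wage_sigma",
    "wage_growth",
    "non_labour_income_fraction",
    "ses_distribution",
    "seed",
}
_ECON_KEYS = {
    "wage_growth",
    "discount_rate",
    "base_year",
    "horizon",
    "standard_annual_hours",
    "weeks_per_year",
    "cpi_factor",
}


def _section(raw: dict, name: str, allowed: set[str]) -> dict:
    section = raw.get(name, {}) or {}
    unknown = set(section) - allowed
    if unknown:
        raise ConfigurationError(f"config section {name}: unknown keys {sorted(unknown)}")
    for key in ("ses_distribution", "initial_age_range"):
        if key in section:
            section[key] = tuple(section[key])
    return section


def load_config(path: str | Path) -> dict:
    """Parse a YAML run config into spec objects.

    Returns {"mortality": MortalitySpec | None, "panel": PanelSpec | None,
    "economics": EconomicParams}.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError("config root must be a mapping")

    mort = _section(raw, "mortality", _MORTALITY_KEYS)
    panel = _section(raw, "panel", _PANEL_KEYS)
    econ = _section(raw, "economics", _ECON_KEYS)

    result = {
        "mortality": MortalitySpec(**mort) if mort else None,
        "panel": PanelSpec(**panel) if panel else None,
        "economics": EconomicParams(**econ),
    }
    for spec in (result["mortality"], result["panel"]):
        if spec is not None:
            spec.validate()
    return result
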