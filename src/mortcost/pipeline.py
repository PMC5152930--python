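"""End-to-end costing pipeline.

Chains the stages: identify premature cancer deaths, index the panel into
matching cells, draw R seeded matching replicates, and accumulate each
matched decedent's counterfactual years of life lost, FTE working years
and present value of lifetime income (PVLI) to the horizon.

The accumulation here is a vectorised equivalent of the per-trajectory
functions in :mod:`mortcost.lifecourse`: person-year contributions are
laid out as (person x year) matrices, prefix-summed along years, and each
decedent's outcome read off from the matched person's row at the death
year. The per-trajectory path is retained as the reference semantics and
the two are cross-checked in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import published
from .errors import DataError
from .lifecourse import EconomicParams
from .matching import (
    MatchAssignment,
    assignments_to_frame,
    build_cells,
    default_age_banding,
    filter_premature,
    run_replicates,
)
from .sites import SiteMap, classify_site, default_site_map, is_cancer_death
from .valuation import net_discount_factor

__all__ = ["PipelineResult", "reporting_age_band", "prepare_deaths", "compute_outcomes", "run_pipeline"]


def reporting_age_band(ages: np.ndarray | pd.Series) -> np.ndarray:
    """Label each age with its reporting band (<15 ... 65-80)."""
    ages = np.asarray(ages, dtype=int)
    out = np.empty(len(ages), dtype=object)
    for band, lo, hi in published.AGE_BANDS:
        out[(ages >= lo) & (ages <= hi)] = band
    return out


def prepare_deaths(
    records: pd.DataFrame, site_map: SiteMap | None = None
) -> pd.DataFrame:
    """Premature cancer deaths with site and reporting age band attached.

    Keeps records whose ICD-10 underlying cause is in C00-C97 and whose
    age at death is below 80; classifies the site if absent.
    """
    if site_map is None:
        site_map = default_site_map()
    cancer = records[records["icd10"].map(is_cancer_death)].copy()
    premature = filter_premature(cancer)
    if "site" not in premature.columns:
        premature["site"] = [
            classify_site(c, site_map) for c in premature["icd10"]
        ]
    premature["age_band"] = reporting_age_band(premature["age"])
    return premature


@dataclass
class _PanelArrays:
    """Panel pivoted to per-person arrays over base_year..horizon."""

    person_index: dict[str, int]
    years: np.ndarray
    cf_death_offset: np.ndarray  # first year-offset with alive == 0; T if never
    wy_prefix: np.ndarray  # prefix sums of FTE-year contributions
    pv_prefix: np.ndarray  # prefix sums of discounted income contributions


def _pivot_panel(panel: pd.DataFrame, params: EconomicParams) -> _PanelArrays:
    years = np.arange(params.base_year, params.horizon + 1)
    window = panel[(panel["year"] >= params.base_year) & (panel["year"] <= params.horizon)]
    covered = window.groupby("person_id")["year"].nunique()
    if (covered < len(years)).any():
        bad = covered.index[covered < len(years)][0]
        raise DataError(
            f"panel person {bad} does not cover {params.base_year}..{params.horizon}"
        )

    def mat(col: str) -> np.ndarray:
        return (
            window.pivot_table(index="person_id", columns="year", values=col, sort=True)
            .reindex(columns=years)
            .to_numpy()
        )

    alive = mat("alive") > 0
    hours = mat("weekly_hours")
    income = mat("annual_income_real")
    person_ids = np.sort(window["person_id"].unique())

    T = len(years)
    # first offset with alive False; T for survivors past the horizon
    dead_any = ~alive
    cf_off = np.where(dead_any.any(axis=1), dead_any.argmax(axis=1), T)

    # person-years in and after the counterfactual death year contribute 0
    # (enforced here so user-supplied panels follow the same convention)
    hours = np.where(alive, hours, 0.0)
    income = np.where(alive, income, 0.0)

    wy_contrib = hours * params.weeks_per_year / params.standard_annual_hours
    factors = np.array(
        [net_discount_factor(params, t) for t in range(T)]
    )
    pv_contrib = income * factors[None, :]

    return _PanelArrays(
        person_index={p: i for i, p in enumerate(person_ids)},
        years=years,
        cf_death_offset=cf_off,
        wy_prefix=np.cumsum(wy_contrib, axis=1),
        pv_prefix=np.cumsum(pv_contrib, axis=1),
    )


def compute_outcomes(
    deaths: pd.DataFrame,
    panel: pd.DataFrame,
    assignments: list[MatchAssignment],
    params: EconomicParams | None = None,
) -> pd.DataFrame:
    """Per-decedent, per-replicate counterfactual outcomes.

    Returns one row per (replicate, decedent) with yll (years),
    working_years (FTE years) and pvli (reporting-year dollars, i.e.
    present value at the base year scaled by the CPI factor).
    """
    if params is None:
        params = EconomicParams()
    arrays = _pivot_panel(panel, params)
    T = len(arrays.years)
    H_off = T - 1

    if "age_band" not in deaths.columns:
        deaths = deaths.assign(age_band=reporting_age_band(deaths["age"]))
    death_order = deaths.sort_values("id").reset_index(drop=True)
    d_off = death_order["year"].to_numpy() - params.base_year
    if (d_off < 0).any() or (d_off > H_off).any():
        raise DataError("death year outside base_year..horizon")

    frames = []
    for a in assignments:
        persons = death_order["id"].map(a.pairs)
        if persons.isna().any():
            missing = death_order.loc[persons.isna(), "id"].iloc[0]
            raise DataError(f"replicate {a.replicate_index}: no match for {missing}")
        p_idx = persons.map(arrays.person_index).to_numpy()

        cf = arrays.cf_death_offset[p_idx]
        yll = np.maximum(0, np.minimum(cf, H_off) - d_off)

        # outcome from death year d to horizon: total minus prefix before d
        before = np.where(d_off > 0, d_off - 1, 0)
        wy_total = arrays.wy_prefix[p_idx, H_off]
        wy_before = np.where(d_off > 0, arrays.wy_prefix[p_idx, before], 0.0)
        pv_total = arrays.pv_prefix[p_idx, H_off]
        pv_before = np.where(d_off > 0, arrays.pv_prefix[p_idx, before], 0.0)

        frames.append(
            pd.DataFrame(
                {
                    "replicate": a.replicate_index,
                    "death_id": death_order["id"],
                    "person_id": persons,
                    "site": death_order["site"],
                    "age_band": death_order["age_band"],
                    "sex": death_order["sex"],
                    "ses_quintile": death_order["ses_quintile"],
                    "yll": yll.astype(float),
                    "working_years": wy_total - wy_before,
                    "pvli": (pv_total - pv_before) * params.cpi_factor,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


@dataclass
class PipelineResult:
    """Everything a report needs: the premature cancer cohort, the raw
    matching assignments, and the per-decedent outcomes."""

    deaths: pd.DataFrame
    assignments: list[MatchAssignment]
    outcomes: pd.DataFrame
    params: EconomicParams

    @property
    def assignment_frame(self) -> pd.DataFrame:
        return assignments_to_frame(self.assignments)

    @property
    def fallback_counts(self) -> dict[int, int]:
        counts: dict[int, int] = {}
        for a in self.assignments:
            for _, level in a.fallback_log:
                counts[level] = counts.get(level, 0) + 1
        return counts


def run_pipeline(
    mortality: pd.DataFrame,
    panel: pd.DataFrame,
    n_replicates: int = 100,
    base_seed: int = 0,
    params: EconomicParams | None = None,
    site_map: SiteMap | None = None,
    banding: list[tuple[int, int]] | None = None,
) -> PipelineResult:
    """Run the full costing: filter, match R times, accumulate, value."""
    if params is None:
        params = EconomicParams()
    if banding is None:
        banding = default_age_banding()
    deaths = prepare_deaths(mortality, site_map)
    cells = build_cells(panel, banding, match_year=params.base_year)
    assignments = run_replicates(deaths, cells, n_replicates, base_seed, banding)
    outcomes = compute_outcomes(deaths, panel, assignments, params)
    return PipelineResult(
        deaths=deaths, assignments=assignments, outcomes=outcomes, params=params
    )
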