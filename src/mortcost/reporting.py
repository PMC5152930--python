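"""Replicate aggregation and report tables.

Outcomes are summarised in a fixed order: within each replicate the
per-person outcomes are summed over the stratum (age band, sex, cancer
site, or the grand total); the stratum's point estimate is then the mean
of the replicate totals and its 95% confidence interval the 2.5th and
97.5th percentiles across replicates (percentile method, linear
interpolation between order statistics).

Display rounding is round-half-up and display-only: shares are computed
from unrounded internals, percentages render as integers, monetary totals
in $ millions, per-death costs in whole $ thousands.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from . import published
from .errors import ConfigurationError, MortcostError
from .lifecourse import EconomicParams

__all__ = [
    "ReportConfig",
    "aggregate",
    "share_of_total",
    "per_death_cost",
    "scenario_savings",
    "round_half_up",
    "render_tables",
]

logger = logging.getLogger(__name__)

OUTCOME_COLUMNS = ("yll", "working_years", "pvli")


@dataclass
class ReportConfig:
    """Reporting configuration: age bands partitioning 0-79, CI level (%),
    and display units."""

    age_bands: list[tuple[str, int, int]] = field(
        default_factory=lambda: list(published.AGE_BANDS)
    )
    ci_level: float = 95.0
    currency_unit: str = "$M"

    def __post_init__(self) -> None:
        if not 0 < self.ci_level < 100:
            raise ConfigurationError("ci_level must be in (0, 100)")
        covered = sorted(
            (lo, hi) for _, lo, hi in self.age_bands
        )
        edges = [a for pair in covered for a in pair]
        if edges != sorted(edges) or covered[0][0] != 0 or covered[-1][1] != 79:
            raise ConfigurationError("age bands must partition ages 0-79")
        for (_, hi_prev), (lo_next, _) in zip(covered, covered[1:]):
            if lo_next != hi_prev + 1:
                raise ConfigurationError("age bands must partition ages 0-79")


def aggregate(
    outcomes: pd.DataFrame,
    by: list[str] | None = None,
    values: tuple[str, ...] = OUTCOME_COLUMNS,
    ci_level: float = 95.0,
) -> pd.DataFrame:
    """Aggregate per-person outcomes into stratum totals with percentile CIs.

    ``outcomes`` needs a ``replicate`` column plus the stratum and value
    columns. Strata absent from a replicate contribute 0 to that
    replicate's total. Returns one row per stratum x value with columns
    mean, ci_low, ci_high, n_replicates.
    """
    if by is None:
        by = []
    unknown = [c for c in by if c not in outcomes.columns]
    if unknown:
        raise ConfigurationError(f"unknown stratum column(s): {unknown}")
    if "replicate" not in outcomes.columns or outcomes["replicate"].nunique() == 0:
        raise ConfigurationError("outcomes must cover at least one replicate")

    replicates = np.sort(outcomes["replicate"].unique())
    work = outcomes.copy()
    if not by:
        work["_total"] = "total"
        by = ["_total"]

    per_rep = (
        work.groupby(["replicate", *by], sort=True)[list(values)].sum().reset_index()
    )
    # zero-fill strata missing from some replicates
    strata = per_rep[by].drop_duplicates()
    full_index = strata.merge(pd.DataFrame({"replicate": replicates}), how="cross")
    per_rep = full_index.merge(per_rep, on=["replicate", *by], how="left").fillna(0.0)

    alpha = (100.0 - ci_level) / 2.0
    rows = []
    for key, grp in per_rep.groupby(by, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        for value in values:
            arr = grp[value].to_numpy()
            rows.append(
                {
                    **dict(zip(by, key)),
                    "outcome": value,
                    "mean": float(arr.mean()),
                    "ci_low": float(np.percentile(arr, alpha)),
                    "ci_high": float(np.percentile(arr, 100.0 - alpha)),
                    "n_replicates": len(replicates),
                }
            )
    result = pd.DataFrame(rows)
    return result.drop(columns="_total", errors="ignore")


def share_of_total(part: float, total: float) -> float:
    """Percentage share 100*part/total (unrounded)."""
    if total <= 0:
        raise MortcostError("share_of_total: total must be positive")
    return 100.0 * part / total


def per_death_cost(total_pvli: float, n_deaths: int) -> float:
    """Average cost per death in the units of ``total_pvli``."""
    if n_deaths <= 0:
        raise MortcostError("per_death_cost: n_deaths must be positive")
    return total_pvli / n_deaths


def scenario_savings(
    site_total_pvli: float, reduction: float, horizon_years: int = 0
) -> tuple[float, float]:
    """Productivity savings from a sustained proportional mortality reduction.

    The annual saving is ``reduction x site_total_pvli``. Because the
    reduction is sustained, each further year adds a new persisting annual
    stream, so the cumulative saving over T years is
    ``annual x T(T+1)/2``.
    """
    if not 0 <= reduction <= 1:
        raise ConfigurationError("reduction must be in [0, 1]")
    if horizon_years < 0:
        raise ConfigurationError("horizon_years must be >= 0")
    annual = reduction * site_total_pvli
    cumulative = annual * horizon_years * (horizon_years + 1) / 2.0
    return annual, cumulative


def round_half_up(value: float, decimals: int = 0) -> float:
    """Round half away from zero on the decimal representation, so 81.5
    displays as 82 (float banker's rounding would give 81)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def _metadata_header(
    params: EconomicParams, seeds: dict[str, int], fallback_counts: dict[int, int]
) -> list[str]:
    lines = ["# mortcost report"]
    for k, v in vars(params).items():
        lines.append(f"# param {k} = {v}")
    for k, v in seeds.items():
        lines.append(f"# seed {k} = {v}")
    for level in sorted(fallback_counts):
        lines.append(f"# fallback level {level} matches = {fallback_counts[level]}")
    return lines


def _write_csv(path: Path, frame: pd.DataFrame, header: list[str]) -> None:
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        frame.to_csv(fh, index=False)


def render_tables(
    outcomes: pd.DataFrame,
    deaths: pd.DataFrame,
    params: EconomicParams,
    config: ReportConfig | None = None,
    out_dir: str | Path = ".",
    seeds: dict[str, int] | None = None,
    fallback_counts: dict[int, int] | None = None,
) -> dict[str, Path]:
    """Write the report tables as CSV files with a metadata header.

    Emits deaths/YLL by age band and sex, PVLI by age band and sex, the
    per-site burden table, and the stratified series behind the working
    years and top-sites figures. Returns the written paths by table name.
    """
    if config is None:
        config = ReportConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seeds = seeds or {}
    fallback_counts = fallback_counts or {}
    header = _metadata_header(params, seeds, fallback_counts)
    written: dict[str, Path] = {}

    if outcomes.empty:
        logger.warning("render_tables: empty outcome set; emitting zero tables")
        zero = pd.DataFrame(
            {"stratum": [], "mean": [], "ci_low": [], "ci_high": []}
        )
        for name in (
            "deaths_yll_by_age_sex",
            "pvli_by_age_sex",
            "site_burden",
            "working_years_by_age_sex",
            "top_sites_by_sex",
        ):
            path = out_dir / f"{name}.csv"
            _write_csv(path, zero, header)
            written[name] = path
        return written

    n_deaths_by = deaths.groupby(["age_band", "sex"]).size().rename("deaths")
    ci = config.ci_level

    # deaths and YLL by age band and sex
    t1 = aggregate(outcomes, ["age_band", "sex"], values=("yll",), ci_level=ci)
    t1 = t1.merge(n_deaths_by.reset_index(), on=["age_band", "sex"], how="left")
    written["deaths_yll_by_age_sex"] = out_dir / "deaths_yll_by_age_sex.csv"
    _write_csv(written["deaths_yll_by_age_sex"], t1, header)

    # PVLI by age band and sex, with display shares of total
    t2 = aggregate(outcomes, ["age_band", "sex"], values=("pvli",), ci_level=ci)
    grand = aggregate(outcomes, values=("pvli",), ci_level=ci)["mean"].iloc[0]
    t2["pct_of_total"] = [
        round_half_up(share_of_total(m, grand)) if grand > 0 else 0.0
        for m in t2["mean"]
    ]
    written["pvli_by_age_sex"] = out_dir / "pvli_by_age_sex.csv"
    _write_csv(written["pvli_by_age_sex"], t2, header)

    # per-site burden
    t3 = aggregate(
        outcomes, ["site"], values=("working_years", "pvli"), ci_level=ci
    )
    t3 = t3.pivot_table(
        index="site", columns="outcome", values=["mean", "ci_low", "ci_high"]
    )
    t3.columns = [f"{v}_{stat}" for stat, v in t3.columns]
    t3 = t3.reset_index()
    site_deaths = deaths.groupby("site").size().rename("deaths").reset_index()
    t3 = t3.merge(site_deaths, on="site", how="left")
    t3["pct_of_total_pvli"] = [
        round_half_up(share_of_total(m, grand), 1) if grand > 0 else 0.0
        for m in t3["pvli_mean"]
    ]
    t3["pvli_per_death"] = [
        round_half_up(per_death_cost(m, n)) if n > 0 else 0.0
        for m, n in zip(t3["pvli_mean"], t3["deaths"])
    ]
    t3 = t3.sort_values("pvli_mean", ascending=False)
    written["site_burden"] = out_dir / "site_burden.csv"
    _write_csv(written["site_burden"], t3, header)

    # figure series: working years by age band and sex; top sites by sex
    f2 = aggregate(outcomes, ["age_band", "sex"], values=("working_years",), ci_level=ci)
    written["working_years_by_age_sex"] = out_dir / "working_years_by_age_sex.csv"
    _write_csv(written["working_years_by_age_sex"], f2, header)

    f3 = aggregate(outcomes, ["sex", "site"], values=("pvli",), ci_level=ci)
    f3 = (
        f3.sort_values(["sex", "mean"], ascending=[True, False])
        .groupby("sex")
        .head(5)
        .reset_index(drop=True)
    )
    written["top_sites_by_sex"] = out_dir / "top_sites_by_sex.csv"
    _write_csv(written["top_sites_by_sex"], f3, header)
    return written
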