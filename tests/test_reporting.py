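"""Replicate aggregation, shares, per-death costs, scenarios, rendering."""

import numpy as np
import pandas as pd
import pytest

from mortcost import published
from mortcost.errors import ConfigurationError, MortcostError
from mortcost.lifecourse import EconomicParams
from mortcost.reporting import (
    ReportConfig,
    aggregate,
    per_death_cost,
    render_tables,
    round_half_up,
    scenario_savings,
    share_of_total,
)


def outcomes_frame(rows):
    return pd.DataFrame(
        rows, columns=["replicate", "death_id", "site", "age_band", "sex", "yll", "working_years", "pvli"]
    )


class TestAggregate:
    def test_single_replicate_degenerate_ci(self):
        out = outcomes_frame([(0, "d1", "Lung cancer", "45-54", "M", 10, 5, 1e5)])
        agg = aggregate(out)
        assert (agg["ci_low"] == agg["mean"]).all()
        assert (agg["ci_high"] == agg["mean"]).all()

    def test_stratum_totals_sum_to_grand_total(self):
        rng = np.random.default_rng(3)
        rows = [
            (r, f"d{i}", rng.choice(["Lung cancer", "Melanoma"]),
             rng.choice(["45-54", "55-64"]), rng.choice(["M", "F"]),
             rng.uniform(0, 30), rng.uniform(0, 10), rng.uniform(0, 1e6))
            for r in range(5)
            for i in range(40)
        ]
        out = outcomes_frame(rows)
        total = aggregate(out, values=("pvli",))["mean"].iloc[0]
        by_sex = aggregate(out, ["sex"], values=("pvli",))["mean"].sum()
        by_site_band = aggregate(out, ["site", "age_band"], values=("pvli",))["mean"].sum()
        assert by_sex == pytest.approx(total, abs=1e-6)
        assert by_site_band == pytest.approx(total, abs=1e-6)

    def test_percentile_interval_matches_order_statistics(self):
        """Replicate totals 1..100: the 95% percentile interval under
        linear interpolation is [3.475, 97.525] — verified against a
        direct order-statistics computation."""
        rows = [(r, "d1", "Lung cancer", "45-54", "M", 0.0, 0.0, float(r + 1)) for r in range(100)]
        agg = aggregate(outcomes_frame(rows), values=("pvli",))
        # oracle: with sorted values x_1..x_n, the q-th percentile sits at
        # rank 1 + q(n-1)/100 and interpolates linearly between neighbours
        x = np.arange(1.0, 101.0)
        rank = 2.5 * (100 - 1) / 100  # zero-based fractional rank
        lo = x[int(rank)] + (rank - int(rank)) * (x[int(rank) + 1] - x[int(rank)])
        rank_hi = 97.5 * (100 - 1) / 100
        hi = x[int(rank_hi)] + (rank_hi - int(rank_hi)) * (x[int(rank_hi) + 1] - x[int(rank_hi)])
        assert agg["ci_low"].iloc[0] == pytest.approx(lo)
        assert agg["ci_high"].iloc[0] == pytest.approx(hi)
        assert (lo, hi) == (pytest.approx(3.475), pytest.approx(97.525))

    def test_missing_stratum_counts_as_zero(self):
        rows = [
            (0, "d1", "Lung cancer", "45-54", "M", 0, 0, 100.0),
            (1, "d1", "Melanoma", "45-54", "M", 0, 0, 60.0),
        ]
        agg = aggregate(outcomes_frame(rows), ["site"], values=("pvli",))
        lung = agg[agg["site"] == "Lung cancer"]
        assert lung["mean"].iloc[0] == pytest.approx(50.0)  # (100 + 0) / 2

    def test_unknown_stratum_key_rejected(self):
        out = outcomes_frame([(0, "d1", "Lung cancer", "45-54", "M", 1, 1, 1)])
        with pytest.raises(ConfigurationError):
            aggregate(out, ["nope"])

    def test_ci_coverage_of_replicate_distribution(self):
        """For normal replicate totals the percentile interval spans close
        to the central 95% of the replicate distribution."""
        rng = np.random.default_rng(12)
        draws = rng.normal(1000.0, 50.0, size=2000)
        rows = [(r, "d1", "s", "b", "M", 0.0, 0.0, float(v)) for r, v in enumerate(draws)]
        agg = aggregate(outcomes_frame(rows), values=("pvli",))
        inside = ((draws >= agg["ci_low"].iloc[0]) & (draws <= agg["ci_high"].iloc[0])).mean()
        assert inside == pytest.approx(0.95, abs=0.005)


class TestRatios:
    @pytest.mark.parametrize(
        "part,total,pct",
        [(15_051, 25_733, 58), (3_128, 4_200, 74), (7, 7, 100)],
    )
    def test_share_of_total_display_values(self, part, total, pct):
        assert round_half_up(share_of_total(part, total)) == pct

    def test_share_requires_positive_total(self):
        with pytest.raises(MortcostError):
            share_of_total(1, 0)

    @pytest.mark.parametrize(
        "pvli_m,n,cost_k",
        [(4_200, 25_733, 163), (765, 5_746, 133), (0, 10, 0)],
    )
    def test_per_death_cost_in_thousands(self, pvli_m, n, cost_k):
        # $ millions over deaths -> $000s per death
        assert round_half_up(per_death_cost(pvli_m * 1000.0, n)) == cost_k

    def test_per_death_cost_requires_deaths(self):
        with pytest.raises(MortcostError):
            per_death_cost(1.0, 0)

    def test_scenario_savings_compound_arithmetic(self):
        annual, cum = scenario_savings(765.0, 0.02, horizon_years=10)
        assert annual == pytest.approx(15.3)
        assert cum == pytest.approx(841.5)
        assert scenario_savings(765.0, 0.0, 10) == (0.0, 0.0)

    def test_round_half_up_convention(self):
        assert round_half_up(81.5) == 82
        assert round_half_up(58.49) == 58
        assert round_half_up(0.25, 1) == 0.3


class TestRenderTables:
    @pytest.fixture()
    def rendered(self, tmp_path):
        rng = np.random.default_rng(4)
        sites = ["Lung cancer", "Melanoma", "Breast cancer"]
        rows = [
            (r, f"d{i}", sites[i % 3], published.AGE_BANDS[i % 7][0],
             "M" if i % 2 else "F",
             rng.uniform(0, 30), rng.uniform(0, 10), rng.uniform(0, 1e6))
            for r in range(10)
            for i in range(30)
        ]
        outcomes = outcomes_frame(rows)
        deaths = outcomes[outcomes["replicate"] == 0][
            ["death_id", "site", "age_band", "sex"]
        ].rename(columns={"death_id": "id"})
        paths = render_tables(
            outcomes, deaths, EconomicParams(), out_dir=tmp_path,
            seeds={"base_seed": 1}, fallback_counts={1: 2},
        )
        return outcomes, deaths, paths

    def test_rerun_is_byte_identical(self, rendered, tmp_path):
        outcomes, deaths, paths = rendered
        other = tmp_path / "again"
        paths2 = render_tables(
            outcomes, deaths, EconomicParams(), out_dir=other,
            seeds={"base_seed": 1}, fallback_counts={1: 2},
        )
        for name in paths:
            assert paths[name].read_bytes() == paths2[name].read_bytes()

    def test_metadata_header_records_parameters(self, rendered):
        _, _, paths = rendered
        text = paths["site_burden"].read_text()
        assert "# param discount_rate = 0.03" in text
        assert "# seed base_seed = 1" in text
        assert "# fallback level 1 matches = 2" in text

    def test_percent_column_sums_to_100_with_rounding_slack(self, rendered):
        _, _, paths = rendered
        t2 = pd.read_csv(paths["pvli_by_age_sex"], comment="#")
        assert t2["pct_of_total"].sum() == pytest.approx(100, abs=3)

    def test_empty_outcomes_yield_zero_tables(self, tmp_path, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            paths = render_tables(
                outcomes_frame([]), pd.DataFrame(columns=["id", "site", "age_band", "sex"]),
                EconomicParams(), out_dir=tmp_path,
            )
        assert any("empty" in r.message for r in caplog.records)
        assert paths["site_burden"].exists()


def test_report_config_band_partition_validation():
    with pytest.raises(ConfigurationError):
        ReportConfig(age_bands=[("<50", 0, 49), ("51-79", 51, 79)])
    with pytest.raises(ConfigurationError):
        ReportConfig(ci_level=0)
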