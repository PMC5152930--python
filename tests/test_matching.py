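"""Premature-death filtering and replicated within-cell random matching."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mortcost.errors import ConfigurationError
from mortcost.matching import (
    MatchCellKey,
    MatchingError,
    age_band_index,
    build_cells,
    default_age_banding,
    filter_premature,
    match_replicate,
    run_replicates,
)


def _deaths(rows):
    return pd.DataFrame(rows, columns=["id", "year", "age", "sex", "ses_quintile"])


def _panel_year(rows):
    """Minimal single-year panel frame (2003 only)."""
    df = pd.DataFrame(rows, columns=["person_id", "age", "sex", "ses_quintile"])
    df["year"] = 2003
    df["alive"] = 1
    return df


class TestFilterPremature:
    @pytest.mark.parametrize("age,kept", [(0, True), (45, True), (79, True), (80, False), (95, False)])
    def test_boundary_at_age_80(self, age, kept):
        out = filter_premature(_deaths([("d", 2003, age, "M", 3)]))
        assert (len(out) == 1) is kept

    def test_empty_input(self):
        assert len(filter_premature(_deaths([]))) == 0

    def test_mixed_ages(self):
        ages = [0, 45, 79, 80, 95]
        out = filter_premature(
            _deaths([(f"d{a}", 2003, a, "F", 1) for a in ages])
        )
        assert sorted(out["age"]) == [0, 45, 79]


class TestBuildCells:
    def test_single_person_single_cell(self):
        cells = build_cells(_panel_year([("p1", 40, "M", 2)]))
        assert list(cells) == [MatchCellKey(8, "M", 2)]
        assert list(cells[MatchCellKey(8, "M", 2)]) == ["p1"]

    def test_identical_persons_share_a_cell(self):
        cells = build_cells(_panel_year([("p1", 40, "M", 2), ("p2", 42, "M", 2)]))
        assert len(cells) == 1
        assert sorted(cells[MatchCellKey(8, "M", 2)]) == ["p1", "p2"]

    def test_partition_conserves_alive_candidates(self):
        rng = np.random.default_rng(0)
        rows = [
            (f"p{i}", rng.integers(0, 80), rng.choice(["M", "F"]), rng.integers(1, 6))
            for i in range(500)
        ]
        panel = _panel_year(rows)
        panel.loc[panel.index[:50], "alive"] = 0
        cells = build_cells(panel)
        total = sum(len(v) for v in cells.values())
        assert total == 450
        all_ids = np.concatenate(list(cells.values()))
        assert len(all_ids) == len(set(all_ids))  # each person in exactly one cell

    def test_ages_outside_banding_excluded(self):
        cells = build_cells(_panel_year([("p1", 85, "F", 1)]))
        assert cells == {}


class TestMatchReplicate:
    def test_forced_choice_single_candidate(self):
        cells = build_cells(_panel_year([("p1", 40, "M", 2)]))
        deaths = _deaths([("d1", 2003, 41, "M", 2)])
        for seed in (0, 1, 99):
            a = match_replicate(deaths, cells, seed=seed)
            assert a.pairs == {"d1": "p1"}
            assert a.fallback_log == []

    def test_seeded_determinism(self):
        panel = _panel_year([(f"p{i}", 40 + (i % 5), "M", 2) for i in range(20)])
        cells = build_cells(panel)
        deaths = _deaths([(f"d{i}", 2003, 42, "M", 2) for i in range(10)])
        a = match_replicate(deaths, cells, seed=7)
        b = match_replicate(deaths, cells, seed=7)
        assert a.pairs == b.pairs

    def test_within_cell_draws_are_uniform(self):
        """10,000 seeded draws from a 4-candidate cell pass a chi-square
        uniformity test at alpha = 0.001."""
        panel = _panel_year([(f"p{i}", 40, "M", 2) for i in range(4)])
        cells = build_cells(panel)
        deaths = _deaths([(f"d{i:05d}", 2003, 41, "M", 2) for i in range(10_000)])
        a = match_replicate(deaths, cells, seed=12345)
        counts = pd.Series(list(a.pairs.values())).value_counts()
        chi2, p = stats.chisquare(counts.reindex([f"p{i}" for i in range(4)], fill_value=0))
        assert p > 0.001

    def test_fallback_ladder_order_and_logging(self):
        # no SES-3 candidates: adjacent quintile (level 1)
        cells = build_cells(_panel_year([("p1", 41, "M", 2)]))
        a = match_replicate(_deaths([("d1", 2003, 42, "M", 3)]), cells, seed=0)
        assert a.pairs == {"d1": "p1"} and a.fallback_log == [("d1", 1)]

        # only an adjacent age band has candidates (level 2)
        cells = build_cells(_panel_year([("p1", 47, "M", 3)]))
        a = match_replicate(_deaths([("d1", 2003, 42, "M", 3)]), cells, seed=0)
        assert a.pairs == {"d1": "p1"} and a.fallback_log == [("d1", 2)]

        # same band, SES far away: level 3 drops SES
        cells = build_cells(_panel_year([("p1", 41, "M", 5)]))
        a = match_replicate(_deaths([("d1", 2003, 42, "M", 1)]), cells, seed=0)
        assert a.pairs == {"d1": "p1"} and a.fallback_log == [("d1", 3)]

    def test_no_candidate_anywhere_is_hard_error(self):
        cells = build_cells(_panel_year([("p1", 41, "F", 3)]))
        with pytest.raises(MatchingError, match="d1"):
            match_replicate(_deaths([("d1", 2003, 42, "M", 3)]), cells, seed=0)


class TestRunReplicates:
    @pytest.fixture()
    def setup(self):
        rng = np.random.default_rng(1)
        panel = _panel_year(
            [
                (f"p{i}", rng.integers(0, 80), rng.choice(["M", "F"]), rng.integers(1, 6))
                for i in range(1000)
            ]
        )
        deaths = _deaths(
            [
                (f"d{i}", 2003, rng.integers(0, 80), rng.choice(["M", "F"]), rng.integers(1, 6))
                for i in range(100)
            ]
        )
        return deaths, build_cells(panel)

    def test_single_replicate_consistent_with_direct_call(self, setup):
        deaths, cells = setup
        [a] = run_replicates(deaths, cells, n_replicates=1, base_seed=55)
        b = match_replicate(deaths, cells, seed=55 ^ 0)
        assert a.pairs == b.pairs

    def test_replicates_complete_and_deterministic(self, setup):
        deaths, cells = setup
        runs = run_replicates(deaths, cells, n_replicates=20, base_seed=9)
        again = run_replicates(deaths, cells, n_replicates=20, base_seed=9)
        assert len(runs) == 20
        for a, b in zip(runs, again):
            assert len(a.pairs) == len(deaths)
            assert a.pairs == b.pairs
            assert a.seed == 9 ^ a.replicate_index

    def test_nonpositive_replicate_count_rejected(self, setup):
        deaths, cells = setup
        with pytest.raises(ConfigurationError):
            run_replicates(deaths, cells, n_replicates=0, base_seed=1)

    def test_matched_pairs_share_cell_key(self, setup):
        deaths, cells = setup
        banding = default_age_banding()
        person_cell = {
            str(p): key for key, pool in cells.items() for p in pool
        }
        for a in run_replicates(deaths, cells, n_replicates=5, base_seed=3):
            fallback_ids = {d for d, _ in a.fallback_log}
            for _, row in deaths.iterrows():
                if row["id"] in fallback_ids:
                    continue
                key = MatchCellKey(
                    int(age_band_index(row["age"], banding)[0]),
                    row["sex"],
                    int(row["ses_quintile"]),
                )
                assert person_cell[a.pairs[row["id"]]] == key
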