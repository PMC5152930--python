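"""Counterfactual matching of decedents to panel persons.

Each premature cancer decedent is matched, at random and with replacement,
to a panel person alive in the matching year who shares the decedent's
(age category, sex, SES quintile) cell. Matching is replicated R times
with independent seeds (replicate r uses ``base_seed ^ r``; the XOR
derivation is part of the public contract so runs reproduce across
machines) and downstream results are summarised across replicates.

With a 1% population sample, a cell can be empty. A fixed relaxation
ladder is then applied and logged, preserving the strongest predictors of
labour-market outcomes (age, sex) longest:

1. merge adjacent SES quintiles (quintile +/- 1);
2. additionally widen the age category by one band (+/- 5 years);
3. drop SES entirely (match on age band and sex alone).

If even the final rung yields no candidate, matching fails loudly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError

__all__ = [
    "MatchCellKey",
    "MatchAssignment",
    "MatchingError",
    "default_age_banding",
    "age_band_index",
    "filter_premature",
    "build_cells",
    "match_replicate",
    "run_replicates",
    "assignments_to_frame",
]

PREMATURE_AGE_LIMIT = 80  # a premature death occurs before this age


class MatchingError(RuntimeError):
    """No candidate available for a decedent even after full relaxation."""


@dataclass(frozen=True)
class MatchCellKey:
    """Matching stratum: age band index x sex x SES quintile."""

    age_band: int
    sex: str
    ses_quintile: int


@dataclass
class MatchAssignment:
    """One replicate's decedent -> panel person map.

    ``fallback_log`` records (death_id, relaxation level) for every pair
    that required the relaxation ladder (level 1-3 as documented above);
    level 0 pairs matched in their own cell and are not logged.
    """

    replicate_index: int
    seed: int
    pairs: dict[str, str]
    fallback_log: list[tuple[str, int]] = field(default_factory=list)


def default_age_banding() -> list[tuple[int, int]]:
    """5-year matching bands 0-4 ... 75-79 (finer than the reporting bands)."""
    return [(lo, lo + 4) for lo in range(0, PREMATURE_AGE_LIMIT, 5)]


def age_band_index(age: np.ndarray | int, banding: list[tuple[int, int]]) -> np.ndarray:
    """Index of the band containing each age; -1 if outside all bands."""
    ages = np.atleast_1d(np.asarray(age, dtype=int))
    out = np.full(len(ages), -1, dtype=int)
    for i, (lo, hi) in enumerate(banding):
        out[(ages >= lo) & (ages <= hi)] = i
    return out


def filter_premature(records: pd.DataFrame) -> pd.DataFrame:
    """Retain exactly the deaths at ages below 80."""
    return records[records["age"] < PREMATURE_AGE_LIMIT].reset_index(drop=True)


def build_cells(
    panel: pd.DataFrame,
    banding: list[tuple[int, int]] | None = None,
    match_year: int | None = None,
) -> dict[MatchCellKey, np.ndarray]:
    """Index panel persons alive in the matching year by matching cell.

    ``panel`` is the long person-year frame; candidates are the rows of
    ``match_year`` (default: the panel's first year) with alive == 1.
    Persons whose age falls outside the banding (e.g. 80+) are not
    candidates, matching the premature-death scope of the analysis.
    """
    if banding is None:
        banding = default_age_banding()
    if match_year is None:
        match_year = int(panel["year"].min())
    base = panel[(panel["year"] == match_year) & (panel["alive"] == 1)]
    bands = age_band_index(base["age"].to_numpy(), banding)
    cells: dict[MatchCellKey, np.ndarray] = {}
    keyframe = pd.DataFrame(
        {
            "band": bands,
            "sex": base["sex"].to_numpy(),
            "ses": base["ses_quintile"].to_numpy(),
            "person_id": base["person_id"].to_numpy(),
        }
    )
    for (band, sex, ses), grp in keyframe[keyframe["band"] >= 0].groupby(
        ["band", "sex", "ses"], sort=True
    ):
        cells[MatchCellKey(int(band), str(sex), int(ses))] = np.sort(
            grp["person_id"].to_numpy()
        )
    return cells


def _candidates_with_fallback(
    key: MatchCellKey,
    cells: dict[MatchCellKey, np.ndarray],
    n_bands: int,
) -> tuple[np.ndarray, int]:
    """Candidate pool and the relaxation level (0-3) that produced it."""
    pool = cells.get(key)
    if pool is not None and len(pool):
        return pool, 0
    # level 1: adjacent SES quintiles
    level1 = [
        cells.get(MatchCellKey(key.age_band, key.sex, q))
        for q in (key.ses_quintile - 1, key.ses_quintile, key.ses_quintile + 1)
        if 1 <= q <= 5
    ]
    merged = np.concatenate([p for p in level1 if p is not None and len(p)] or [[]])
    if len(merged):
        return np.sort(merged), 1
    # level 2: widen age band by one on either side, SES still merged
    level2 = [
        cells.get(MatchCellKey(b, key.sex, q))
        for b in (key.age_band - 1, key.age_band, key.age_band + 1)
        if 0 <= b < n_bands
        for q in (key.ses_quintile - 1, key.ses_quintile, key.ses_quintile + 1)
        if 1 <= q <= 5
    ]
    merged = np.concatenate([p for p in level2 if p is not None and len(p)] or [[]])
    if len(merged):
        return np.sort(merged), 2
    # level 3: drop SES, own age band and sex only
    level3 = [
        cells.get(MatchCellKey(key.age_band, key.sex, q)) for q in range(1, 6)
    ]
    merged = np.concatenate([p for p in level3 if p is not None and len(p)] or [[]])
    if len(merged):
        return np.sort(merged), 3
    return np.array([], dtype=object), 3


def match_replicate(
    deaths: pd.DataFrame,
    cells: dict[MatchCellKey, np.ndarray],
    seed: int,
    banding: list[tuple[int, int]] | None = None,
    replicate_index: int = 0,
) -> MatchAssignment:
    """Assign every decedent a candidate drawn uniformly, with replacement.

    Decedents are processed in id order so the draw sequence — hence the
    assignment — is a pure function of (deaths, cells, seed).
    """
    if banding is None:
        banding = default_age_banding()
    rng = np.random.default_rng(seed)
    ordered = deaths.sort_values("id")
    bands = age_band_index(ordered["age"].to_numpy(), banding)

    pairs: dict[str, str] = {}
    fallback_log: list[tuple[str, int]] = []
    pool_cache: dict[MatchCellKey, tuple[np.ndarray, int]] = {}
    for death_id, band, sex, ses in zip(
        ordered["id"], bands, ordered["sex"], ordered["ses_quintile"]
    ):
        key = MatchCellKey(int(band), str(sex), int(ses))
        if key not in pool_cache:
            pool_cache[key] = _candidates_with_fallback(key, cells, len(banding))
        pool, level = pool_cache[key]
        if len(pool) == 0:
            raise MatchingError(
                f"no panel candidate for decedent {death_id} "
                f"(band {band}, sex {sex}, SES {ses}) even after full relaxation"
            )
        pairs[death_id] = str(pool[rng.integers(len(pool))])
        if level > 0:
            fallback_log.append((str(death_id), level))
    return MatchAssignment(
        replicate_index=replicate_index, seed=seed, pairs=pairs,
        fallback_log=fallback_log,
    )


def run_replicates(
    deaths: pd.DataFrame,
    cells: dict[MatchCellKey, np.ndarray],
    n_replicates: int,
    base_seed: int,
    banding: list[tuple[int, int]] | None = None,
) -> list[MatchAssignment]:
    """R independent matching replicates; replicate r seeds with base_seed ^ r."""
    if n_replicates < 1:
        raise ConfigurationError("n_replicates must be >= 1")
    return [
        match_replicate(
            deaths, cells, seed=base_seed ^ r, banding=banding, replicate_index=r
        )
        for r in range(n_replicates)
    ]


def assignments_to_frame(assignments: list[MatchAssignment]) -> pd.DataFrame:
    """Flatten assignments to a frame: replicate, death_id, person_id,
    fallback_level (0 = matched in own cell)."""
    rows = []
    for a in assignments:
        fallback = dict(a.fallback_log)
        for death_id, person_id in a.pairs.items():
            rows.append(
                {
                    "replicate": a.replicate_index,
                    "death_id": death_id,
                    "person_id": person_id,
                    "fallback_level": fallback.get(death_id, 0),
                }
            )
    return pd.DataFrame(rows)
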