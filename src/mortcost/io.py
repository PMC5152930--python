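"""CSV readers/writers for the two input datasets and run outputs.

Mortality CSV: id, year, age, sex {M,F}, ses_quintile {1..5}, icd10.
Panel CSV (long): person_id, year, age, sex, ses_quintile, alive {0,1},
weekly_hours, annual_income_real.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .errors import DataError

MORTALITY_COLUMNS = ["id", "year", "age", "sex", "ses_quintile", "icd10"]
PANEL_COLUMNS = [
    "person_id",
    "year",
    "age",
    "sex",
    "ses_quintile",
    "alive",
    "weekly_hours",
    "annual_income_real",
]


def _require(df: pd.DataFrame, columns: list[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise DataError(f"{what} file is missing columns: {missing}")


def read_mortality(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"id": str, "icd10": str})
    _require(df, MORTALITY_COLUMNS, "mortality")
    return df


def write_mortality(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_panel(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"person_id": str})
    _require(df, PANEL_COLUMNS, "panel")
    return df


def write_panel(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)
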