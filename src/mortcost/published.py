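"""Published summary tables for the 2003 Australian cancer-mortality costing.

These are the printed aggregate results of the original analysis — death
and years-of-life-lost counts by age band and sex, present value of
lifetime income (PVLI) lost by age band and sex, and the per-site burden
table — kept here as machine-readable inputs. They serve two purposes:

* ratio-style quantities (shares of total, cost per death, scenario
  savings) are recomputable from them with the reporting operations;
* the synthetic-data generator uses their marginals as default weights,
  so a synthetic cohort has the published age/sex/site structure.

Only point values are carried; some of the printed confidence-interval
cells are typographically corrupt in the source tables and are omitted.
Monetary values are $ millions in 2016 Australian dollars.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "AGE_BANDS",
    "deaths_yll_by_age_sex",
    "pvli_by_age_sex",
    "site_burden",
]

#: Reporting age bands (inclusive integer-age bounds). Premature deaths are
#: deaths before age 80, so the top band "65-80" covers ages 65–79.
AGE_BANDS: list[tuple[str, int, int]] = [
    ("<15", 0, 14),
    ("15-24", 15, 24),
    ("25-34", 25, 34),
    ("35-44", 35, 44),
    ("45-54", 45, 54),
    ("55-64", 55, 64),
    ("65-80", 65, 79),
]

_DEATHS_YLL = [
    # age_band, deaths_male, yll_male, deaths_female, yll_female
    ("<15", 54, 1261, 35, 804),
    ("15-24", 57, 1345, 42, 980),
    ("25-34", 121, 2791, 153, 3568),
    ("35-44", 422, 9783, 524, 12396),
    ("45-54", 1338, 31069, 1376, 32928),
    ("55-64", 3385, 73828, 2497, 56708),
    ("65-80", 9674, 141598, 6055, 100115),
]

_PVLI_AGE_SEX = [
    # age_band, pvli_male_m, pvli_female_m  ($ millions)
    ("<15", 14, 17),
    ("15-24", 45, 22),
    ("25-34", 142, 79),
    ("35-44", 505, 233),
    ("45-54", 1084, 382),
    ("55-64", 950, 269),
    ("65-80", 388, 68),
]

_SITE_BURDEN = [
    # site, working_years, pvli_m, deaths, pvli_per_death_k
    ("Lung cancer", 15943, 765, 5746, 133),
    ("Colorectal cancer", 10332, 497, 3253, 153),
    ("Brain cancer", 6571, 326, 1003, 325),
    ("Breast cancer", 7519, 307, 2171, 142),
    ("Melanoma", 4897, 249, 867, 288),
    ("Lymphoma", 4263, 209, 1101, 190),
    ("Leukaemia", 4180, 201, 990, 203),
    ("Pancreatic cancer", 4083, 197, 1398, 141),
    ("Oesophageal cancer", 3134, 156, 849, 184),
    ("Stomach cancer", 3113, 154, 830, 186),
    ("Liver cancer (excluding hepatitis B and C related)", 2929, 150, 720, 209),
    ("Mouth and oropharynx cancers", 2805, 142, 566, 250),
    ("Prostate cancer", 2605, 125, 1547, 81),
    ("Kidney cancer", 2414, 121, 656, 185),
    ("Bone and connective tissue cancer", 1890, 88, 240, 368),
    ("Ovarian cancer", 1505, 61, 632, 97),
    ("Multiple myeloma", 1205, 58, 488, 120),
    ("Bladder cancer", 1029, 50, 480, 104),
    ("Cervical cancer", 967, 39, 213, 183),
    ("Laryngeal cancer", 718, 36, 186, 192),
    ("Non-melanoma skin cancers", 639, 32, 197, 163),
    ("Gallbladder cancer", 544, 26, 192, 134),
    ("Corpus uteri cancer", 354, 14, 183, 79),
    ("Testicular cancer", 237, 13, 16, 793),
    ("Eye cancer", 126, 7, 24, 275),
    ("Thyroid cancer", 96, 4, 54, 78),
    ("Other malignant neoplasms", 3554, 171, 1131, 151),
]


def deaths_yll_by_age_sex() -> pd.DataFrame:
    """Premature cancer deaths in 2003 and counterfactual YLL to 2030.

    Columns: age_band, sex {M,F}, deaths, yll. One row per (band, sex).
    """
    rows = []
    for band, dm, ym, df_, yf in _DEATHS_YLL:
        rows.append({"age_band": band, "sex": "M", "deaths": dm, "yll": ym})
        rows.append({"age_band": band, "sex": "F", "deaths": df_, "yll": yf})
    return pd.DataFrame(rows)


#: Printed PVLI totals ($ millions). The source table's rounded rows do not
#: sum exactly to these (the female rows total 1,070 as printed against a
#: printed subtotal of 1,071), so share arithmetic uses the printed totals.
PVLI_TOTALS_M: dict[str, int] = {"M": 3128, "F": 1071, "All": 4200}


def pvli_by_age_sex() -> pd.DataFrame:
    """PVLI lost ($ millions, 2016 AUD) by age band and sex."""
    rows = []
    for band, pm, pf in _PVLI_AGE_SEX:
        rows.append({"age_band": band, "sex": "M", "pvli_m": pm})
        rows.append({"age_band": band, "sex": "F", "pvli_m": pf})
    return pd.DataFrame(rows)


def site_burden() -> pd.DataFrame:
    """Cumulative burden by cancer site, 2003 deaths modelled to 2030.

    Columns: site, working_years, pvli_m ($ millions), deaths,
    pvli_per_death_k ($ thousands per death).
    """
    return pd.DataFrame(
        _SITE_BURDEN,
        columns=["site", "working_years", "pvli_m", "deaths", "pvli_per_death_k"],
    )
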