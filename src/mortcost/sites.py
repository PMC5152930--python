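"""ICD-10 cause-of-death parsing and cancer-site grouping.

Cancer deaths are identified from the underlying-cause ICD-10 code: any
code whose three-character category falls in C00–C97 counts as a malignant
neoplasm. For site-level reporting, codes are grouped into 26 named cancer
sites plus a catch-all "Other malignant neoplasms" using inclusive
three-character category ranges (standard WHO ICD-10 groupings). The
default map is overridable by a user-supplied CSV so alternative
site definitions can be plugged in without code changes.

Notes on the default map:

* "Liver cancer (excluding hepatitis B and C related)" is mapped to plain
  C22. Hepatitis attribution cannot be derived from the underlying-cause
  code alone, so the exclusion in the label is *not* enforced here.
* C97 (independent multiple primaries) falls through to the catch-all.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "SiteMap",
    "default_site_map",
    "is_cancer_death",
    "parse_icd10",
    "classify_site",
    "OTHER_SITE_LABEL",
]

OTHER_SITE_LABEL = "Other malignant neoplasms"

_ICD10_RE = re.compile(r"^([A-Z])(\d{2})(?:\.(\d{1,2}))?$")


class ICD10ParseError(ValueError):
    """Raised for tokens that are not ICD-10-shaped codes."""


def parse_icd10(code: str) -> tuple[str, int]:
    """Parse an ICD-10 token into (chapter letter, two-digit category number).

    Subcodes beyond the three-character category (e.g. ``C34.1``) are
    accepted and ignored: classification operates on the category.
    """
    if not isinstance(code, str):
        raise ICD10ParseError(f"ICD-10 code must be a string, got {code!r}")
    token = code.strip().upper()
    m = _ICD10_RE.match(token)
    if m is None:
        raise ICD10ParseError(f"malformed ICD-10 code: {code!r}")
    return m.group(1), int(m.group(2))


def is_cancer_death(code: str) -> bool:
    """True iff the three-character category lies within C00–C97."""
    letter, num = parse_icd10(code)
    return letter == "C" and 0 <= num <= 97


@dataclass(frozen=True)
class SiteMap:
    """Ordered grouping of ICD-10 categories into reported cancer sites.

    ``entries`` maps a site label to a list of inclusive (start, end)
    category-number ranges within the C chapter. Lookup returns the first
    matching entry; any cancer code matching no entry returns
    ``catch_all`` (by construction the partition over C00–C97 is total).
    """

    entries: tuple[tuple[str, tuple[tuple[int, int], ...]], ...]
    catch_all: str = OTHER_SITE_LABEL

    def __post_init__(self) -> None:
        labels = [label for label, _ in self.entries]
        if len(labels) != len(set(labels)):
            raise ValueError("site labels must be unique")
        for label, ranges in self.entries:
            for lo, hi in ranges:
                if not (0 <= lo <= hi <= 97):
                    raise ValueError(
                        f"range C{lo:02d}-C{hi:02d} for {label!r} outside C00-C97"
                    )

    @property
    def labels(self) -> list[str]:
        """All site labels, catch-all last."""
        return [label for label, _ in self.entries] + [self.catch_all]

    def lookup(self, category_number: int) -> str:
        for label, ranges in self.entries:
            for lo, hi in ranges:
                if lo <= category_number <= hi:
                    return label
        return self.catch_all

    @classmethod
    def from_csv(cls, path: str | Path) -> "SiteMap":
        """Load a map from CSV with columns site_label, code_start, code_end.

        Rows are repeatable per site; row order fixes lookup precedence.
        The catch-all label need not be listed.
        """
        df = pd.read_csv(path, dtype=str)
        required = {"site_label", "code_start", "code_end"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"site map file missing columns: {sorted(missing)}")
        grouped: dict[str, list[tuple[int, int]]] = {}
        order: list[str] = []
        for _, row in df.iterrows():
            label = row["site_label"]
            _, lo = parse_icd10(row["code_start"])
            _, hi = parse_icd10(row["code_end"])
            if label not in grouped:
                grouped[label] = []
                order.append(label)
            grouped[label].append((lo, hi))
        return cls(entries=tuple((lab, tuple(grouped[lab])) for lab in order))

    def to_csv(self, path: str | Path) -> None:
        rows = [
            {"site_label": label, "code_start": f"C{lo:02d}", "code_end": f"C{hi:02d}"}
            for label, ranges in self.entries
            for lo, hi in ranges
        ]
        pd.DataFrame(rows).to_csv(path, index=False)


# Default grouping: 26 named sites + catch-all, standard WHO ICD-10
# category ranges. Order is precedence order for lookup.
_DEFAULT_ENTRIES: tuple[tuple[str, tuple[tuple[int, int], ...]], ...] = (
    ("Mouth and oropharynx cancers", ((0, 14),)),
    ("Oesophageal cancer", ((15, 15),)),
    ("Stomach cancer", ((16, 16),)),
    ("Colorectal cancer", ((18, 21),)),
    ("Liver cancer (excluding hepatitis B and C related)", ((22, 22),)),
    ("Gallbladder cancer", ((23, 24),)),
    ("Pancreatic cancer", ((25, 25),)),
    ("Laryngeal cancer", ((32, 32),)),
    ("Lung cancer", ((33, 34),)),
    ("Bone and connective tissue cancer", ((40, 41), (47, 47), (49, 49))),
    ("Melanoma", ((43, 43),)),
    ("Non-melanoma skin cancers", ((44, 44),)),
    ("Breast cancer", ((50, 50),)),
    ("Cervical cancer", ((53, 53),)),
    ("Corpus uteri cancer", ((54, 55),)),
    ("Ovarian cancer", ((56, 56),)),
    ("Prostate cancer", ((61, 61),)),
    ("Testicular cancer", ((62, 62),)),
    ("Kidney cancer", ((64, 66),)),
    ("Bladder cancer", ((67, 67),)),
    ("Eye cancer", ((69, 69),)),
    ("Brain cancer", ((70, 72),)),
    ("Thyroid cancer", ((73, 73),)),
    ("Lymphoma", ((81, 85),)),
    ("Multiple myeloma", ((88, 90),)),
    ("Leukaemia", ((91, 95),)),
)


def default_site_map() -> SiteMap:
    """The default 27-label site map (26 named sites + catch-all)."""
    return SiteMap(entries=_DEFAULT_ENTRIES)


def classify_site(code: str, site_map: SiteMap | None = None) -> str:
    """Map a cancer ICD-10 code to its reported site label.

    Raises ``ValueError`` for codes outside C00–C97: classification is only
    defined for cancer deaths.
    """
    if site_map is None:
        site_map = default_site_map()
    letter, num = parse_icd10(code)
    if letter != "C" or num > 97:
        raise ValueError(f"not a cancer underlying-cause code: {code!r}")
    return site_map.lookup(num)
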