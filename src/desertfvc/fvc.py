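"""Fractional vegetation coverage and desertification grading.

FVC is the percentage of image pixels classified as vegetation.  Grassland
desertification severity is keyed to FVC in five bands (national sandified-
land monitoring practice): severe below 5%, high 5-20%, moderate 21-50%,
slight 51-70%, and non-desertification above 70%.  The published bands are
integer-valued and leave real-valued gaps (e.g. 20.5%); the implementation
uses the half-open intervals [0,5), [5,21), [21,51), [51,71), [71,100] so
that every FVC in [0, 100] receives exactly one grade.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FVCValue",
    "Grade",
    "GRADES",
    "GRADE_LABELS",
    "compute_fvc",
    "assign_grade",
    "grade_severity",
    "grade_report_frame",
]


@dataclass(frozen=True)
class FVCValue:
    """Fractional vegetation coverage of one mask, as a percentage."""

    fvc: float
    n_vegetation: int
    n_total: int


@dataclass(frozen=True)
class Grade:
    label: str
    lower: float  # inclusive
    upper: float  # exclusive, except the last band which includes 100

#: Five severity bands ordered from most to least desertified.
GRADES: tuple[Grade, ...] = (
    Grade("Severe", 0.0, 5.0),
    Grade("High", 5.0, 21.0),
    Grade("Moderate", 21.0, 51.0),
    Grade("Slight", 51.0, 71.0),
    Grade("Non-desertification", 71.0, 100.0),
)

GRADE_LABELS: tuple[str, ...] = tuple(g.label for g in GRADES)
_SEVERITY = {g.label: i for i, g in enumerate(GRADES)}


def compute_fvc(mask: np.ndarray) -> FVCValue:
    """Exact pixel-count FVC of a binary vegetation mask, in percent."""
    arr = np.asarray(mask)
    if arr.size == 0:
        raise ValueError("empty mask: FVC undefined")
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("mask must be binary (0/1)")
    n_veg = int(arr.sum())
    n_total = int(arr.size)
    return FVCValue(fvc=100.0 * n_veg / n_total, n_vegetation=n_veg, n_total=n_total)


def assign_grade(fvc: float) -> str:
    """Desertification grade label for an FVC percentage in [0, 100]."""
    if not np.isfinite(fvc) or fvc < 0 or fvc > 100:
        raise ValueError(f"FVC must lie in [0, 100], got {fvc!r}")
    for grade in GRADES[:-1]:
        if fvc < grade.upper:
            return grade.label
    return GRADES[-1].label


def grade_severity(label: str) -> int:
    """Severity rank of a grade label: 0 = Severe ... 4 = Non-desertification."""
    return _SEVERITY[label]


def grade_report_frame(rows: list[dict]) -> pd.DataFrame:
    """Assemble per-image FVC/grade rows into the standard report table."""
    return pd.DataFrame(
        rows, columns=["image_id", "n_vegetation", "n_total", "fvc_percent", "grade"]
    )
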