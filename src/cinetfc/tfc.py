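"""2010 ARVC Task Force Criteria — the CMR criterion and point tally.

The imaging criterion of the revised 2010 Task Force Criteria requires a
regional RV wall-motion abnormality (akinesia, dyskinesia or dyssynchrony)
*plus* a functional or dimensional threshold:

* major: RVEF <= 40%, or RVEDVI >= 110 ml/m² (males) / >= 100 ml/m² (females)
* minor: 40% < RVEF <= 45%, or RVEDVI in [100, 110) ml/m² (males) /
  [90, 100) ml/m² (females)

A major criterion scores 2 points, a minor 1, none 0.  Points from the five
non-CMR categories (tissue characterization, repolarization, depolarization,
arrhythmias, family history/genetics) are consumed as a given total; a
definite ARVC diagnosis is a total of at least 4 points.  This plain-sum
tally is a simplification of the full 2010 category-combination rules.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

__all__ = [
    "TfcThresholds",
    "TfcInput",
    "TfcResult",
    "classify_cmr",
    "total_tfc",
    "CATEGORY_POINTS",
]

CATEGORY_POINTS = {"none": 0, "minor": 1, "major": 2}


@dataclass(frozen=True)
class TfcThresholds:
    """Numeric cutoffs of the CMR criterion, externalized for audit.

    ``female_major_inclusive`` selects whether the female major RVEDVI
    cutoff is ``>= 100`` (default) or strictly ``> 100`` ml/m²; published
    wordings differ and the choice only matters exactly at 100.
    """

    rvef_major_max: float = 40.0
    rvef_minor_max: float = 45.0
    rvedvi_major: dict[str, float] | None = None
    rvedvi_minor_low: dict[str, float] | None = None
    female_major_inclusive: bool = True
    diagnosis_points: int = 4

    def __post_init__(self) -> None:
        if self.rvedvi_major is None:
            object.__setattr__(self, "rvedvi_major", {"male": 110.0, "female": 100.0})
        if self.rvedvi_minor_low is None:
            object.__setattr__(self, "rvedvi_minor_low", {"male": 100.0, "female": 90.0})

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "TfcThresholds":
        return cls(**json.loads(Path(path).read_text()))


DEFAULT_THRESHOLDS = TfcThresholds()


@dataclass
class TfcInput:
    """Inputs of the CMR criterion plus the non-CMR point total."""

    sex: str
    rwma: bool
    rvef_percent: float
    rvedvi_ml_per_m2: float
    noncmr_points: int = 0

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if not (0 <= self.rvef_percent <= 100):
            raise ValueError("rvef_percent must lie in [0, 100]")
        if self.rvedvi_ml_per_m2 < 0:
            raise ValueError("rvedvi_ml_per_m2 must be non-negative")


@dataclass
class TfcResult:
    cmr_category: str  # none | minor | major
    cmr_points: int
    total_points: int
    definite_diagnosis: bool


def classify_cmr(inp: TfcInput,
                 thresholds: TfcThresholds = DEFAULT_THRESHOLDS) -> str:
    """CMR criterion category for one subject: 'none', 'minor' or 'major'.

    Without a regional wall-motion abnormality the category is 'none'
    regardless of volumes; major takes precedence over minor.  Volumes are
    compared at full floating precision.
    """
    t = thresholds
    if not inp.rwma:
        return "none"
    ef, edvi, sex = inp.rvef_percent, inp.rvedvi_ml_per_m2, inp.sex
    major_cut = t.rvedvi_major[sex]
    if sex == "female" and not t.female_major_inclusive:
        major_by_volume = edvi > major_cut
    else:
        major_by_volume = edvi >= major_cut
    if ef <= t.rvef_major_max or major_by_volume:
        return "major"
    minor_by_ef = t.rvef_major_max < ef <= t.rvef_minor_max
    minor_by_volume = t.rvedvi_minor_low[sex] <= edvi and not major_by_volume
    if minor_by_ef or minor_by_volume:
        return "minor"
    return "none"


def total_tfc(noncmr_points: int, cmr_category: str,
              thresholds: TfcThresholds = DEFAULT_THRESHOLDS) -> TfcResult:
    """Total TFC point score and definite-diagnosis flag (total >= 4)."""
    if noncmr_points < 0:
        raise ValueError("noncmr_points must be non-negative")
    if cmr_category not in CATEGORY_POINTS:
        raise ValueError(f"cmr_category must be one of {tuple(CATEGORY_POINTS)}")
    cmr_points = CATEGORY_POINTS[cmr_category]
    total = noncmr_points + cmr_points
    return TfcResult(cmr_category, cmr_points, total,
                     total >= thresholds.diagnosis_points)


def score_subject(inp: TfcInput,
                  thresholds: TfcThresholds = DEFAULT_THRESHOLDS) -> TfcResult:
    """Classify the CMR criterion and tally the total score in one call."""
    return total_tfc(inp.noncmr_points, classify_cmr(inp, thresholds), thresholds)
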