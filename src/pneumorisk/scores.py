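"""Clinical severity score and biomarker threshold rules.

CRB-65 is the standard 4-point primary-care severity score for
community-acquired pneumonia: one point each for new-onset confusion,
respiratory rate >= 30/min, low blood pressure (systolic < 90 mmHg or
diastolic <= 60 mmHg, counted once) and age >= 65 years.

CRP guideline bands: < 20 mg/l effectively rules pneumonia out,
> 100 mg/l supports treating, and the 20-100 mg/l range leaves the
decision to the clinical picture.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional


class CrpBand(str, Enum):
    RULE_OUT = "rule_out"
    INTERMEDIATE = "intermediate"
    TREAT = "treat"


def _require(value, name: str) -> float:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        raise ValueError(f"CRB-65 input {name!r} is missing; no partial scores")
    return float(value)


@dataclass(frozen=True)
class Crb65Inputs:
    """The four CRB-65 criteria inputs; all must be non-missing."""

    confusion_new_onset: int
    respiratory_rate_per_min: float
    systolic_bp_mmHg: float
    diastolic_bp_mmHg: float
    age_years: int

    def score(self) -> int:
        return crb65_score(
            self.confusion_new_onset,
            self.respiratory_rate_per_min,
            self.systolic_bp_mmHg,
            self.diastolic_bp_mmHg,
            self.age_years,
        )


def crb65_score(
    confusion_new_onset,
    respiratory_rate_per_min,
    systolic_bp_mmHg,
    diastolic_bp_mmHg,
    age_years,
) -> int:
    """CRB-65 score in [0, 4]; raises on any missing input."""
    c = _require(confusion_new_onset, "confusion_new_onset")
    rr = _require(respiratory_rate_per_min, "respiratory_rate_per_min")
    sbp = _require(systolic_bp_mmHg, "systolic_bp_mmHg")
    dbp = _require(diastolic_bp_mmHg, "diastolic_bp_mmHg")
    age = _require(age_years, "age_years")
    if c not in (0.0, 1.0):
        raise ValueError("confusion_new_onset must be 0 or 1")
    score = 0
    score += int(c == 1.0)
    score += int(rr >= 30.0)
    score += int(sbp < 90.0 or dbp <= 60.0)  # B criterion counts once
    score += int(age >= 65)
    return score


def crp_band(crp_mg_per_l: float) -> CrpBand:
    """Guideline CRP band: <20 rule-out, 20-100 inclusive intermediate, >100 treat."""
    crp = float(crp_mg_per_l)
    if math.isnan(crp) or crp < 0:
        raise ValueError(f"CRP must be a non-negative number, got {crp_mg_per_l!r}")
    if crp < 20.0:
        return CrpBand.RULE_OUT
    if crp > 100.0:
        return CrpBand.TREAT
    return CrpBand.INTERMEDIATE


def biomarker_indicator(value, cutoff: float) -> Optional[int]:
    """Dichotomise a biomarker at a strict ``>`` cutoff.

    Values exactly at the cutoff score 0 (the prediction model's
    "CRP > 30 mg/l" convention). Missing values propagate as ``None``.
    """
    if cutoff is None or not cutoff > 0:
        raise ValueError("cutoff must be positive")
    if value is None:
        return None
    v = float(value)
    if math.isnan(v):
        return None
    if v < 0:
        raise ValueError(f"biomarker value must be non-negative, got {value!r}")
    return int(v > float(cutoff))
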