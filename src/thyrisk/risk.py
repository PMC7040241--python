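"""Total risk score and the sequential management algorithm.

The total risk score is the sum of the ultrasound and genomic classifier
scores, TRS = X_US + X_GC. Management follows a sequential rule: a high-risk
ultrasound pattern (X_US = 0.9) goes straight to surgical referral — molecular
testing adds no specificity in that stratum — while low-to-intermediate
patterns are referred to surgery when TRS >= 0.7 and to active surveillance
otherwise.

Score comparisons use an absolute tolerance of 1e-9 because the score lattice
is decimal (0.2 + 0.5 must count as >= 0.7 despite binary rounding).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional

from .errors import ValidationError
from .ultrasound import XUS_VALUES

#: Absolute tolerance for cutoff comparisons on the decimal score lattice.
SCORE_TOL = 1e-9

#: Study cutoffs for dichotomizing each score (test-positive iff score >= cutoff).
XUS_CUTOFF = 0.9
XGC_CUTOFF = 0.6
TRS_CUTOFF = 0.7


class Management(str, Enum):
    SURGERY = "SURGERY"
    SURVEILLANCE = "SURVEILLANCE"


class Truth(str, Enum):
    """Reference-standard histology label."""

    MALIGNANT = "MALIGNANT"
    BENIGN = "BENIGN"


def ge(a: float, b: float, tol: float = SCORE_TOL) -> bool:
    """``a >= b`` with the decimal-lattice tolerance."""
    return a >= b - tol


def compute_trs(x_us: float, x_gc: float) -> float:
    """Total risk score: the exact sum X_US + X_GC."""
    if not any(abs(x_us - v) <= SCORE_TOL for v in XUS_VALUES):
        raise ValidationError("bad-xus", f"x_us must be one of {XUS_VALUES}, got {x_us}")
    if x_gc < 0:
        raise ValidationError("bad-xgc", f"x_gc must be >= 0, got {x_gc}")
    return x_us + x_gc


def classify_management(
    x_us: float, trs: float, trs_cutoff: float = TRS_CUTOFF
) -> Management:
    """Management recommendation from the sequential algorithm.

    SURGERY when X_US = 0.9 (the molecular result is ignored in the high-risk
    ultrasound stratum), otherwise SURGERY when TRS >= ``trs_cutoff`` and
    SURVEILLANCE below it. The cutoff comparison is inclusive.
    """
    if trs < x_us - SCORE_TOL:
        raise ValidationError("trs-below-xus", f"trs {trs} < x_us {x_us}")
    if ge(x_us, XUS_CUTOFF):
        return Management.SURGERY
    return Management.SURGERY if ge(trs, trs_cutoff) else Management.SURVEILLANCE


@dataclass(frozen=True)
class ScoredNodule:
    """Joined scores, TRS and management recommendation for one nodule."""

    nodule_id: str
    x_us: float
    x_gc: float
    trs: float
    recommendation: Management
    truth: Optional[Truth] = None


def score_nodule(
    nodule_id: str,
    x_us: float,
    x_gc: float,
    truth: Optional[Truth] = None,
    trs_cutoff: float = TRS_CUTOFF,
) -> ScoredNodule:
    """Compute TRS and the management recommendation for one nodule."""
    trs = compute_trs(x_us, x_gc)
    return ScoredNodule(
        nodule_id=nodule_id,
        x_us=x_us,
        x_gc=x_gc,
        trs=trs,
        recommendation=classify_management(x_us, trs, trs_cutoff),
        truth=truth,
    )
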