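"""Per-patient response classification: RECIST 1.0 and Choi criteria.

RECIST 1.0 classifies on the percent change of the sum of target-lesion
longest diameters: PR at <= -30% from baseline, PD at >= +20% from the
smallest sum recorded since treatment start (the nadir), new lesions are
always PD, disappearance of all lesions is CR.

Choi criteria add CT attenuation: PR is a >= 10% decrease in size *or* a
>= 15% decrease in mean tumour attenuation (HU); PD is a >= 10% increase in
size that does not meet the attenuation PR condition, or new lesions. The
attenuation PR therefore overrides a size increase — a lesion set that grows
while becoming markedly hypodense is still a response.

Aggregation: size via the sum of longest diameters over the eligible lesions
(vanished lesions contribute 0); attenuation via the unweighted mean of
per-lesion mean HU over the attenuation-evaluable lesions, compared between
baseline and evaluation as a percent change.

Classification always uses unrounded percent changes; integer display
rounding (half away from zero) is presentation-only.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

from .datatypes import (
    CriteriaThresholds,
    LesionMeasurement,
    PRBasis,
    ResponseAssessment,
    ResponseCategory,
)

__all__ = [
    "percent_change",
    "display_percent",
    "patient_size_sum",
    "patient_mean_attenuation",
    "classify_recist",
    "classify_choi",
    "classify_choi_separate",
    "best_response",
    "clinical_benefit",
]


class NotEvaluableError(ValueError):
    """Raised when a quantity cannot be computed from the available lesions."""


def percent_change(baseline_value: float, evaluation_value: float) -> float:
    """Percent change from baseline: 100 * (evaluation - baseline) / baseline."""
    if baseline_value <= 0:
        raise ValueError(f"baseline must be > 0, got {baseline_value}")
    if evaluation_value < 0:
        raise ValueError(f"evaluation must be >= 0, got {evaluation_value}")
    return 100.0 * (evaluation_value - baseline_value) / baseline_value


def display_percent(pct: float) -> int:
    """Round a percent change to the nearest integer, half away from zero."""
    return int(math.floor(abs(pct) + 0.5)) * (-1 if pct < 0 else 1)


def patient_size_sum(lesions: Sequence[Optional[LesionMeasurement]]) -> float:
    """Sum of longest diameters (mm); a vanished lesion (None) contributes 0."""
    if not lesions:
        raise NotEvaluableError("no included lesions: size sum not evaluable")
    return float(sum(0.0 if les is None else les.longest_diameter_mm
                     for les in lesions))


def patient_mean_attenuation(lesions: Sequence[LesionMeasurement]) -> float:
    """Unweighted mean of per-lesion mean HU over attenuation-evaluable lesions."""
    values = [les.mean_attenuation_hu for les in lesions
              if les is not None and les.mean_attenuation_hu is not None]
    if not values:
        raise NotEvaluableError(
            "no attenuation-evaluable lesions: mean attenuation not evaluable"
        )
    return float(sum(values) / len(values))


def classify_recist(
    baseline_sum: float,
    eval_sum: float,
    reference_min_sum: float,
    new_lesions: bool,
    all_disappeared: bool,
    thresholds: CriteriaThresholds = CriteriaThresholds(),
) -> ResponseCategory:
    """RECIST 1.0 category from diameter sums.

    ``reference_min_sum`` is the nadir (smallest sum since treatment start);
    at first evaluation it equals the baseline sum. Check order:
    new lesions -> PD, complete disappearance -> CR, PR from baseline,
    PD from nadir, else SD.
    """
    if baseline_sum <= 0 or reference_min_sum <= 0 or eval_sum < 0:
        raise ValueError("diameter sums must be positive (evaluation >= 0)")
    if reference_min_sum > baseline_sum:
        raise ValueError("reference_min_sum cannot exceed baseline_sum")
    if new_lesions:
        return ResponseCategory.PD
    if all_disappeared:
        return ResponseCategory.CR
    if percent_change(baseline_sum, eval_sum) <= thresholds.recist_pr_pct:
        return ResponseCategory.PR
    if percent_change(reference_min_sum, eval_sum) >= thresholds.recist_pd_pct:
        return ResponseCategory.PD
    return ResponseCategory.SD


def classify_choi(
    size_pct: float,
    attenuation_pct: Optional[float],
    new_lesions: bool,
    all_disappeared: bool,
    nonmeasurable_progression: bool = False,
    thresholds: CriteriaThresholds = CriteriaThresholds(),
) -> tuple[ResponseCategory, PRBasis]:
    """Choi category and the basis of a partial response.

    PR requires a size decrease >= 10% or an attenuation decrease >= 15%
    (inclusive thresholds); an attenuation PR overrides a size increase. PD
    is a size increase >= 10% without the attenuation PR, or new lesions, or
    obvious progression of non-measurable disease. An absent attenuation
    change leaves the attenuation condition unmet.
    """
    if new_lesions or nonmeasurable_progression:
        return ResponseCategory.PD, PRBasis.NONE
    if all_disappeared:
        return ResponseCategory.CR, PRBasis.NONE
    size_pr = size_pct <= thresholds.choi_pr_size_pct
    atten_pr = (attenuation_pct is not None
                and attenuation_pct <= thresholds.choi_pr_attenuation_pct)
    if size_pr or atten_pr:
        if size_pr and atten_pr:
            basis = PRBasis.BOTH
        elif size_pr:
            basis = PRBasis.SIZE_ONLY
        else:
            basis = PRBasis.ATTENUATION_ONLY
        return ResponseCategory.PR, basis
    if size_pct >= thresholds.choi_pd_size_pct:
        return ResponseCategory.PD, PRBasis.NONE
    return ResponseCategory.SD, PRBasis.NONE


def classify_choi_separate(
    size_pct: Optional[float],
    attenuation_pct: Optional[float],
    new_lesions: bool,
    thresholds: CriteriaThresholds = CriteriaThresholds(),
    mode: str = "size_only",
) -> ResponseCategory:
    """Single-criterion Choi dichotomy (responder PR vs non-responder SD).

    ``mode='size_only'`` uses only the >= 10% size decrease;
    ``mode='attenuation_only'`` only the >= 15% attenuation decrease.
    New lesions force PD in either mode.
    """
    if mode not in ("size_only", "attenuation_only"):
        raise ValueError(f"unknown mode {mode!r}")
    if new_lesions:
        return ResponseCategory.PD
    if mode == "size_only":
        if size_pct is None:
            return ResponseCategory.NOT_EVALUABLE
        return (ResponseCategory.PR
                if size_pct <= thresholds.choi_pr_size_pct
                else ResponseCategory.SD)
    if attenuation_pct is None:
        return ResponseCategory.NOT_EVALUABLE
    return (ResponseCategory.PR
            if attenuation_pct <= thresholds.choi_pr_attenuation_pct
            else ResponseCategory.SD)


def best_response(
    assessments: Sequence[ResponseAssessment],
) -> tuple[ResponseCategory, Optional[float]]:
    """Best category over time (CR > PR > SD > PD) and months to first PR."""
    if not assessments:
        raise ValueError("best_response needs at least one assessment")
    ordered = sorted(assessments, key=lambda a: a.months_from_start)
    evaluable = [a for a in ordered
                 if a.category is not ResponseCategory.NOT_EVALUABLE]
    if not evaluable:
        return ResponseCategory.NOT_EVALUABLE, None
    best = max(evaluable, key=lambda a: a.rank()).category
    months_to_pr = next(
        (a.months_from_start for a in evaluable
         if a.category in (ResponseCategory.PR, ResponseCategory.CR)), None,
    )
    return best, months_to_pr


def clinical_benefit(
    best: ResponseCategory,
    pfs_months: float,
    thresholds: CriteriaThresholds = CriteriaThresholds(),
) -> bool:
    """Clinical benefit: CR or PR, or SD maintained for at least 12 weeks."""
    if best in (ResponseCategory.CR, ResponseCategory.PR):
        return True
    return (best is ResponseCategory.SD
            and pfs_months >= thresholds.clinical_benefit_months)
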