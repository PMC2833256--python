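"""Shared domain types for the response-criteria pipeline.

Units are fixed package-wide: lesion diameters in millimetres, attenuation in
Hounsfield units (HU), all times in months from the first day of treatment.
The twelve-week clinical-benefit window is expressed exactly as 84 days in
average months (84 / 30.4375).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from typing import Optional

__all__ = [
    "OrganSite",
    "ExclusionReason",
    "ResponseCategory",
    "PRBasis",
    "CriteriaSet",
    "CensorReason",
    "Endpoint",
    "LesionMeasurement",
    "Scan",
    "PatientTimeline",
    "ResponseAssessment",
    "SurvivalEndpoint",
    "CriteriaThresholds",
    "DAYS_PER_MONTH",
    "TWELVE_WEEKS_MONTHS",
]

#: Average Gregorian month length in days (365.25 / 12).
DAYS_PER_MONTH = 30.4375

#: The 12-week clinical-benefit window expressed in months (84 days).
TWELVE_WEEKS_MONTHS = 84.0 / DAYS_PER_MONTH


class OrganSite(str, enum.Enum):
    """Anatomical site of a metastatic lesion (or the primary tumour)."""

    LUNG = "lung"
    LYMPH_NODE = "lymph_node"
    LIVER = "liver"
    ABDOMINAL_OTHER = "abdominal_other"
    THORACIC_OTHER = "thoracic_other"
    BONE = "bone"
    BRAIN = "brain"
    PRIMARY_TUMOUR = "primary_tumour"


#: Sites excluded from target-lesion selection under both criteria sets.
EXCLUDED_SITES = {OrganSite.BONE, OrganSite.BRAIN, OrganSite.PRIMARY_TUMOUR}


class ExclusionReason(str, enum.Enum):
    BONE_METASTASIS = "bone_metastasis"
    PRIMARY_TUMOUR = "primary_tumour"
    BRAIN_METASTASIS = "brain_metastasis"
    BASELINE_UNDER_15MM = "baseline_under_15mm"
    CAVITATION_AT_EVALUATION = "cavitation_at_evaluation"
    BEAM_HARDENING_ARTEFACT = "beam_hardening_artefact"
    BASELINE_UNDER_10MM = "baseline_under_10mm"
    ORGAN_CAP_EXCEEDED = "organ_cap_exceeded"
    TOTAL_CAP_EXCEEDED = "total_cap_exceeded"


class ResponseCategory(str, enum.Enum):
    CR = "CR"
    PR = "PR"
    SD = "SD"
    PD = "PD"
    NOT_EVALUABLE = "not_evaluable"


#: Ordering used for best response over time (higher is better).
_CATEGORY_RANK = {
    ResponseCategory.CR: 4,
    ResponseCategory.PR: 3,
    ResponseCategory.SD: 2,
    ResponseCategory.PD: 1,
    ResponseCategory.NOT_EVALUABLE: 0,
}


class PRBasis(str, enum.Enum):
    SIZE_ONLY = "size_only"
    ATTENUATION_ONLY = "attenuation_only"
    BOTH = "both"
    NONE = "none"


class CriteriaSet(str, enum.Enum):
    RECIST = "recist"
    CHOI = "choi"
    CHOI_SIZE_ONLY = "choi_size_only"
    CHOI_ATTENUATION_ONLY = "choi_attenuation_only"


class CensorReason(str, enum.Enum):
    NONE = "none"
    LAST_FOLLOWUP = "last_followup"
    LAST_ADEQUATE_ASSESSMENT = "last_adequate_assessment"


class Endpoint(str, enum.Enum):
    PFS = "PFS"
    OS = "OS"


@dataclass(frozen=True)
class LesionMeasurement:
    """One lesion measured on one scan.

    ``mean_attenuation_hu`` may be ``None`` when the lesion vanished or the
    attenuation could not be measured (cavitation, artefact).
    """

    lesion_id: str
    organ_site: OrganSite
    longest_diameter_mm: float
    mean_attenuation_hu: Optional[float] = None
    cavitated: bool = False
    artefact: bool = False
    is_new: bool = False

    def __post_init__(self) -> None:
        if self.longest_diameter_mm < 0:
            raise ValueError(
                f"lesion {self.lesion_id}: diameter must be >= 0 mm, "
                f"got {self.longest_diameter_mm}"
            )


@dataclass(frozen=True)
class Scan:
    """All target-lesion measurements from one CT timepoint."""

    months_from_start: float
    lesions: tuple[LesionMeasurement, ...]
    new_lesions: bool = False

    def lesion_map(self) -> dict[str, LesionMeasurement]:
        return {les.lesion_id: les for les in self.lesions}


@dataclass
class PatientTimeline:
    """Baseline and follow-up scans plus clinical event dates for one patient.

    The first scan is the baseline (months_from_start <= 0); scans are kept
    sorted by time. Event fields are ``None`` when unobserved.
    """

    patient_id: str
    scans: list[Scan]
    clinical_pd_months: Optional[float] = None
    death_months: Optional[float] = None
    death_due_to_pd: bool = False
    last_followup_months: float = 0.0

    def __post_init__(self) -> None:
        if not self.scans:
            raise ValueError(f"patient {self.patient_id}: no scans")
        self.scans = sorted(self.scans, key=lambda s: s.months_from_start)
        if self.scans[0].months_from_start > 0:
            raise ValueError(
                f"patient {self.patient_id}: first scan must be baseline "
                f"(months_from_start <= 0)"
            )
        for t in (self.clinical_pd_months, self.death_months):
            if t is not None and t < 0:
                raise ValueError(
                    f"patient {self.patient_id}: event before treatment start"
                )
        observed = [s.months_from_start for s in self.scans]
        observed += [
            t for t in (self.clinical_pd_months, self.death_months) if t is not None
        ]
        if self.last_followup_months < max(observed):
            raise ValueError(
                f"patient {self.patient_id}: last_followup_months earlier than a "
                f"recorded event"
            )

    @property
    def baseline(self) -> Scan:
        return self.scans[0]

    @property
    def followups(self) -> list[Scan]:
        return self.scans[1:]


@dataclass(frozen=True)
class ResponseAssessment:
    """Per-patient classification at one timepoint under one criteria set."""

    patient_id: str
    months_from_start: float
    criteria: CriteriaSet
    category: ResponseCategory
    size_pct_change: Optional[float] = None
    attenuation_pct_change: Optional[float] = None
    pr_basis: PRBasis = PRBasis.NONE

    def rank(self) -> int:
        return _CATEGORY_RANK[self.category]


@dataclass(frozen=True)
class SurvivalEndpoint:
    """Derived (time, event) pair for PFS or OS with the censoring reason."""

    patient_id: str
    endpoint: Endpoint
    time_months: float
    event: bool
    censor_reason: CensorReason = CensorReason.NONE

    def __post_init__(self) -> None:
        if self.time_months < 0:
            raise ValueError("survival time must be >= 0")
        if self.event and self.censor_reason is not CensorReason.NONE:
            raise ValueError("event=True requires censor_reason='none'")


@dataclass(frozen=True)
class CriteriaThresholds:
    """All classification cut-offs in one place.

    Defaults are the published constants: RECIST 1.0 PR at -30% / PD at +20%
    on the sum of longest diameters; Choi PR at -10% size or -15% attenuation,
    PD at +10% size; size floors of 10 mm (RECIST) and 15 mm (Choi); the
    12-week stable-disease window for clinical benefit; target-lesion caps of
    10 overall and 5 per organ.
    """

    recist_pr_pct: float = -30.0
    recist_pd_pct: float = 20.0
    choi_pr_size_pct: float = -10.0
    choi_pr_attenuation_pct: float = -15.0
    choi_pd_size_pct: float = 10.0
    choi_min_diameter_mm: float = 15.0
    recist_min_diameter_mm: float = 10.0
    clinical_benefit_weeks: float = 12.0
    max_lesions: int = 10
    max_per_organ: int = 5

    def __post_init__(self) -> None:
        if not (self.recist_pr_pct < 0 and self.choi_pr_size_pct < 0
                and self.choi_pr_attenuation_pct < 0):
            raise ValueError("PR thresholds must be negative percent changes")
        if not (self.recist_pd_pct > 0 and self.choi_pd_size_pct > 0):
            raise ValueError("PD thresholds must be positive percent changes")
        if self.max_lesions <= 0 or self.max_per_organ <= 0:
            raise ValueError("lesion caps must be positive")

    @property
    def clinical_benefit_months(self) -> float:
        return self.clinical_benefit_weeks * 7.0 / DAYS_PER_MONTH


# convenience re-export for callers building variants
__all__.append("replace")
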