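"""Target-lesion selection and exclusion accounting.

Selects the lesions that enter the RECIST and Choi analyses and records why
each remaining lesion was excluded, reproducing the study-style exclusion
taxonomy:

* bone and brain metastases and the primary tumour are excluded from both
  criteria sets;
* baseline longest diameter < 10 mm excludes from both; 10 mm <= d < 15 mm is
  measurable by RECIST but below the Choi size floor;
* cavitation or a beam-hardening artefact at evaluation removes a lesion from
  the Choi (attenuation) analysis only;
* at most 10 target lesions per patient, at most 5 per organ, keeping the
  largest baseline diameters (ties broken by lesion_id order).

Boundary conventions are inclusive exactly as printed: 15.0 mm is
Choi-eligible, 10.0 mm RECIST-eligible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .datatypes import (
    EXCLUDED_SITES,
    CriteriaThresholds,
    ExclusionReason,
    LesionMeasurement,
    OrganSite,
)

__all__ = [
    "EligibilityResult",
    "select_targets",
    "attenuation_evaluable",
    "exclusion_tally",
]

_SITE_REASON = {
    OrganSite.BONE: ExclusionReason.BONE_METASTASIS,
    OrganSite.BRAIN: ExclusionReason.BRAIN_METASTASIS,
    OrganSite.PRIMARY_TUMOUR: ExclusionReason.PRIMARY_TUMOUR,
}


@dataclass
class EligibilityResult:
    """Per-patient target-lesion selection for both criteria sets.

    ``exclusions`` maps each lesion that is missing from at least one
    criteria set to the governing reason; lesions included in both sets do
    not appear in it.
    """

    included_recist: list[str] = field(default_factory=list)
    included_choi: list[str] = field(default_factory=list)
    exclusions: dict[str, ExclusionReason] = field(default_factory=dict)
    attenuation_evaluable_ids: list[str] = field(default_factory=list)

    @property
    def choi_evaluable(self) -> bool:
        """Patient has at least one Choi-eligible baseline target lesion."""
        return bool(self.included_choi)


def attenuation_evaluable(
    baseline: LesionMeasurement,
    evaluation: Optional[LesionMeasurement],
    thresholds: CriteriaThresholds = CriteriaThresholds(),
) -> bool:
    """Whether a Choi-included lesion contributes to the attenuation change.

    A lesion that shrinks below the 15 mm floor at evaluation, cavitates,
    shows a beam-hardening artefact, or vanishes keeps contributing to the
    size change but is dropped from the attenuation analysis.
    """
    if evaluation is None:
        return False
    if evaluation.longest_diameter_mm < thresholds.choi_min_diameter_mm:
        return False
    if evaluation.cavitated or evaluation.artefact:
        return False
    return evaluation.mean_attenuation_hu is not None


def _apply_caps(
    ordered_ids: list[str],
    lesions: dict[str, LesionMeasurement],
    thresholds: CriteriaThresholds,
) -> tuple[list[str], dict[str, ExclusionReason]]:
    """Keep <= max_lesions total and <= max_per_organ per organ.

    ``ordered_ids`` must already be sorted by descending baseline diameter
    (ties by input order), so truncation keeps the largest lesions.
    """
    kept: list[str] = []
    dropped: dict[str, ExclusionReason] = {}
    per_organ: dict[OrganSite, int] = {}
    for lid in ordered_ids:
        site = lesions[lid].organ_site
        if len(kept) >= thresholds.max_lesions:
            dropped[lid] = ExclusionReason.TOTAL_CAP_EXCEEDED
        elif per_organ.get(site, 0) >= thresholds.max_per_organ:
            dropped[lid] = ExclusionReason.ORGAN_CAP_EXCEEDED
        else:
            kept.append(lid)
            per_organ[site] = per_organ.get(site, 0) + 1
    return kept, dropped


def select_targets(
    baseline_lesions: Sequence[LesionMeasurement],
    evaluation_lesions: Sequence[LesionMeasurement],
    thresholds: CriteriaThresholds = CriteriaThresholds(),
) -> EligibilityResult:
    """Select target lesions for RECIST and Choi and record exclusions.

    ``evaluation_lesions`` are matched to baseline by lesion_id; a baseline
    lesion with no evaluation entry has vanished (diameter 0 for size change,
    not evaluable for attenuation). Evaluation lesions flagged ``is_new`` are
    new disease, not targets. Any other unmatched evaluation id is an error.
    """
    baseline = {}
    for les in baseline_lesions:
        if les.lesion_id in baseline:
            raise ValueError(f"duplicate lesion_id {les.lesion_id!r} at baseline")
        baseline[les.lesion_id] = les
    evaluation = {}
    for les in evaluation_lesions:
        if les.is_new:
            continue
        if les.lesion_id in evaluation:
            raise ValueError(f"duplicate lesion_id {les.lesion_id!r} at evaluation")
        if les.lesion_id not in baseline:
            raise ValueError(
                f"evaluation lesion {les.lesion_id!r} has no baseline match "
                f"and is not flagged is_new"
            )
        evaluation[les.lesion_id] = les

    result = EligibilityResult()
    recist_candidates: list[str] = []
    choi_only_reason: dict[str, ExclusionReason] = {}

    for lid, les in baseline.items():
        ev = evaluation.get(lid)
        if les.organ_site in EXCLUDED_SITES:
            result.exclusions[lid] = _SITE_REASON[les.organ_site]
            continue
        if les.longest_diameter_mm < thresholds.recist_min_diameter_mm:
            result.exclusions[lid] = ExclusionReason.BASELINE_UNDER_10MM
            continue
        recist_candidates.append(lid)
        if les.longest_diameter_mm < thresholds.choi_min_diameter_mm:
            choi_only_reason[lid] = ExclusionReason.BASELINE_UNDER_15MM
        elif ev is not None and ev.cavitated:
            choi_only_reason[lid] = ExclusionReason.CAVITATION_AT_EVALUATION
        elif ev is not None and ev.artefact:
            choi_only_reason[lid] = ExclusionReason.BEAM_HARDENING_ARTEFACT

    # caps keep the largest baseline diameters; ties by input order
    recist_candidates.sort(
        key=lambda lid: -baseline[lid].longest_diameter_mm
    )
    result.included_recist, cap_dropped = _apply_caps(
        recist_candidates, baseline, thresholds
    )
    result.exclusions.update(cap_dropped)

    result.included_choi = [
        lid for lid in result.included_recist if lid not in choi_only_reason
    ]
    for lid, reason in choi_only_reason.items():
        if lid in result.included_recist:
            result.exclusions[lid] = reason

    result.attenuation_evaluable_ids = [
        lid for lid in result.included_choi
        if attenuation_evaluable(baseline[lid], evaluation.get(lid), thresholds)
    ]
    return result


def exclusion_tally(results: Sequence[EligibilityResult]) -> pd.DataFrame:
    """Aggregate exclusion counts by reason plus eligible totals.

    Returns a table with one row per exclusion reason and two total rows
    (``recist_eligible``, ``choi_eligible``), in the style of a study lesion
    accounting table.
    """
    counts = {reason.value: 0 for reason in ExclusionReason}
    n_recist = 0
    n_choi = 0
    for res in results:
        n_recist += len(res.included_recist)
        n_choi += len(res.included_choi)
        for reason in res.exclusions.values():
            counts[reason.value] += 1
    rows = [{"reason": k, "n_lesions": v} for k, v in counts.items()]
    rows.append({"reason": "recist_eligible", "n_lesions": n_recist})
    rows.append({"reason": "choi_eligible", "n_lesions": n_choi})
    return pd.DataFrame(rows)
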