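"""Synthetic cohort generation.

Generates patient cohorts with the lesion-level and survival structure the
response-criteria analysis expects, so every downstream stage is testable
without external data. The generator emulates a metastatic renal cell cancer
cohort under an anti-angiogenic tyrosine kinase inhibitor:

* per-patient lesion counts, organ sites, log-normal baseline sizes and
  clipped-normal baseline attenuations, stratified by site;
* a responder / non-responder mixture: responders receive a marked
  attenuation drop with modest shrinkage at the first evaluation (the
  necrosis-over-shrinkage pattern), non-responders mild growth with little
  attenuation change;
* response-coupled survival: progression-free survival drawn from a
  phenotype-specific distribution, overall survival as PFS plus an
  independent post-progression survival (so OS >= PFS by construction),
  then administrative censoring;
* occasional cavitation of lung lesions and beam-hardening artefacts at
  evaluation, and new lesions in a fraction of non-responders.

All randomness flows from a single integer seed; each patient uses an
independent sub-stream keyed by patient index, so enlarging a cohort never
reshuffles existing patients.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .datatypes import (
    LesionMeasurement,
    OrganSite,
    PatientTimeline,
    Scan,
)

__all__ = [
    "CohortConfig",
    "SyntheticCohort",
    "PatientTruth",
    "default_config",
    "generate_cohort",
    "generate_lesion_fixture",
    "write_cohort",
    "load_cohort",
]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

class RangeSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")
    min: int = Field(ge=0)
    max: int = Field(ge=0)

    @model_validator(mode="after")
    def _ordered(self) -> "RangeSpec":
        if self.min > self.max:
            raise ValueError("lesions_per_patient: min must be <= max")
        return self


class LogNormalSpec(BaseModel):
    """Log-normal with a stated median: ln X ~ N(ln median, sigma^2)."""

    model_config = ConfigDict(extra="forbid")
    median: float = Field(gt=0)
    sigma: float = Field(gt=0)


class NormalSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")
    mean: float
    sd: float = Field(gt=0)


class EffectSpec(BaseModel):
    """Patient-level percent-change effect with per-lesion noise on top."""

    model_config = ConfigDict(extra="forbid")
    size_pct_mean: float
    size_pct_sd: float = Field(ge=0)
    attenuation_pct_mean: float
    attenuation_pct_sd: float = Field(ge=0)
    lesion_size_pct_sd: float = Field(ge=0)
    lesion_attenuation_pct_sd: float = Field(ge=0)


class SurvivalSpec(BaseModel):
    """Exponential survival per phenotype, parameterised by the median."""

    model_config = ConfigDict(extra="forbid")
    distribution: str = "exponential"
    responder_median: float = Field(gt=0)
    nonresponder_median: float = Field(gt=0)

    @model_validator(mode="after")
    def _known_dist(self) -> "SurvivalSpec":
        if self.distribution != "exponential":
            raise ValueError("distribution: only 'exponential' is supported")
        return self


class CohortConfig(BaseModel):
    """Full generative specification of a synthetic cohort."""

    model_config = ConfigDict(extra="forbid")

    config_version: str = "1.0"
    n_patients: int = Field(ge=0)
    responder_fraction: float = Field(ge=0, le=1)
    site_mix: dict[OrganSite, float]
    lesions_per_patient: RangeSpec
    baseline_size_mm: dict[OrganSite, LogNormalSpec]
    baseline_attenuation_hu: dict[OrganSite, NormalSpec]
    hu_clip: tuple[float, float] = (-50.0, 400.0)
    responder_effect: EffectSpec
    nonresponder_effect: EffectSpec
    pfs_months: SurvivalSpec
    os_months: SurvivalSpec
    followup_admin_censor_months: float = Field(gt=0)
    first_eval_months: tuple[float, float]
    followup_interval_months: float = Field(default=3.0, gt=0)
    max_followup_scans: int = Field(default=3, ge=1)
    new_lesion_prob_nonresponder: float = Field(default=0.25, ge=0, le=1)
    cavitation_prob_lung: float = Field(default=0.08, ge=0, le=1)
    artefact_prob: float = Field(default=0.025, ge=0, le=1)
    seed: int = 0

    @model_validator(mode="after")
    def _consistent(self) -> "CohortConfig":
        total = sum(self.site_mix.values())
        if not math.isclose(total, 1.0, abs_tol=1e-6):
            raise ValueError(f"site_mix: probabilities sum to {total}, not 1")
        if any(p < 0 for p in self.site_mix.values()):
            raise ValueError("site_mix: probabilities must be >= 0")
        lo, hi = self.first_eval_months
        if not (0 < lo <= hi):
            raise ValueError("first_eval_months: need 0 < min <= max")
        if self.hu_clip[0] >= self.hu_clip[1]:
            raise ValueError("hu_clip: lower bound must be below upper bound")
        missing = set(self.site_mix) - set(self.baseline_size_mm)
        if missing:
            raise ValueError(f"baseline_size_mm: missing sites {sorted(missing)}")
        missing = set(self.site_mix) - set(self.baseline_attenuation_hu)
        if missing:
            raise ValueError(
                f"baseline_attenuation_hu: missing sites {sorted(missing)}"
            )
        # OS must stochastically dominate PFS within each phenotype
        if (self.os_months.responder_median < self.pfs_months.responder_median
                or self.os_months.nonresponder_median
                < self.pfs_months.nonresponder_median):
            raise ValueError("os_months: median OS must be >= median PFS")
        return self

    @classmethod
    def from_json(cls, path: str | Path) -> "CohortConfig":
        return cls.model_validate(json.loads(Path(path).read_text()))


def default_config(**overrides) -> CohortConfig:
    """The versioned default configuration shipped with the package."""
    raw = json.loads(
        resources.files("respcrit.data")
        .joinpath("default_cohort_config.json")
        .read_text()
    )
    raw.update(overrides)
    return CohortConfig.model_validate(raw)


# ---------------------------------------------------------------------------
# Cohort containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PatientTruth:
    """Generative ground truth for one synthetic patient."""

    patient_id: str
    responder: bool
    true_pfs_months: float
    true_os_months: float


@dataclass
class SyntheticCohort:
    patients: list[PatientTimeline]
    truth: dict[str, PatientTruth]
    config: CohortConfig

    def __post_init__(self) -> None:
        ids = {p.patient_id for p in self.patients}
        if set(self.truth) != ids:
            raise ValueError("truth labels must cover every patient id exactly once")


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _patient_rng(seed: int, index: int) -> np.random.Generator:
    # independent sub-stream per patient: cohorts extend without reshuffling
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index,)))


def _exponential(rng: np.random.Generator, median: float) -> float:
    return float(rng.exponential(median / math.log(2.0)))


def _evolve_lesion(
    les: LesionMeasurement,
    size_pct: float,
    atten_pct: float,
    cavitated: bool,
    artefact: bool,
) -> Optional[LesionMeasurement]:
    """Apply a percent effect to one lesion; returns None if it vanished."""
    new_d = les.longest_diameter_mm * (1.0 + size_pct / 100.0)
    if new_d < 0.5:  # below CT resolution: lesion vanished
        return None
    hu = les.mean_attenuation_hu
    new_hu = None if hu is None else hu * (1.0 + atten_pct / 100.0)
    if cavitated or artefact:
        new_hu = None
    return LesionMeasurement(
        lesion_id=les.lesion_id,
        organ_site=les.organ_site,
        longest_diameter_mm=round(new_d, 1),
        mean_attenuation_hu=None if new_hu is None else round(new_hu, 1),
        cavitated=cavitated,
        artefact=artefact,
    )


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a deterministic synthetic cohort from ``config``.

    Scan schedule per patient: a baseline scan at month 0, a first evaluation
    at a uniform time in ``first_eval_months``, then further evaluations every
    ``followup_interval_months`` (up to ``max_followup_scans`` total
    follow-ups) while the patient is progression-free and on follow-up.
    Treatment effects deepen on later scans, so a slow responder can cross a
    response threshold after the first evaluation.
    """
    sites = list(config.site_mix)
    probs = np.array([config.site_mix[s] for s in sites], dtype=float)
    probs = probs / probs.sum()
    hu_lo, hu_hi = config.hu_clip

    patients: list[PatientTimeline] = []
    truth: dict[str, PatientTruth] = {}
    for i in range(config.n_patients):
        rng = _patient_rng(config.seed, i)
        pid = f"P{i:04d}"
        responder = bool(rng.random() < config.responder_fraction)
        effect = config.responder_effect if responder else config.nonresponder_effect

        pfs_median = (config.pfs_months.responder_median if responder
                      else config.pfs_months.nonresponder_median)
        os_median = (config.os_months.responder_median if responder
                     else config.os_months.nonresponder_median)
        true_pfs = _exponential(rng, pfs_median)
        # OS = PFS + independent post-progression survival (median difference)
        true_os = true_pfs + _exponential(rng, os_median - pfs_median + 1e-9)

        t_first = float(rng.uniform(*config.first_eval_months))
        # cohort is conditioned on having a first-evaluation scan, mirroring
        # the eligibility requirement of baseline + first-evaluation imaging
        true_os = max(true_os, t_first + 0.1)

        n_lesions = int(rng.integers(config.lesions_per_patient.min,
                                     config.lesions_per_patient.max + 1))
        baseline_lesions: list[LesionMeasurement] = []
        for j in range(n_lesions):
            site = sites[int(rng.choice(len(sites), p=probs))]
            size_spec = config.baseline_size_mm[site]
            hu_spec = config.baseline_attenuation_hu[site]
            d = float(np.exp(rng.normal(math.log(size_spec.median),
                                        size_spec.sigma)))
            hu = float(np.clip(rng.normal(hu_spec.mean, hu_spec.sd),
                               hu_lo, hu_hi))
            baseline_lesions.append(LesionMeasurement(
                lesion_id=f"{pid}-L{j:02d}",
                organ_site=site,
                longest_diameter_mm=round(d, 1),
                mean_attenuation_hu=round(hu, 1),
            ))

        # patient-level effect; per-lesion noise drawn once and reused so
        # later scans deepen the same per-lesion trajectory
        size_eff = float(rng.normal(effect.size_pct_mean, effect.size_pct_sd))
        atten_eff = float(rng.normal(effect.attenuation_pct_mean,
                                     effect.attenuation_pct_sd))
        size_noise = rng.normal(0.0, effect.lesion_size_pct_sd, n_lesions)
        atten_noise = rng.normal(0.0, effect.lesion_attenuation_pct_sd, n_lesions)
        cavit = np.array([
            les.organ_site is OrganSite.LUNG
            and rng.random() < config.cavitation_prob_lung
            for les in baseline_lesions
        ])
        artef = np.array([rng.random() < config.artefact_prob
                          for les in baseline_lesions])

        admin = config.followup_admin_censor_months
        last_followup = min(true_os, admin)
        death = true_os if true_os <= admin else None
        clinical_pd = true_pfs if true_pfs <= last_followup else None

        scan_times = [t_first]
        t = t_first
        while (len(scan_times) < config.max_followup_scans
               and t + config.followup_interval_months < min(true_pfs,
                                                             last_followup)):
            t += config.followup_interval_months
            scan_times.append(t)

        new_lesions_first = (not responder
                             and rng.random()
                             < config.new_lesion_prob_nonresponder)

        scans = [Scan(0.0, tuple(baseline_lesions))]
        for k, t_scan in enumerate(scan_times):
            # effect deepens 40% per additional evaluation, saturating at -100%
            depth = 1.0 + 0.4 * k
            lesions = []
            for j, les in enumerate(baseline_lesions):
                evolved = _evolve_lesion(
                    les,
                    max(-100.0, (size_eff + size_noise[j]) * depth),
                    max(-100.0, (atten_eff + atten_noise[j]) * depth),
                    bool(cavit[j]),
                    bool(artef[j]),
                )
                if evolved is not None:
                    lesions.append(evolved)
            new_flag = new_lesions_first and k == 0
            if new_flag:
                lesions.append(LesionMeasurement(
                    lesion_id=f"{pid}-N00",
                    organ_site=OrganSite.LUNG,
                    longest_diameter_mm=12.0,
                    mean_attenuation_hu=45.0,
                    is_new=True,
                ))
            scans.append(Scan(round(t_scan, 2), tuple(lesions),
                              new_lesions=new_flag))

        patients.append(PatientTimeline(
            patient_id=pid,
            scans=scans,
            clinical_pd_months=clinical_pd,
            death_months=death,
            death_due_to_pd=death is not None,
            last_followup_months=last_followup,
        ))
        truth[pid] = PatientTruth(pid, responder, true_pfs, true_os)

    return SyntheticCohort(patients, truth, config)


# ---------------------------------------------------------------------------
# Lesion fixtures for eligibility testing
# ---------------------------------------------------------------------------

_FIXTURE_KINDS = ("sub15mm", "bone", "brain", "primary", "cavitated",
                  "artefact", "eligible")


def generate_lesion_fixture(
    kind: str,
) -> tuple[LesionMeasurement, LesionMeasurement]:
    """A (baseline, evaluation) pair triggering exactly one eligibility outcome."""
    if kind not in _FIXTURE_KINDS:
        raise ValueError(f"unknown fixture kind {kind!r}; one of {_FIXTURE_KINDS}")
    site = OrganSite.LUNG
    baseline_d, eval_d = 48.0, 39.0
    hu_b, hu_e = 107.0, 65.0
    cavitated = artefact = False
    if kind == "sub15mm":
        baseline_d, eval_d = 12.0, 10.0
    elif kind == "bone":
        site = OrganSite.BONE
    elif kind == "brain":
        site = OrganSite.BRAIN
    elif kind == "primary":
        site = OrganSite.PRIMARY_TUMOUR
    elif kind == "cavitated":
        cavitated = True
    elif kind == "artefact":
        artefact = True
    baseline = LesionMeasurement("FX0", site, baseline_d, hu_b)
    evaluation = LesionMeasurement(
        "FX0", site, eval_d,
        None if (cavitated or artefact) else hu_e,
        cavitated=cavitated, artefact=artefact,
    )
    return baseline, evaluation


# ---------------------------------------------------------------------------
# Serialisation: lesions.csv + patients.csv (+ truth.csv for synthetic runs)
# ---------------------------------------------------------------------------

LESION_COLUMNS = [
    "patient_id", "scan_id", "months_from_start", "lesion_id", "organ_site",
    "longest_diameter_mm", "mean_attenuation_hu", "cavitated", "artefact",
    "is_new",
]
PATIENT_COLUMNS = [
    "patient_id", "treatment_start_offset_months", "clinical_pd_months",
    "death_months", "death_due_to_pd", "last_followup_months",
]


def cohort_frames(
    patients: list[PatientTimeline],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flatten timelines into the two canonical tables."""
    lesion_rows = []
    patient_rows = []
    for p in patients:
        for s_idx, scan in enumerate(p.scans):
            for les in scan.lesions:
                lesion_rows.append({
                    "patient_id": p.patient_id,
                    "scan_id": f"S{s_idx}",
                    "months_from_start": scan.months_from_start,
                    "lesion_id": les.lesion_id,
                    "organ_site": les.organ_site.value,
                    "longest_diameter_mm": les.longest_diameter_mm,
                    "mean_attenuation_hu": les.mean_attenuation_hu,
                    "cavitated": les.cavitated,
                    "artefact": les.artefact,
                    "is_new": les.is_new,
                })
        patient_rows.append({
            "patient_id": p.patient_id,
            "treatment_start_offset_months": 0.0,
            "clinical_pd_months": p.clinical_pd_months,
            "death_months": p.death_months,
            "death_due_to_pd": p.death_due_to_pd,
            "last_followup_months": p.last_followup_months,
        })
    lesions = pd.DataFrame(lesion_rows, columns=LESION_COLUMNS)
    pats = pd.DataFrame(patient_rows, columns=PATIENT_COLUMNS)
    return lesions, pats


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lesions, pats = cohort_frames(cohort.patients)
    lesions.to_csv(out / "lesions.csv", index=False)
    pats.to_csv(out / "patients.csv", index=False)
    truth = pd.DataFrame(
        [{"patient_id": t.patient_id, "responder": t.responder,
          "true_pfs_months": t.true_pfs_months,
          "true_os_months": t.true_os_months}
         for t in cohort.truth.values()]
    )
    truth.to_csv(out / "truth.csv", index=False)


def _opt(value) -> Optional[float]:
    return None if pd.isna(value) else float(value)


def load_cohort(in_dir: str | Path) -> list[PatientTimeline]:
    """Read ``lesions.csv`` + ``patients.csv`` back into patient timelines."""
    in_dir = Path(in_dir)
    lesions = pd.read_csv(in_dir / "lesions.csv")
    pats = pd.read_csv(in_dir / "patients.csv")
    timelines = []
    for _, prow in pats.iterrows():
        pid = prow["patient_id"]
        sub = lesions[lesions["patient_id"] == pid]
        scans = []
        for t, scan_rows in sub.groupby("months_from_start", sort=True):
            lesion_list = tuple(
                LesionMeasurement(
                    lesion_id=str(r["lesion_id"]),
                    organ_site=OrganSite(r["organ_site"]),
                    longest_diameter_mm=float(r["longest_diameter_mm"]),
                    mean_attenuation_hu=_opt(r["mean_attenuation_hu"]),
                    cavitated=bool(r["cavitated"]),
                    artefact=bool(r["artefact"]),
                    is_new=bool(r["is_new"]),
                )
                for _, r in scan_rows.iterrows()
            )
            scans.append(Scan(float(t), lesion_list,
                              new_lesions=any(l.is_new for l in lesion_list)))
        timelines.append(PatientTimeline(
            patient_id=str(pid),
            scans=scans,
            clinical_pd_months=_opt(prow["clinical_pd_months"]),
            death_months=_opt(prow["death_months"]),
            death_due_to_pd=bool(prow["death_due_to_pd"]),
            last_followup_months=float(prow["last_followup_months"]),
        ))
    return timelines
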