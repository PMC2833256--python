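"""Pipeline orchestration and paper-shaped summary reporting.

Chains the stages simulate -> filter -> classify -> survive and renders the
summary artefacts an early-response study reports: the RECIST x Choi response
cross-tabulation, the lesion exclusion tally, the per-site size/attenuation
change summary, the survival comparison per response grouping, and
Kaplan-Meier curves.

Display rounding follows the usual table precision: percentages and
HU/mm medians to the nearest integer, months to one decimal. All
classification happens on unrounded values.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import response_criteria as rc
from . import survival_stats as ss
from .datatypes import (
    CensorReason,
    CriteriaSet,
    CriteriaThresholds,
    Endpoint,
    LesionMeasurement,
    PatientTimeline,
    PRBasis,
    ResponseAssessment,
    ResponseCategory,
    SurvivalEndpoint,
)
from .eligibility import EligibilityResult, exclusion_tally, select_targets
from .synthetic_cohort import (
    CohortConfig,
    generate_cohort,
    load_cohort,
    write_cohort,
)

logger = logging.getLogger("respcrit")

__all__ = [
    "RunConfig",
    "PatientAssessments",
    "assess_patient",
    "assess_cohort",
    "crosstab_responses",
    "site_change_summary",
    "survival_comparison",
    "run_pipeline",
]

_CATEGORIES = ["CR", "PR", "SD", "PD", "not_evaluable"]


# ---------------------------------------------------------------------------
# Per-patient classification across all criteria sets and timepoints
# ---------------------------------------------------------------------------

@dataclass
class PatientAssessments:
    """Everything the classifier derives for one patient."""

    patient_id: str
    eligibility: EligibilityResult
    assessments: list[ResponseAssessment] = field(default_factory=list)

    def by(self, criteria: CriteriaSet) -> list[ResponseAssessment]:
        return [a for a in self.assessments if a.criteria is criteria]

    def first_eval(self, criteria: CriteriaSet) -> Optional[ResponseAssessment]:
        seq = self.by(criteria)
        return seq[0] if seq else None


def _sum_for(
    ids: Sequence[str], lesion_map: dict[str, LesionMeasurement]
) -> float:
    # vanished lesions (absent at this scan) contribute 0 mm
    return float(sum(lesion_map[i].longest_diameter_mm
                     for i in ids if i in lesion_map))


def _mean_hu_for(
    ids: Sequence[str], lesion_map: dict[str, LesionMeasurement]
) -> Optional[float]:
    vals = [lesion_map[i].mean_attenuation_hu for i in ids
            if i in lesion_map and lesion_map[i].mean_attenuation_hu is not None
            and not lesion_map[i].cavitated and not lesion_map[i].artefact]
    return float(np.mean(vals)) if vals else None


def assess_patient(
    timeline: PatientTimeline,
    thresholds: CriteriaThresholds = CriteriaThresholds(),
) -> PatientAssessments:
    """Classify one patient at every follow-up scan under all criteria sets.

    Target-lesion eligibility is decided once, from the baseline scan and the
    first evaluation (cavitation and artefacts declare themselves there). The
    RECIST PD reference is the nadir: the smallest diameter sum recorded at or
    after treatment start.
    """
    baseline = timeline.baseline
    followups = timeline.followups
    if not followups:
        raise ValueError(f"patient {timeline.patient_id}: no follow-up scan")

    elig = select_targets(baseline.lesions, followups[0].lesions, thresholds)
    out = PatientAssessments(timeline.patient_id, elig)

    base_map = baseline.lesion_map()
    recist_base = _sum_for(elig.included_recist, base_map)
    choi_base = _sum_for(elig.included_choi, base_map)
    hu_base = _mean_hu_for(elig.attenuation_evaluable_ids, base_map)

    nadir = recist_base if recist_base > 0 else None
    for scan in followups:
        ev_map = scan.lesion_map()
        t = scan.months_from_start

        # --- RECIST ---
        if recist_base > 0:
            ev_sum = _sum_for(elig.included_recist, ev_map)
            all_gone = ev_sum == 0.0
            cat = rc.classify_recist(
                recist_base, ev_sum, nadir, scan.new_lesions, all_gone,
                thresholds,
            )
            size_pct = rc.percent_change(recist_base, ev_sum)
            nadir = min(nadir, ev_sum) if ev_sum > 0 else nadir
            out.assessments.append(ResponseAssessment(
                timeline.patient_id, t, CriteriaSet.RECIST, cat,
                size_pct_change=size_pct,
            ))
        else:
            out.assessments.append(ResponseAssessment(
                timeline.patient_id, t, CriteriaSet.RECIST,
                ResponseCategory.NOT_EVALUABLE,
            ))

        # --- Choi (combined and separate criteria) ---
        if choi_base > 0:
            ev_sum_c = _sum_for(elig.included_choi, ev_map)
            size_pct_c = rc.percent_change(choi_base, ev_sum_c)
            hu_eval = _mean_hu_for(elig.attenuation_evaluable_ids, ev_map)
            atten_pct = (rc.percent_change(hu_base, hu_eval)
                         if hu_base is not None and hu_base > 0
                         and hu_eval is not None else None)
            all_gone_c = ev_sum_c == 0.0
            cat, basis = rc.classify_choi(
                size_pct_c, atten_pct, scan.new_lesions, all_gone_c,
                thresholds=thresholds,
            )
            out.assessments.append(ResponseAssessment(
                timeline.patient_id, t, CriteriaSet.CHOI, cat,
                size_pct_change=size_pct_c, attenuation_pct_change=atten_pct,
                pr_basis=basis,
            ))
            for mode, crit in (
                ("size_only", CriteriaSet.CHOI_SIZE_ONLY),
                ("attenuation_only", CriteriaSet.CHOI_ATTENUATION_ONLY),
            ):
                cat_m = rc.classify_choi_separate(
                    size_pct_c, atten_pct, scan.new_lesions, thresholds, mode,
                )
                out.assessments.append(ResponseAssessment(
                    timeline.patient_id, t, crit, cat_m,
                    size_pct_change=size_pct_c,
                    attenuation_pct_change=atten_pct,
                ))
        else:
            for crit in (CriteriaSet.CHOI, CriteriaSet.CHOI_SIZE_ONLY,
                         CriteriaSet.CHOI_ATTENUATION_ONLY):
                out.assessments.append(ResponseAssessment(
                    timeline.patient_id, t, crit,
                    ResponseCategory.NOT_EVALUABLE,
                ))
    return out


def assess_cohort(
    patients: Sequence[PatientTimeline],
    thresholds: CriteriaThresholds = CriteriaThresholds(),
) -> list[PatientAssessments]:
    return [assess_patient(p, thresholds) for p in patients]


# ---------------------------------------------------------------------------
# Summary tables
# ---------------------------------------------------------------------------

def crosstab_responses(
    recist: Sequence[ResponseAssessment],
    choi: Sequence[ResponseAssessment],
) -> pd.DataFrame:
    """Category cross-tabulation (RECIST rows x Choi columns) with margins.

    Besides the raw 5x5 grid the table carries a responder/non-responder
    dichotomy margin (responders = CR + PR).
    """
    r_by_pid = {a.patient_id: a for a in recist}
    c_by_pid = {a.patient_id: a for a in choi}
    if set(r_by_pid) != set(c_by_pid):
        raise ValueError("RECIST and Choi assessments cover different patients")
    cats = pd.DataFrame({
        "recist": [r_by_pid[p].category.value for p in sorted(r_by_pid)],
        "choi": [c_by_pid[p].category.value for p in sorted(r_by_pid)],
    })
    tab = pd.crosstab(cats["recist"], cats["choi"])
    tab = tab.reindex(index=_CATEGORIES, columns=_CATEGORIES, fill_value=0)
    tab.index.name = "recist"
    tab.columns.name = "choi"
    return tab


def site_change_summary(
    patients: Sequence[PatientTimeline],
    assessed: Sequence[PatientAssessments],
) -> pd.DataFrame:
    """Per-site lesion change summary over Choi-eligible lesions.

    For every organ site: lesion counts for the size and attenuation
    analyses, median baseline and first-evaluation size and attenuation, and
    median per-lesion percent changes. Vanished lesions enter the size
    analysis at 0 mm (-100%).
    """
    rows = []
    by_pid = {a.patient_id: a for a in assessed}
    for p in patients:
        elig = by_pid[p.patient_id].eligibility
        base_map = p.baseline.lesion_map()
        ev_map = p.followups[0].lesion_map()
        for lid in elig.included_choi:
            b = base_map[lid]
            e = ev_map.get(lid)
            ev_d = e.longest_diameter_mm if e is not None else 0.0
            atten_ok = lid in elig.attenuation_evaluable_ids
            hu_e = (e.mean_attenuation_hu
                    if atten_ok and e is not None else None)
            rows.append({
                "site": b.organ_site.value,
                "baseline_mm": b.longest_diameter_mm,
                "eval_mm": ev_d,
                "size_pct": rc.percent_change(b.longest_diameter_mm, ev_d),
                "baseline_hu": b.mean_attenuation_hu,
                "eval_hu": hu_e,
                "atten_pct": (rc.percent_change(b.mean_attenuation_hu, hu_e)
                              if hu_e is not None
                              and b.mean_attenuation_hu else None),
            })
    if not rows:
        return pd.DataFrame()
    df = pd.DataFrame(rows)
    out = []
    groups = [(site, g) for site, g in df.groupby("site")] + [("total", df)]
    for site, g in groups:
        atten = g.dropna(subset=["atten_pct"])
        out.append({
            "site": site,
            "n_size": len(g),
            "n_attenuation": len(atten),
            "median_baseline_mm": round(g["baseline_mm"].median()),
            "median_eval_mm": round(g["eval_mm"].median()),
            "median_size_pct": round(g["size_pct"].median()),
            "median_baseline_hu": round(g["baseline_hu"].median()),
            "median_eval_hu": (round(atten["eval_hu"].median())
                               if len(atten) else None),
            "median_atten_pct": (round(atten["atten_pct"].median())
                                 if len(atten) else None),
        })
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Survival comparison (Table-5 analogue)
# ---------------------------------------------------------------------------

def _responder_split(
    assessed: Sequence[PatientAssessments],
    grouping: str,
    endpoints_by_pid: dict[str, dict[Endpoint, SurvivalEndpoint]],
    thresholds: CriteriaThresholds,
) -> tuple[list[str], list[str]]:
    """Split patient ids into (responders, non-responders) per grouping."""
    resp, nonresp = [], []
    for pa in assessed:
        pid = pa.patient_id
        if grouping == "choi_first_eval":
            a = pa.first_eval(CriteriaSet.CHOI)
        elif grouping == "recist_first_eval":
            a = pa.first_eval(CriteriaSet.RECIST)
        elif grouping == "recist_best":
            best, _ = rc.best_response(pa.by(CriteriaSet.RECIST))
            (resp if best in (ResponseCategory.CR, ResponseCategory.PR)
             else nonresp).append(pid)
            continue
        elif grouping == "recist_clinical_benefit":
            best, _ = rc.best_response(pa.by(CriteriaSet.RECIST))
            pfs = endpoints_by_pid[pid][Endpoint.PFS].time_months
            (resp if rc.clinical_benefit(best, pfs, thresholds)
             else nonresp).append(pid)
            continue
        else:
            raise ValueError(f"unknown grouping {grouping!r}")
        if a is None or a.category is ResponseCategory.NOT_EVALUABLE:
            continue
        (resp if a.category in (ResponseCategory.CR, ResponseCategory.PR)
         else nonresp).append(pid)
    return resp, nonresp


GROUPINGS = ("choi_first_eval", "recist_first_eval", "recist_best",
             "recist_clinical_benefit")


def survival_comparison(
    assessed: Sequence[PatientAssessments],
    endpoints: Sequence[SurvivalEndpoint],
    thresholds: CriteriaThresholds = CriteriaThresholds(),
    groupings: Sequence[str] = GROUPINGS,
) -> dict:
    """KM medians and log-rank statistics per response grouping and endpoint."""
    by_pid: dict[str, dict[Endpoint, SurvivalEndpoint]] = {}
    for e in endpoints:
        by_pid.setdefault(e.patient_id, {})[e.endpoint] = e

    result: dict = {}
    for grouping in groupings:
        resp, nonresp = _responder_split(assessed, grouping, by_pid, thresholds)
        entry: dict = {"n_responders": len(resp),
                       "n_nonresponders": len(nonresp)}
        for ep in (Endpoint.PFS, Endpoint.OS):
            ga = [by_pid[p][ep] for p in resp if ep in by_pid.get(p, {})]
            gb = [by_pid[p][ep] for p in nonresp if ep in by_pid.get(p, {})]
            stats_entry: dict = {}
            if ga and gb:
                km_a = ss.km_estimate(ga)
                km_b = ss.km_estimate(gb)
                try:
                    chi2, p = ss.logrank_test(ga, gb)
                except ValueError:
                    chi2, p = None, None
                stats_entry = {
                    "median_responders": km_a.median_months,
                    "median_nonresponders": km_b.median_months,
                    "logrank_chi2": chi2,
                    "logrank_p": p,
                }
            entry[ep.value] = stats_entry
        result[grouping] = entry
    return result


# ---------------------------------------------------------------------------
# Pipeline driver
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Configuration for one pipeline run.

    Either ``simulate`` (a CohortConfig) or ``input_dir`` (pre-existing
    lesions.csv + patients.csv) must be provided.
    """

    out_dir: Path
    simulate: Optional[CohortConfig] = None
    input_dir: Optional[Path] = None
    thresholds: CriteriaThresholds = field(default_factory=CriteriaThresholds)
    seed: Optional[int] = None
    make_plots: bool = True

    def __post_init__(self) -> None:
        if self.simulate is None and self.input_dir is None:
            raise ValueError("RunConfig needs either simulate or input_dir")


def _assessments_frame(assessed: Sequence[PatientAssessments]) -> pd.DataFrame:
    rows = []
    for pa in assessed:
        for a in pa.assessments:
            rows.append({
                "patient_id": a.patient_id,
                "months": round(a.months_from_start, 2),
                "criteria": a.criteria.value,
                "category": a.category.value,
                "size_pct": (None if a.size_pct_change is None
                             else round(a.size_pct_change, 4)),
                "attenuation_pct": (None if a.attenuation_pct_change is None
                                    else round(a.attenuation_pct_change, 4)),
                "pr_basis": a.pr_basis.value,
            })
    return pd.DataFrame(rows)


def _best_response_frame(
    assessed: Sequence[PatientAssessments],
) -> pd.DataFrame:
    rows = []
    for pa in assessed:
        for crit in CriteriaSet:
            seq = pa.by(crit)
            if not seq:
                continue
            best, t_pr = rc.best_response(seq)
            rows.append({
                "patient_id": pa.patient_id,
                "criteria": crit.value,
                "best_category": best.value,
                "months_to_first_pr": (None if t_pr is None
                                       else round(t_pr, 2)),
            })
    return pd.DataFrame(rows)


def _km_plot(endpoints: Sequence[SurvivalEndpoint], assessed, thresholds,
             grouping: str, ep: Endpoint, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from lifelines import KaplanMeierFitter

    by_pid: dict[str, dict[Endpoint, SurvivalEndpoint]] = {}
    for e in endpoints:
        by_pid.setdefault(e.patient_id, {})[e.endpoint] = e
    resp, nonresp = _responder_split(assessed, grouping, by_pid, thresholds)
    fig, ax = plt.subplots(figsize=(5, 4))
    for label, pids, style in (("responders", resp, "-"),
                               ("non-responders", nonresp, "--")):
        eps = [by_pid[p][ep] for p in pids if ep in by_pid.get(p, {})]
        if not eps:
            continue
        kmf = KaplanMeierFitter()
        kmf.fit([e.time_months for e in eps], [e.event for e in eps],
                label=f"{label} (n={len(eps)})")
        kmf.plot_survival_function(ax=ax, ci_show=False, linestyle=style)
    ax.set_xlabel("months from treatment start")
    ax.set_ylabel(f"{ep.value} probability")
    ax.set_title(grouping.replace("_", " "))
    ax.set_ylim(0, 1.02)
    fig.tight_layout()
    fig.savefig(path, format="svg")
    plt.close(fig)


def run_pipeline(config: RunConfig) -> dict:
    """Execute simulate -> filter -> classify -> survive -> report.

    Writes all stage outputs under ``config.out_dir`` and returns the report
    bundle as a dict (also written as ``report.json``).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    thresholds = config.thresholds

    # --- stage 1: obtain cohort ---
    try:
        if config.simulate is not None:
            sim_cfg = config.simulate
            if config.seed is not None:
                sim_cfg = sim_cfg.model_copy(update={"seed": config.seed})
            logger.info("simulate: n=%d seed=%d", sim_cfg.n_patients,
                        sim_cfg.seed)
            cohort = generate_cohort(sim_cfg)
            write_cohort(cohort, out)
            patients = cohort.patients
        else:
            patients = load_cohort(config.input_dir)
            logger.info("loaded %d patients from %s", len(patients),
                        config.input_dir)
    except Exception as exc:
        raise RuntimeError(f"stage 'simulate/load' failed: {exc}") from exc

    if not patients:
        bundle = {"n_patients": 0}
        (out / "report.json").write_text(json.dumps(bundle, indent=2))
        return bundle

    # --- stage 2+3: eligibility + classification ---
    try:
        assessed = assess_cohort(patients, thresholds)
        elig_df = exclusion_tally([pa.eligibility for pa in assessed])
        elig_df.to_csv(out / "exclusion_tally.csv", index=False)
        _assessments_frame(assessed).to_csv(out / "responses.csv", index=False)
        _best_response_frame(assessed).to_csv(out / "best_response.csv",
                                              index=False)
    except Exception as exc:
        raise RuntimeError(f"stage 'classify' failed: {exc}") from exc

    # --- stage 4: endpoints + comparisons ---
    try:
        endpoints: list[SurvivalEndpoint] = []
        for p, pa in zip(patients, assessed):
            endpoints.append(ss.derive_pfs(p, pa.by(CriteriaSet.RECIST)))
            endpoints.append(ss.derive_os(p))
        pd.DataFrame([{
            "patient_id": e.patient_id, "endpoint": e.endpoint.value,
            "time_months": round(e.time_months, 3), "event": e.event,
            "censor_reason": e.censor_reason.value,
        } for e in endpoints]).to_csv(out / "endpoints.csv", index=False)
        comparisons = survival_comparison(assessed, endpoints, thresholds)
        (out / "comparisons.json").write_text(
            json.dumps(comparisons, indent=2))
    except Exception as exc:
        raise RuntimeError(f"stage 'survive' failed: {exc}") from exc

    # --- stage 5: report ---
    try:
        recist_first = [pa.first_eval(CriteriaSet.RECIST) for pa in assessed]
        choi_first = [pa.first_eval(CriteriaSet.CHOI) for pa in assessed]
        xtab = crosstab_responses(
            [a for a in recist_first if a is not None],
            [a for a in choi_first if a is not None],
        )
        sites = site_change_summary(patients, assessed)
        basis_counts = {
            b.value: sum(1 for a in choi_first
                         if a is not None
                         and a.category is ResponseCategory.PR
                         and a.pr_basis is b)
            for b in (PRBasis.SIZE_ONLY, PRBasis.ATTENUATION_ONLY, PRBasis.BOTH)
        }
        bundle = {
            "n_patients": len(patients),
            "crosstab_recist_x_choi": xtab.to_dict(),
            "choi_pr_basis_counts": basis_counts,
            "site_change_summary": sites.to_dict(orient="records"),
            "survival_comparison": comparisons,
            "category_counts": {
                "recist_first_eval": _count(recist_first),
                "choi_first_eval": _count(choi_first),
            },
        }
        (out / "report.json").write_text(json.dumps(bundle, indent=2))
        _write_markdown(bundle, xtab, sites, out / "report.md")
        if config.make_plots:
            for grouping in GROUPINGS:
                for ep in (Endpoint.PFS, Endpoint.OS):
                    _km_plot(endpoints, assessed, thresholds, grouping, ep,
                             out / f"km_{grouping}_{ep.value.lower()}.svg")
    except Exception as exc:
        raise RuntimeError(f"stage 'report' failed: {exc}") from exc
    return bundle


def _count(assessments: Sequence[Optional[ResponseAssessment]]) -> dict:
    counts = {c: 0 for c in _CATEGORIES}
    for a in assessments:
        if a is not None:
            counts[a.category.value] += 1
    return counts


def _write_markdown(bundle: dict, xtab: pd.DataFrame, sites: pd.DataFrame,
                    path: Path) -> None:
    lines = ["# Response-criteria pipeline report", ""]
    lines.append(f"Patients analysed: {bundle['n_patients']}")
    lines.append("")
    lines.append("## Response categories at first evaluation")
    lines.append("")
    for crit, counts in bundle["category_counts"].items():
        lines.append(f"- {crit}: " + ", ".join(
            f"{k}={v}" for k, v in counts.items()))
    lines.append("")
    lines.append("## RECIST x Choi cross-tabulation")
    lines.append("")
    lines.append(xtab.to_markdown())
    lines.append("")
    lines.append("## Choi PR basis")
    lines.append("")
    for k, v in bundle["choi_pr_basis_counts"].items():
        lines.append(f"- {k}: {v}")
    lines.append("")
    if len(sites):
        lines.append("## Per-site change summary (Choi-eligible lesions)")
        lines.append("")
        lines.append(sites.to_markdown(index=False))
        lines.append("")
    lines.append("## Survival comparison")
    lines.append("")
    for grouping, entry in bundle["survival_comparison"].items():
        lines.append(
            f"- {grouping}: responders n={entry['n_responders']}, "
            f"non-responders n={entry['n_nonresponders']}")
        for ep in ("PFS", "OS"):
            st = entry.get(ep) or {}
            if st:
                chi2 = st.get("logrank_chi2")
                p = st.get("logrank_p")
                lines.append(
                    f"    - {ep}: median responders "
                    f"{_fmt_months(st.get('median_responders'))} vs "
                    f"non-responders "
                    f"{_fmt_months(st.get('median_nonresponders'))} months; "
                    f"log-rank chi2="
                    f"{'NA' if chi2 is None else format(chi2, '.1f')}, "
                    f"p={'NA' if p is None else format(p, '.3g')}")
    Path(path).write_text("\n".join(lines) + "\n")


def _fmt_months(x: Optional[float]) -> str:
    return "NR" if x is None else format(x, ".1f")
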