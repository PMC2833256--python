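"""Survival endpoints and the statistical layer.

Derives progression-free and overall survival with the trial's censoring
rules, then provides the estimators and tests the analysis uses:
Kaplan–Meier product-limit curves, the two-group log-rank test, the Wilcoxon
signed-rank test for paired before/after measurements, and Spearman rank
correlation.

Conventions
-----------
* Median survival is the smallest time t with S(t) <= 0.5; undefined when the
  curve never reaches 0.5.
* At tied times, events precede censorings (standard convention).
* All p-values are two-tailed.
* Wilcoxon signed-rank: zero differences are dropped; for n <= 25 the exact
  null distribution of W+ is computed (average ranks for ties; the exact
  distribution is built by dynamic programming over the tied rank multiset),
  otherwise a tie-corrected normal approximation is used.
* Spearman: average ranks for ties; exact permutation p for n <= 9, otherwise
  the usual t approximation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

from .datatypes import (
    CensorReason,
    CriteriaSet,
    Endpoint,
    PatientTimeline,
    ResponseAssessment,
    ResponseCategory,
    SurvivalEndpoint,
    TWELVE_WEEKS_MONTHS,
)

__all__ = [
    "KMEstimate",
    "derive_pfs",
    "derive_os",
    "km_estimate",
    "logrank_test",
    "wilcoxon_signed_rank",
    "spearman_corr",
]


# ---------------------------------------------------------------------------
# Endpoint derivation
# ---------------------------------------------------------------------------

def derive_pfs(
    timeline: PatientTimeline,
    assessments: Sequence[ResponseAssessment],
) -> SurvivalEndpoint:
    """Derive progression-free survival for one patient.

    The PFS event is the earliest of: radiological PD on a follow-up scan
    (RECIST assessments), clear clinical evidence of PD, or death due to PD
    within 12 weeks after the last response evaluation. Without progression,
    PFS is censored at the last follow-up; a PD-attributed death later than
    12 weeks after the last evaluation is censored at the last adequate
    tumour assessment instead.
    """
    if timeline.death_months is not None and timeline.death_months < 0:
        raise ValueError("death before treatment start")

    recist = sorted(
        (a for a in assessments
         if a.criteria is CriteriaSet.RECIST and a.months_from_start > 0),
        key=lambda a: a.months_from_start,
    )
    radiological_pd = next(
        (a.months_from_start for a in recist
         if a.category is ResponseCategory.PD), None,
    )
    last_eval = max(
        (a.months_from_start for a in recist
         if a.category is not ResponseCategory.NOT_EVALUABLE),
        default=0.0,
    )

    candidates = [t for t in (radiological_pd, timeline.clinical_pd_months)
                  if t is not None]
    pd_death_late = False
    if timeline.death_months is not None and timeline.death_due_to_pd:
        if timeline.death_months - last_eval <= TWELVE_WEEKS_MONTHS:
            candidates.append(timeline.death_months)
        else:
            pd_death_late = True

    if candidates:
        return SurvivalEndpoint(
            timeline.patient_id, Endpoint.PFS, min(candidates), True
        )
    if pd_death_late:
        # PD date unknown: censor at the last adequate tumour assessment
        return SurvivalEndpoint(
            timeline.patient_id, Endpoint.PFS, last_eval, False,
            CensorReason.LAST_ADEQUATE_ASSESSMENT,
        )
    return SurvivalEndpoint(
        timeline.patient_id, Endpoint.PFS, timeline.last_followup_months,
        False, CensorReason.LAST_FOLLOWUP,
    )


def derive_os(timeline: PatientTimeline) -> SurvivalEndpoint:
    """Overall survival: death of any cause, else censored at last known alive."""
    if timeline.death_months is not None:
        if timeline.death_months < 0:
            raise ValueError("death before treatment start")
        return SurvivalEndpoint(
            timeline.patient_id, Endpoint.OS, timeline.death_months, True
        )
    return SurvivalEndpoint(
        timeline.patient_id, Endpoint.OS, timeline.last_followup_months,
        False, CensorReason.LAST_FOLLOWUP,
    )


# ---------------------------------------------------------------------------
# Kaplan–Meier
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KMEstimate:
    """Product-limit survival curve evaluated at the distinct event times."""

    event_times: np.ndarray        # ascending distinct event times
    survival_probs: np.ndarray     # S(t) just after each event time
    n_at_risk: np.ndarray          # risk-set size at each event time
    median_months: Optional[float]

    def survival_at(self, t: float) -> float:
        """S(t), right-continuous step function; S = 1 before the first event."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival_probs[idx])


def _unpack(endpoints: Sequence[SurvivalEndpoint]) -> tuple[np.ndarray, np.ndarray]:
    times = np.array([e.time_months for e in endpoints], dtype=float)
    events = np.array([e.event for e in endpoints], dtype=bool)
    return times, events


def km_estimate(endpoints: Sequence[SurvivalEndpoint]) -> KMEstimate:
    """Kaplan–Meier product-limit estimate of the survival function."""
    if not endpoints:
        raise ValueError("km_estimate needs at least one endpoint")
    times, events = _unpack(endpoints)
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)

    event_times = np.sort(np.unique(times[events]))
    if event_times.size:
        probs = (
            kmf.survival_function_.reindex(event_times, method="ffill")
            .to_numpy().ravel()
        )
        # risk set: subjects with time >= t (ties: events precede censorings)
        n_at_risk = np.array([(times >= t).sum() for t in event_times])
    else:
        probs = np.array([])
        n_at_risk = np.array([], dtype=int)

    median = None
    below = np.nonzero(probs <= 0.5 + 1e-12)[0]
    if below.size:
        median = float(event_times[below[0]])
    return KMEstimate(event_times, probs, n_at_risk, median)


def logrank_test(
    group_a: Sequence[SurvivalEndpoint],
    group_b: Sequence[SurvivalEndpoint],
) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square with 1 df, two-tailed p)."""
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    ta, ea = _unpack(group_a)
    tb, eb = _unpack(group_b)
    if not (ea.any() or eb.any()):
        raise ValueError("log-rank undefined: zero events")
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------

def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-tailed p for W+ given the (possibly tied) rank multiset.

    Builds the exact null distribution of 2*W+ by dynamic programming: each
    rank independently contributes 0 or its doubled value with probability
    1/2. Average ranks are half-integers, so doubling makes them integers.
    """
    r2 = np.round(2 * ranks).astype(int)
    total = int(r2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = 0.5 * (dist + shifted)
    w2 = int(round(2 * w_plus))
    p_le = dist[: w2 + 1].sum()
    p_ge = dist[w2:].sum()
    return float(min(1.0, 2 * min(p_le, p_ge)))


def wilcoxon_signed_rank(
    paired_before: Sequence[float], paired_after: Sequence[float]
) -> tuple[float, float]:
    """Wilcoxon signed-rank test on paired measurements.

    Returns (W+, two-tailed p) where W+ is the sum of the ranks of positive
    ``after - before`` differences. All-zero differences are a degenerate
    case and return (0, 1).
    """
    before = np.asarray(paired_before, dtype=float)
    after = np.asarray(paired_after, dtype=float)
    if before.shape != after.shape or before.ndim != 1:
        raise ValueError("paired samples must be equal-length 1-D sequences")
    d = after - before
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 0.0, 1.0
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= 25:
        p = _exact_signed_rank_p(ranks, w_plus)
    else:
        mean = n * (n + 1) / 4.0
        # tie correction: subtract sum(t^3 - t)/48 from the null variance
        _, counts = np.unique(ranks, return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - ((counts**3 - counts).sum()) / 48.0
        z = (w_plus - mean) / math.sqrt(var)
        p = 2 * stats.norm.sf(abs(z))
    return w_plus, float(min(1.0, p))


# ---------------------------------------------------------------------------
# Spearman correlation
# ---------------------------------------------------------------------------

def spearman_corr(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    Returns (rho, two-tailed p). For n <= 9 the p-value is exact over all n!
    permutations; otherwise the t approximation is used. A constant input
    vector leaves the correlation undefined and raises ``ValueError``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    n = x.size
    if n < 3:
        raise ValueError("need n >= 3 for a rank correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: Spearman correlation undefined")

    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])

    if n <= 9:
        rx_c = rx - rx.mean()
        denom = math.sqrt((rx_c**2).sum()) * math.sqrt(((ry - ry.mean()) ** 2).sum())
        perms = np.array(list(itertools.permutations(ry)))
        rho_perm = (perms - ry.mean()) @ rx_c / denom
        p = float(np.mean(np.abs(rho_perm) >= abs(rho) - 1e-12))
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1 - rho**2))
            p = float(2 * stats.t.sf(abs(t), df=n - 2))
    return rho, p
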