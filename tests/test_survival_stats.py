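"""Endpoint derivation and the statistical layer against hand oracles."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from respcrit import (
    CensorReason,
    CriteriaSet,
    Endpoint,
    LesionMeasurement,
    OrganSite,
    PatientTimeline,
    ResponseAssessment,
    ResponseCategory,
    Scan,
    SurvivalEndpoint,
    derive_os,
    derive_pfs,
    km_estimate,
    logrank_test,
    spearman_corr,
    wilcoxon_signed_rank,
)


def ep(t, event, pid="x"):
    return SurvivalEndpoint(pid, Endpoint.PFS, t, event,
                            CensorReason.NONE if event
                            else CensorReason.LAST_FOLLOWUP)


def _timeline(clinical_pd=None, death=None, death_pd=False, last=12.0):
    scans = [Scan(0.0, (LesionMeasurement("L0", OrganSite.LUNG, 30.0, 60.0),)),
             Scan(1.9, (LesionMeasurement("L0", OrganSite.LUNG, 28.0, 55.0),))]
    return PatientTimeline("P", scans, clinical_pd, death, death_pd, last)


def _recist(cat, months):
    return ResponseAssessment("P", months, CriteriaSet.RECIST, cat)


class TestDerivePFS:
    def test_radiological_pd_is_event(self):
        e = derive_pfs(_timeline(last=12.0),
                       [_recist(ResponseCategory.SD, 1.9),
                        _recist(ResponseCategory.PD, 6.0)])
        assert (e.time_months, e.event) == (6.0, True)

    def test_no_progression_censored_at_last_followup(self):
        e = derive_pfs(_timeline(last=12.0),
                       [_recist(ResponseCategory.SD, 1.9)])
        assert (e.time_months, e.event) == (12.0, False)
        assert e.censor_reason is CensorReason.LAST_FOLLOWUP

    def test_pd_death_within_12_weeks_is_event(self):
        e = derive_pfs(_timeline(death=4.0, death_pd=True, last=4.0),
                       [_recist(ResponseCategory.SD, 1.9)])
        assert (e.time_months, e.event) == (4.0, True)

    def test_late_pd_death_censored_at_last_assessment(self):
        e = derive_pfs(_timeline(death=10.0, death_pd=True, last=10.0),
                       [_recist(ResponseCategory.SD, 1.9),
                        _recist(ResponseCategory.SD, 5.0)])
        assert (e.time_months, e.event) == (5.0, False)
        assert e.censor_reason is CensorReason.LAST_ADEQUATE_ASSESSMENT

    def test_clinical_pd_is_event(self):
        e = derive_pfs(_timeline(clinical_pd=3.0),
                       [_recist(ResponseCategory.SD, 1.9)])
        assert (e.time_months, e.event) == (3.0, True)


class TestDeriveOS:
    def test_death_is_event(self):
        e = derive_os(_timeline(death=25.4, death_pd=True, last=25.4))
        assert (e.time_months, e.event) == (25.4, True)

    def test_alive_censored(self):
        e = derive_os(_timeline(last=30.0))
        assert (e.time_months, e.event) == (30.0, False)

    def test_death_before_start_rejected(self):
        with pytest.raises(ValueError):
            _timeline(death=-1.0, last=5.0)


class TestKaplanMeier:
    def test_all_events_closed_form(self):
        km = km_estimate([ep(1, True), ep(2, True), ep(3, True)])
        assert np.allclose(km.survival_probs, [2 / 3, 1 / 3, 0.0])
        assert km.median_months == 2

    def test_censoring_hand_product_limit(self):
        # at t=1: 3 at risk, 1 event -> 2/3; t=2 censored; t=3: 1 at risk ->
        # S(3) = (2/3) * (1 - 1/1) = 0
        km = km_estimate([ep(1, True), ep(2, False), ep(3, True)])
        assert np.allclose(km.event_times, [1, 3])
        assert np.allclose(km.survival_probs, [2 / 3, 0.0])
        assert np.allclose(km.n_at_risk, [3, 1])

    def test_all_censored_survival_is_one(self):
        km = km_estimate([ep(1, False), ep(2, False)])
        assert km.event_times.size == 0
        assert km.median_months is None
        assert km.survival_at(5.0) == 1.0

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(5)
        times = rng.exponential(10, 40)
        km = km_estimate([ep(t, True, f"p{i}") for i, t in enumerate(times)])
        for t in [0.5, 2.0, 7.5, 20.0]:
            empirical = np.mean(times > t)
            assert km.survival_at(t) == pytest.approx(empirical, abs=1e-12)

    def test_order_invariance(self):
        eps = [ep(t, e, f"p{i}") for i, (t, e) in
               enumerate([(5, True), (2, False), (9, True), (2, True)])]
        km1 = km_estimate(eps)
        km2 = km_estimate(eps[::-1])
        assert np.array_equal(km1.event_times, km2.event_times)
        assert np.allclose(km1.survival_probs, km2.survival_probs)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([])


def logrank_oracle(ta, ea, tb, eb):
    """Hand computation: sum of hypergeometric O-E terms over event times."""
    ta, ea, tb, eb = map(np.asarray, (ta, ea, tb, eb))
    event_times = np.unique(np.concatenate([ta[ea == 1], tb[eb == 1]]))
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        n_a = np.sum(ta >= t)
        n_b = np.sum(tb >= t)
        d_a = np.sum((ta == t) & (ea == 1))
        d_b = np.sum((tb == t) & (eb == 1))
        n, d = n_a + n_b, d_a + d_b
        o_minus_e += d_a - d * n_a / n
        if n > 1:
            var += d * (n_a / n) * (n_b / n) * (n - d) / (n - 1)
    chi2 = o_minus_e**2 / var
    return chi2, float(sps.chi2.sf(chi2, 1))


class TestLogrank:
    def test_identical_groups_null(self):
        grp = [ep(t, True, f"p{i}") for i, t in enumerate([1, 3, 5, 8])]
        chi2, p = logrank_test(grp, grp)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_six_patient_hand_example(self):
        ta, ea = [1.0, 3.0, 5.0], [1, 1, 0]
        tb, eb = [2.0, 4.0, 6.0], [1, 1, 1]
        chi2, p = logrank_test([ep(t, bool(e), f"a{i}")
                                for i, (t, e) in enumerate(zip(ta, ea))],
                               [ep(t, bool(e), f"b{i}")
                                for i, (t, e) in enumerate(zip(tb, eb))])
        chi2_o, p_o = logrank_oracle(ta, ea, tb, eb)
        assert chi2 == pytest.approx(chi2_o, abs=1e-10)
        assert p == pytest.approx(p_o, abs=1e-10)

    def test_random_data_matches_oracle(self):
        rng = np.random.default_rng(11)
        ta = rng.exponential(10, 30).round(1)
        tb = rng.exponential(5, 25).round(1)
        ea = rng.random(30) < 0.8
        eb = rng.random(25) < 0.8
        chi2, p = logrank_test(
            [ep(t, bool(e), f"a{i}") for i, (t, e) in enumerate(zip(ta, ea))],
            [ep(t, bool(e), f"b{i}") for i, (t, e) in enumerate(zip(tb, eb))])
        chi2_o, p_o = logrank_oracle(ta, ea, tb, eb)
        assert chi2 == pytest.approx(chi2_o, rel=1e-9)
        assert p == pytest.approx(p_o, rel=1e-9)

    def test_symmetry_in_group_labels(self):
        ga = [ep(t, True, f"a{i}") for i, t in enumerate([1, 4, 7])]
        gb = [ep(t, True, f"b{i}") for i, t in enumerate([2, 3, 9, 12])]
        assert logrank_test(ga, gb)[0] == pytest.approx(
            logrank_test(gb, ga)[0], abs=1e-12)

    def test_strong_separation(self):
        ga = [ep(t, True, f"a{i}") for i, t in
              enumerate(np.linspace(1, 10, 50))]
        gb = [ep(t + 40, True, f"b{i}") for i, t in
              enumerate(np.linspace(1, 10, 50))]
        _, p = logrank_test(ga, gb)
        assert p < 0.001

    def test_zero_events_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([ep(1, False)], [ep(2, False)])


def wilcoxon_enumeration_oracle(diffs):
    """Exact two-tailed p by exhaustive sign enumeration (n <= 15)."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    ws = np.array([
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=n)
    ])
    p_le = np.mean(ws <= w_obs + 1e-9)
    p_ge = np.mean(ws >= w_obs - 1e-9)
    return w_obs, min(1.0, 2 * min(p_le, p_ge))


class TestWilcoxon:
    def test_degenerate_all_zero(self):
        w, p = wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])
        assert (w, p) == (0.0, 1.0)

    @pytest.mark.parametrize("after", [
        [2.0, 1.5, 4.0, 2.5, 7.0, 5.5],          # n=6 mixed signs
        [0.5, 1.2, 2.8, 4.5, 5.1, 6.9],
        [2.0, 3.0, 2.0, 6.0, 4.0, 8.0],          # ties in |d|
    ])
    def test_exact_matches_enumeration(self, after):
        before = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        w, p = wilcoxon_signed_rank(before, after)
        w_o, p_o = wilcoxon_enumeration_oracle(np.subtract(after, before))
        assert w == pytest.approx(w_o)
        assert p == pytest.approx(p_o, abs=1e-12)

    def test_exact_matches_enumeration_n15(self):
        rng = np.random.default_rng(3)
        before = rng.normal(10, 2, 15)
        after = before + rng.normal(-1, 1.5, 15)
        w, p = wilcoxon_signed_rank(before, after)
        w_o, p_o = wilcoxon_enumeration_oracle(after - before)
        assert w == pytest.approx(w_o)
        assert p == pytest.approx(p_o, abs=1e-12)

    def test_one_sided_saturation_large_n(self):
        before = np.arange(1.0, 31.0)
        after = before - np.linspace(0.5, 3.0, 30)  # all differences negative
        _, p = wilcoxon_signed_rank(before, after)
        assert p <= 0.001

    def test_approx_close_to_exact_at_boundary(self):
        # n=25 exact vs n=26 normal approximation should roughly agree
        rng = np.random.default_rng(9)
        before = rng.normal(size=26)
        after = before + rng.normal(-0.8, 1.0, 26)
        _, p26 = wilcoxon_signed_rank(before, after)
        _, p25 = wilcoxon_signed_rank(before[:25], after[:25])
        assert 0 <= p26 <= 1 and 0 <= p25 <= 1


class TestSpearman:
    def test_perfect_monotone(self):
        rho, _ = spearman_corr([1, 2, 3, 4], [10, 20, 30, 40])
        assert rho == pytest.approx(1.0)
        rho, _ = spearman_corr([1, 2, 3, 4], [40, 30, 20, 10])
        assert rho == pytest.approx(-1.0)

    def test_one_swapped_pair_rank_formula(self):
        # d^2 sums to 2: rho = 1 - 6*2 / (5 * 24) = 0.9
        rho, p = spearman_corr([1, 2, 3, 4, 5], [1, 2, 4, 3, 5])
        assert rho == pytest.approx(0.9)
        # exact permutation p over 5! arrangements
        perms = itertools.permutations([1, 2, 3, 4, 5])
        rhos = [np.corrcoef([1, 2, 3, 4, 5], pm)[0, 1] for pm in perms]
        p_exact = np.mean([abs(r) >= 0.9 - 1e-12 for r in rhos])
        assert p == pytest.approx(p_exact)

    def test_large_n_matches_scipy_t_approx(self):
        rng = np.random.default_rng(21)
        x = rng.normal(size=40)
        y = x + rng.normal(size=40)
        rho, p = spearman_corr(x, y)
        ref = sps.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            spearman_corr([1, 1, 1, 1], [1, 2, 3, 4])

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            spearman_corr([1, 2], [3, 4])
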