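"""Target-lesion selection, exclusion accounting, and caps."""

import pytest

from respcrit import (
    CriteriaThresholds,
    LesionMeasurement,
    OrganSite,
    attenuation_evaluable,
    exclusion_tally,
    generate_cohort,
    generate_lesion_fixture,
    default_config,
    select_targets,
)
from respcrit.datatypes import ExclusionReason
from respcrit.reporting import assess_cohort


def L(lid, site=OrganSite.LUNG, d=30.0, hu=60.0, **kw):
    return LesionMeasurement(lid, site, d, hu, **kw)


class TestSelectTargets:
    def test_sub15_is_recist_only(self):
        res = select_targets([L("a", d=12.0)], [L("a", d=10.0)])
        assert res.included_recist == ["a"]
        assert res.included_choi == []
        assert res.exclusions["a"] is ExclusionReason.BASELINE_UNDER_15MM

    def test_bone_excluded_from_both(self):
        res = select_targets([L("a", OrganSite.BONE, 30.0)],
                             [L("a", OrganSite.BONE, 28.0)])
        assert res.included_recist == [] and res.included_choi == []
        assert res.exclusions["a"] is ExclusionReason.BONE_METASTASIS

    @pytest.mark.parametrize("site,reason", [
        (OrganSite.BRAIN, ExclusionReason.BRAIN_METASTASIS),
        (OrganSite.PRIMARY_TUMOUR, ExclusionReason.PRIMARY_TUMOUR),
    ])
    def test_other_site_exclusions(self, site, reason):
        res = select_targets([L("a", site, 40.0)], [L("a", site, 40.0)])
        assert res.exclusions["a"] is reason

    def test_clean_lung_lesion_in_both(self):
        res = select_targets([L("a", d=48.0, hu=107.0)],
                             [L("a", d=39.0, hu=65.0)])
        assert res.included_recist == ["a"]
        assert res.included_choi == ["a"]
        assert res.attenuation_evaluable_ids == ["a"]
        assert res.exclusions == {}

    def test_under_10mm_excluded_from_both(self):
        res = select_targets([L("a", d=8.0)], [L("a", d=8.0)])
        assert res.included_recist == []
        assert res.exclusions["a"] is ExclusionReason.BASELINE_UNDER_10MM

    def test_boundaries_inclusive_as_printed(self):
        res = select_targets([L("a", d=15.0), L("b", d=10.0)],
                             [L("a", d=15.0), L("b", d=10.0)])
        assert set(res.included_recist) == {"a", "b"}
        assert res.included_choi == ["a"]

    def test_cavitation_excludes_choi_only(self):
        res = select_targets(
            [L("a", d=30.0)],
            [L("a", d=25.0, hu=None, cavitated=True)])
        assert res.included_recist == ["a"]
        assert res.included_choi == []
        assert res.exclusions["a"] is ExclusionReason.CAVITATION_AT_EVALUATION

    def test_artefact_excludes_choi_only(self):
        res = select_targets([L("a", d=30.0)],
                             [L("a", d=28.0, hu=None, artefact=True)])
        assert res.exclusions["a"] is ExclusionReason.BEAM_HARDENING_ARTEFACT

    def test_vanished_lesion_still_selected(self):
        res = select_targets([L("a", d=30.0)], [])
        assert res.included_recist == ["a"]
        assert res.included_choi == ["a"]
        assert res.attenuation_evaluable_ids == []

    def test_duplicate_and_unmatched_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            select_targets([L("a"), L("a")], [])
        with pytest.raises(ValueError, match="no baseline match"):
            select_targets([L("a")], [L("b")])

    def test_new_lesions_are_not_targets(self):
        res = select_targets([L("a")], [L("a", d=28.0),
                                        L("n", d=12.0, is_new=True)])
        assert res.included_recist == ["a"]

    def test_total_cap_keeps_largest(self):
        baseline = [L(f"l{i:02d}", OrganSite.LUNG, 20.0 + i)
                    for i in range(4)]
        baseline += [L(f"n{i:02d}", OrganSite.LYMPH_NODE, 40.0 + i)
                     for i in range(4)]
        baseline += [L(f"v{i:02d}", OrganSite.LIVER, 60.0 + i)
                     for i in range(4)]
        res = select_targets(baseline, baseline)
        assert len(res.included_recist) == 10
        # the two smallest lung lesions fall out of the total cap
        assert res.exclusions["l00"] is ExclusionReason.TOTAL_CAP_EXCEEDED
        assert res.exclusions["l01"] is ExclusionReason.TOTAL_CAP_EXCEEDED

    def test_organ_cap_five_per_organ(self):
        baseline = [L(f"l{i}", OrganSite.LUNG, 20.0 + i) for i in range(7)]
        res = select_targets(baseline, baseline)
        assert len(res.included_recist) == 5
        assert res.exclusions["l0"] is ExclusionReason.ORGAN_CAP_EXCEEDED
        assert res.exclusions["l1"] is ExclusionReason.ORGAN_CAP_EXCEEDED

    def test_idempotent_on_included_subset(self):
        baseline = [L(f"l{i}", OrganSite.LUNG, 14.0 + i) for i in range(8)]
        evaluation = [L(f"l{i}", OrganSite.LUNG, 13.0 + i) for i in range(8)]
        res1 = select_targets(baseline, evaluation)
        sub_b = [l for l in baseline if l.lesion_id in res1.included_recist]
        sub_e = [l for l in evaluation if l.lesion_id in res1.included_recist]
        res2 = select_targets(sub_b, sub_e)
        assert set(res2.included_recist) == set(res1.included_recist)
        assert set(res2.included_choi) == set(res1.included_choi)


class TestAttenuationEvaluable:
    def test_shrunk_below_floor_not_evaluable(self):
        assert not attenuation_evaluable(L("a", d=26.0), L("a", d=13.0))

    def test_cavitated_not_evaluable(self):
        assert not attenuation_evaluable(
            L("a", d=30.0), L("a", d=25.0, hu=None, cavitated=True))

    def test_clean_pair_evaluable(self):
        assert attenuation_evaluable(L("a", d=48.0, hu=107.0),
                                     L("a", d=39.0, hu=65.0))

    def test_vanished_not_evaluable(self):
        assert not attenuation_evaluable(L("a", d=30.0), None)


class TestFixturesAndTally:
    @pytest.mark.parametrize("kind,reason", [
        ("sub15mm", ExclusionReason.BASELINE_UNDER_15MM),
        ("bone", ExclusionReason.BONE_METASTASIS),
        ("brain", ExclusionReason.BRAIN_METASTASIS),
        ("primary", ExclusionReason.PRIMARY_TUMOUR),
        ("cavitated", ExclusionReason.CAVITATION_AT_EVALUATION),
        ("artefact", ExclusionReason.BEAM_HARDENING_ARTEFACT),
    ])
    def test_each_fixture_triggers_its_reason(self, kind, reason):
        base, ev = generate_lesion_fixture(kind)
        res = select_targets([base], [ev])
        assert res.exclusions[base.lesion_id] is reason

    def test_eligible_fixture_passes_cleanly(self):
        base, ev = generate_lesion_fixture("eligible")
        assert base.longest_diameter_mm >= 15.0
        res = select_targets([base], [ev])
        assert res.included_choi == [base.lesion_id]
        assert res.exclusions == {}

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            generate_lesion_fixture("volumetric")

    def test_tally_empty_input(self):
        tab = exclusion_tally([])
        assert (tab["n_lesions"] == 0).all()

    def test_tally_one_per_reason(self):
        kinds = ["sub15mm", "bone", "brain", "primary", "cavitated",
                 "artefact"]
        results = []
        for kind in kinds:
            base, ev = generate_lesion_fixture(kind)
            results.append(select_targets([base], [ev]))
        tab = exclusion_tally(results).set_index("reason")["n_lesions"]
        for reason in ["baseline_under_15mm", "bone_metastasis",
                       "brain_metastasis", "primary_tumour",
                       "cavitation_at_evaluation", "beam_hardening_artefact"]:
            assert tab[reason] == 1

    def test_tally_matches_direct_recount_on_cohort(self):
        cohort = generate_cohort(default_config(n_patients=40, seed=77))
        assessed = assess_cohort(cohort.patients)
        results = [pa.eligibility for pa in assessed]
        tab = exclusion_tally(results).set_index("reason")["n_lesions"]
        # independent recount straight from the result objects
        n_recist = sum(len(r.included_recist) for r in results)
        n_choi = sum(len(r.included_choi) for r in results)
        n_reasons = sum(len(r.exclusions) for r in results)
        assert tab["recist_eligible"] == n_recist
        assert tab["choi_eligible"] == n_choi
        reason_rows = tab.drop(["recist_eligible", "choi_eligible"])
        assert reason_rows.sum() == n_reasons

    def test_counting_identity_choi_subset_of_recist(self):
        cohort = generate_cohort(default_config(n_patients=40, seed=78))
        for pa in assess_cohort(cohort.patients):
            r = pa.eligibility
            assert set(r.included_choi) <= set(r.included_recist)
            choi_only = [lid for lid in r.included_recist
                         if lid in r.exclusions]
            assert len(r.included_choi) == (len(r.included_recist)
                                            - len(choi_only))

    def test_caps_never_exceeded_on_cohort(self):
        cfg = default_config(n_patients=30, seed=79,
                             lesions_per_patient={"min": 8, "max": 14})
        for pa in assess_cohort(generate_cohort(cfg).patients):
            r = pa.eligibility
            for ids in (r.included_recist, r.included_choi):
                assert len(ids) <= 10
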