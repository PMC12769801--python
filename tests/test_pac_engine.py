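import datetime as dt
import random

import pytest

from pacpheno.corpus_io import PatientRecord, StructuredObservation
from pacpheno.pac_engine import (
    AsthmaStatus,
    EngineConfig,
    build_evidence,
    classify,
    determine_index_date,
    eval_pft_criterion,
)

from conftest import make_mention


def D(s):
    return dt.date.fromisoformat(s)


def obs(kind, value, date, pid="P1"):
    return StructuredObservation(pid, D(date), kind, value)


def record(pid="P1", birth="1950-01-01", observations=()):
    return PatientRecord(
        patient_id=pid,
        birth_date=D(birth) if birth else None,
        observations=list(observations),
    )


def evidence(mentions=(), observations=(), birth="1950-01-01", config=EngineConfig()):
    return build_evidence(record(observations=observations, birth=birth), list(mentions), config)


class TestCondition1:
    def test_combination_across_notes_dated_at_completion(self):
        ev = evidence(
            [make_mention("cough", "2002-01-10"), make_mention("wheezing", "2002-03-05")]
        )
        assert ev.first("cond1") == D("2002-03-05")

    def test_cough_alone_is_not_enough(self):
        ev = evidence([make_mention("cough", "2002-01-10")])
        assert ev.first("cond1") is None

    def test_dyspnea_plus_wheeze_on_exam_qualifies(self):
        ev = evidence(
            [make_mention("dyspnea", "2002-01-10"), make_mention("wheeze_on_exam", "2002-02-01")]
        )
        assert ev.first("cond1") == D("2002-02-01")

    def test_negated_wheezing_contributes_nothing(self):
        ev = evidence(
            [
                make_mention("wheezing", "2002-01-10", assertion="negated"),
                make_mention("cough", "2002-02-01"),
            ]
        )
        assert ev.first("cond1") is None and not ev.cond1_dates

    def test_family_experiencer_contributes_nothing(self):
        ev = evidence(
            [
                make_mention("wheezing", "2002-01-10", experiencer="other"),
                make_mention("cough", "2002-02-01"),
            ]
        )
        assert ev.first("cond1") is None

    def test_min_episodes_two_requires_two_distinct_dates(self):
        mentions = [make_mention("cough", "2002-01-10"), make_mention("wheezing", "2002-01-10")]
        assert evidence(mentions).first("cond1") == D("2002-01-10")
        assert evidence(mentions, config=EngineConfig(min_episodes=2)).first("cond1") is None


class TestMinorCriteria:
    def test_eosinophil_threshold_is_strict(self):
        ev = evidence(observations=[obs("eosinophil_count", 300, "2003-04-01")])
        assert "eosinophilia_gt300" not in ev.minor_criteria
        ev = evidence(observations=[obs("eosinophil_count", 301, "2003-04-01")])
        assert ev.minor_criteria["eosinophilia_gt300"] == D("2003-04-01")

    def test_nonsmoker_waits_for_fourteenth_birthday(self):
        ev = evidence(
            observations=[obs("smoking_status", "never", "2003-06-01")], birth="1990-01-01"
        )
        assert ev.minor_criteria["nonsmoker_14plus"] == D("2004-01-01")

    def test_current_smoker_fails_criterion(self):
        ev = evidence(observations=[obs("smoking_status", "current", "2003-06-01")])
        assert "nonsmoker_14plus" not in ev.minor_criteria

    def test_former_smoker_admitted_only_when_configured(self):
        o = [obs("smoking_status", "former", "2003-06-01")]
        assert "nonsmoker_14plus" not in evidence(observations=o).minor_criteria
        ev = evidence(observations=o, config=EngineConfig(admit_former_smoker=True))
        assert ev.minor_criteria["nonsmoker_14plus"] == D("2003-06-01")

    def test_elevated_ige_flag_counts_as_atopy_test(self):
        ev = evidence(observations=[obs("serum_ige", "elevated", "2003-04-01")])
        assert ev.minor_criteria["atopy_test_positive"] == D("2003-04-01")

    def test_numeric_ige_needs_configured_threshold(self):
        o = [obs("serum_ige", 250.0, "2003-04-01")]
        assert "atopy_test_positive" not in evidence(observations=o).minor_criteria
        ev = evidence(observations=o, config=EngineConfig(ige_threshold=100.0))
        assert ev.minor_criteria["atopy_test_positive"] == D("2003-04-01")

    def test_numeric_bronchodilator_improvement(self):
        ev = evidence(observations=[obs("fev1_bd_improvement", 15, "2003-04-01")])
        assert ev.minor_criteria["bronchodilator_response"] == D("2003-04-01")
        ev = evidence(observations=[obs("fev1_bd_improvement", 10, "2003-04-01")])
        assert "bronchodilator_response" not in ev.minor_criteria


class TestPftCriterion:
    def test_low_then_improvement_dated_at_second_test(self):
        o = [
            obs("fev1_pct_pred", 65, "2001-05-01"),
            obs("fev1_bd_improvement", 22, "2001-06-01"),
            obs("fev1_post_bd_pct_pred", 79, "2001-06-01"),
        ]
        assert eval_pft_criterion(o) == D("2001-06-01")

    def test_methacholine_boundary_inclusive(self):
        assert eval_pft_criterion([obs("methacholine_fev1_decline", 20, "2004-02-02")]) == D(
            "2004-02-02"
        )
        assert eval_pft_criterion([obs("methacholine_fev1_decline", 19.5, "2004-02-02")]) is None

    def test_improvement_boundary_inclusive_but_must_reach_70(self):
        o = [
            obs("fvc_pct_pred", 69, "2001-05-01"),
            obs("fev1_bd_improvement", 20, "2001-06-01"),
            obs("fev1_post_bd_pct_pred", 71, "2001-06-01"),
        ]
        assert eval_pft_criterion(o) == D("2001-06-01")
        o[2] = obs("fev1_post_bd_pct_pred", 70, "2001-06-01")
        assert eval_pft_criterion(o) is None

    def test_lone_normal_fev1_is_absent(self):
        assert eval_pft_criterion([obs("fev1_pct_pred", 72, "2001-05-01")]) is None

    def test_empty_input_is_absent(self):
        assert eval_pft_criterion([]) is None


def _case_mentions(minors=(), dx=None):
    ms = [
        make_mention("cough", "2002-01-10"),
        make_mention("wheezing", "2002-03-05"),
        make_mention("symptom_variability", "2002-05-01"),
    ]
    for i, concept in enumerate(minors):
        ms.append(make_mention(concept, f"2003-0{i+1}-01"))
    if dx:
        ms.append(make_mention("physician_asthma_dx", dx, section_label="diagnosis"))
    return ms


class TestClassify:
    def test_physician_dx_alone_is_definite(self):
        ev = evidence([make_mention("physician_asthma_dx", "2005-03-03", section_label="diagnosis")])
        st = classify(ev)
        assert (st.granular, st.asthma, st.index_date) == ("definite", True, D("2005-03-03"))

    def test_dx_outside_diagnosis_sections_not_credited(self):
        ev = evidence([make_mention("physician_asthma_dx", "2005-03-03", section_label="unknown")])
        assert classify(ev).granular == "none"

    def test_conditions_one_two_only_is_probable(self):
        st = classify(evidence(_case_mentions()))
        assert (st.granular, st.asthma) == ("probable", True)
        assert st.index_date == D("2002-05-01")

    def test_two_minor_criteria_make_definite(self):
        st = classify(evidence(_case_mentions(minors=["nasal_polyps", "nocturnal_cough_wheeze"])))
        assert st.granular == "definite"

    def test_one_minor_criterion_is_still_probable(self):
        st = classify(evidence(_case_mentions(minors=["nasal_polyps"])))
        assert st.granular == "probable"

    def test_exclusion_vetoes_classification(self):
        ms = _case_mentions(minors=["nasal_polyps", "nocturnal_cough_wheeze"])
        ms.append(make_mention("cystic_fibrosis", "2004-01-01"))
        st = classify(evidence(ms))
        assert (st.granular, st.asthma, st.index_date) == ("excluded", False, None)

    def test_condition_one_alone_is_none(self):
        st = classify(
            evidence([make_mention("cough", "2002-01-10"), make_mention("wheezing", "2002-03-05")])
        )
        assert (st.granular, st.asthma, st.index_date) == ("none", False, None)

    def test_zero_evidence_is_none(self):
        st = classify(evidence())
        assert (st.granular, st.index_date) == ("none", None)

    def test_as_of_before_completion_is_none(self):
        ev = evidence(_case_mentions())
        assert classify(ev, as_of=D("2002-04-01")).granular == "none"
        assert classify(ev, as_of=D("2002-05-01")).granular == "probable"

    def test_igg_observation_triggers_exclusion(self):
        ms = _case_mentions()
        ev = evidence(ms, observations=[obs("igg", 1.5, "2003-01-01")])
        assert classify(ev).granular == "excluded"

    def test_consistently_low_fev1_needs_two_readings(self):
        ms = _case_mentions()
        one = [obs("fev1_pct_pred", 45, "2003-01-01")]
        assert classify(evidence(ms, observations=one)).granular == "probable"
        two = one + [obs("fev1_pct_pred", 42, "2003-06-01")]
        assert classify(evidence(ms, observations=two)).granular == "excluded"

    def test_foreign_body_only_excludes_near_index(self):
        near = _case_mentions() + [make_mention("foreign_body_near_index", "2002-08-01")]
        assert classify(evidence(near)).granular == "excluded"
        far = _case_mentions() + [make_mention("foreign_body_near_index", "2006-01-01")]
        assert classify(evidence(far)).granular == "probable"

    def test_foreign_patient_mention_rejected(self):
        with pytest.raises(ValueError, match="patient"):
            evidence([make_mention("cough", "2002-01-10", patient_id="P9")])


class TestIndexDate:
    def test_probable_route_is_max_of_condition_firsts(self):
        ev = evidence(
            [
                make_mention("cough", "2001-10-01"),
                make_mention("wheezing", "2002-03-05"),
                make_mention("symptom_variability", "2001-11-20"),
            ]
        )
        assert determine_index_date(ev) == D("2002-03-05")

    def test_minimum_over_routes(self):
        ms = [
            make_mention("cough", "2002-06-01"),
            make_mention("wheezing", "2002-12-01"),
            make_mention("symptom_variability", "2003-01-01"),
            make_mention("physician_asthma_dx", "2004-01-01", section_label="diagnosis"),
        ]
        assert determine_index_date(evidence(ms)) == D("2003-01-01")

    def test_no_route_is_absent(self):
        assert determine_index_date(evidence([make_mention("cough", "2002-01-10")])) is None

    def test_definite_by_criteria_route_uses_second_minor(self):
        ms = [
            make_mention("cough", "2001-01-01"),
            make_mention("wheezing", "2001-02-01"),
            make_mention("symptom_variability", "2001-03-01"),
            make_mention("nasal_polyps", "2001-04-01"),
            make_mention("nocturnal_cough_wheeze", "2001-06-01"),
        ]
        ev = evidence(ms)
        # probable route (2001-03-01) precedes the definite-by-criteria route
        assert determine_index_date(ev) == D("2001-03-01")
        assert classify(ev).granular == "definite"


class TestMonotonicity:
    CONCEPTS = [
        "cough", "wheezing", "dyspnea", "wheeze_on_exam",
        "symptom_variability", "symptom_free_weeks",
        "nasal_polyps", "nocturnal_cough_wheeze", "hay_fever",
    ]

    def test_adding_evidence_never_retracts_asthma_or_delays_index(self):
        rng = random.Random(42)
        dates = [D("2001-01-01"), D("2001-06-01"), D("2002-01-01"), D("2003-01-01")]
        for _ in range(80):
            base = [
                make_mention(rng.choice(self.CONCEPTS), rng.choice(dates).isoformat())
                for _ in range(rng.randint(0, 6))
            ]
            extra = base + [
                make_mention(rng.choice(self.CONCEPTS), rng.choice(dates).isoformat())
            ]
            st0, st1 = classify(evidence(base)), classify(evidence(extra))
            if st0.asthma:
                assert st1.asthma
                assert st1.index_date <= st0.index_date


class TestStatusInvariants:
    def test_index_date_iff_asthma(self):
        with pytest.raises(ValueError):
            AsthmaStatus("P1", "none", False, D("2002-01-01"))
        with pytest.raises(ValueError):
            AsthmaStatus("P1", "probable", True, None)

    def test_excluded_forces_flag_false(self):
        with pytest.raises(ValueError):
            AsthmaStatus("P1", "excluded", True, D("2002-01-01"))
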