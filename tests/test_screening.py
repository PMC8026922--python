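"""Screening logic: schedules, test hierarchies, per-lesion detection,
surveillance policy, and the pairing/dominance contracts."""

import math

import numpy as np
import pytest

from crcscreen import rng
from crcscreen.natural_history import NaturalHistoryParams, natural_course
from crcscreen.population import (
    ScriptedHistory,
    ScriptedLesion,
    make_scripted_individual,
    sample_cohort,
)
from crcscreen.scenarios import SensitivityArms, SizeClass, build_scenarios
from crcscreen.screening import TestProfile as StoolProfile
from crcscreen.screening import (
    ColonoscopyFindings,
    ColonoscopyProfile,
    DEFAULT_POLICY,
    FIT_PROFILE,
    MTSDNA_PROFILE,
    STRATEGY_COLONOSCOPY,
    STRATEGY_FIT,
    STRATEGY_MTSDNA,
    Strategy,
    colonoscopy,
    run_strategy,
    stool_test,
    surveillance_interval,
)

PARAMS = NaturalHistoryParams.default()
SCEN = {sdef.id: arms for sdef, arms in build_scenarios()}

PERFECT_STOOL = StoolProfile("FIT", 1.0, 1.0, 1.0, 1.0, 1)
NEVER_COMPLICATE = ColonoscopyProfile(
    full_reach_prob=1.0, complication_base=0.0, specificity=1.0
)


def flat_arms(p: float) -> SensitivityArms:
    m = {sc: p for sc in SizeClass}
    return SensitivityArms(base=dict(m), screening=dict(m), followup=dict(m))


def lesion_free(death=90.0, pid=0):
    return make_scripted_individual(
        ScriptedHistory(lesions=(), other_cause_death_age=death), individual_id=pid
    )


def one_lesion(onset, t10, death=90.0, pid=0, transition=None, sojourn=None):
    return make_scripted_individual(
        ScriptedHistory(
            lesions=(ScriptedLesion(onset, t10, transition, sojourn),),
            other_cause_death_age=death,
        ),
        individual_id=pid,
    )


class TestScheduleArithmetic:
    @pytest.mark.parametrize(
        "strategy,profile,n_stool,n_colo",
        [
            (STRATEGY_FIT, StoolProfile("FIT", 1, 1, 1, 1.0, 1), 26, 0),
            (STRATEGY_MTSDNA, StoolProfile("mt-sDNA", 1, 1, 1, 1.0, 3), 9, 0),
            (STRATEGY_COLONOSCOPY, None, 0, 3),
        ],
    )
    def test_lesion_free_exam_counts(self, strategy, profile, n_stool, n_colo):
        """Integer-age schedule, 100% adherence, perfect specificity:
        26 annual FIT (50..75), 9 triennial mt-sDNA (50,53,..,74), or
        3 ten-yearly colonoscopies (50,60,70)."""
        ind, hist = lesion_free()
        sh = run_strategy(
            ind, hist, strategy, SCEN[1], PARAMS,
            stool_profile=profile, colo_profile=NEVER_COMPLICATE,
        )
        assert sh.n_stool_tests == n_stool
        assert sh.n_colonoscopies == n_colo
        assert sh.crc_diagnosis_age is None
        assert sh.death_age == 90.0

    def test_colonoscopy_exam_ages(self):
        ind, hist = lesion_free()
        sh = run_strategy(
            ind, hist, STRATEGY_COLONOSCOPY, SCEN[1], PARAMS,
            colo_profile=NEVER_COMPLICATE,
        )
        assert [f.age for f in sh.exams] == [50, 60, 70]
        assert all(f.indication == "screening" for f in sh.exams)

    def test_screening_stops_at_death(self):
        ind, hist = lesion_free(death=57.5)
        sh = run_strategy(
            ind, hist, STRATEGY_FIT, SCEN[1], PARAMS,
            stool_profile=StoolProfile("FIT", 1, 1, 1, 1.0, 1),
            colo_profile=NEVER_COMPLICATE,
        )
        assert sh.n_stool_tests == 8          # ages 50..57
        assert sh.death_age == 57.5


class TestStoolTest:
    def test_perfect_specificity_never_fires(self):
        ind, hist = lesion_free()
        assert not any(
            stool_test(ind, hist, {}, age, StoolProfile("FIT", 1, 1, 1, 1.0, 1))
            for age in range(50, 76)
        )

    def test_certain_crc_detection(self):
        ind, hist = one_lesion(40, 8, transition=50.0, sojourn=10.0)
        assert stool_test(ind, hist, {}, 55, PERFECT_STOOL)

    def test_hierarchy_uses_most_advanced_lesion(self):
        # advanced adenoma present (>=10mm), sens_advanced=1, nonadv=0
        profile = StoolProfile("FIT", 0.0, 1.0, 0.0, 1.0, 1)
        ind, hist = one_lesion(40, 8)         # 10mm at 48
        assert stool_test(ind, hist, {}, 55, profile)
        # same lesion while still small, sens_nonadvanced=0 -> negative
        assert not stool_test(ind, hist, {}, 42, profile)

    def test_mtsdna_false_positive_rate(self):
        """With no lesions, positivity is 1 - specificity = 10.2%."""
        n = 100_000
        hits = 0
        for i in range(n):
            ind, hist = lesion_free(pid=i)
            hits += stool_test(ind, hist, {}, 60, MTSDNA_PROFILE)
        p = 1.0 - 0.898
        tol = 3 * math.sqrt(p * (1 - p) / n)
        assert hits / n == pytest.approx(p, abs=tol)

    def test_removed_lesion_is_invisible(self):
        ind, hist = one_lesion(40, 8)
        assert not stool_test(ind, hist, {0: 50.0}, 55, PERFECT_STOOL)


class TestColonoscopy:
    def test_blind_exam_detects_nothing(self):
        ind, hist = one_lesion(40, 8)
        f = colonoscopy(ind, hist, {}, 60, flat_arms(0.0).screening,
                        NEVER_COMPLICATE, "screening")
        assert f.n_present == 1 and f.n_detected == 0

    def test_large_adenoma_base_detection_rate(self):
        """A 12 mm adenoma under the base-case screening arm (95% for
        >=10 mm) is found in ~95% of exams."""
        t10 = 10 * math.log(10) / math.log(12)       # 12 mm at onset+10
        n = 100_000
        det = 0
        for i in range(n):
            ind, hist = one_lesion(50, t10, pid=i)
            f = colonoscopy(ind, hist, {}, 60, SCEN[1].screening,
                            NEVER_COMPLICATE, "screening")
            det += f.n_detected
        tol = 3 * math.sqrt(0.95 * 0.05 / n)
        assert det / n == pytest.approx(0.95, abs=tol)

    def test_scenario10_arm_gap_for_large_adenoma(self):
        """Scenario 10 large: screening 87.5% vs follow-up 98.1%; the
        paired per-lesion uniforms make the detection-rate gap ~10.6 pp
        and detection pathwise monotone across arms."""
        t10 = 10 * math.log(10) / math.log(12)
        n = 100_000
        d_scr = d_fup = 0
        for i in range(n):
            ind, hist = one_lesion(50, t10, pid=i)
            fs = colonoscopy(ind, hist, {}, 60, SCEN[10].screening,
                             NEVER_COMPLICATE, "screening")
            ff = colonoscopy(ind, hist, dict(), 60, SCEN[10].followup,
                             NEVER_COMPLICATE, "followup")
            assert ff.n_detected >= fs.n_detected
            d_scr += fs.n_detected
            d_fup += ff.n_detected
        gap = (d_fup - d_scr) / n
        expected = 0.98099 - 0.87545
        tol = 3 * math.sqrt(expected * (1 - expected) / n)
        assert gap == pytest.approx(expected, abs=tol)

    def test_detected_adenoma_is_removed(self):
        ind, hist = one_lesion(40, 8)
        removed = {}
        f = colonoscopy(ind, hist, removed, 60, flat_arms(1.0).screening,
                        NEVER_COMPLICATE, "screening")
        assert f.n_detected == 1
        assert removed == {0: 60.0}

    def test_partial_reach_counts_two_exams(self):
        never_reach = ColonoscopyProfile(full_reach_prob=0.0,
                                         complication_base=0.0, specificity=1.0)
        ind, hist = lesion_free()
        f = colonoscopy(ind, hist, {}, 60, flat_arms(1.0).screening,
                        never_reach, "screening")
        assert f.n_exams == 2 and not f.reach_full_first_pass

    def test_unknown_indication_rejected(self):
        ind, hist = lesion_free()
        with pytest.raises(Exception):
            colonoscopy(ind, hist, {}, 60, flat_arms(1.0).screening,
                        NEVER_COMPLICATE, "elective")


class TestSurveillancePolicy:
    def mk(self, n, large):
        return ColonoscopyFindings(60, "followup", n, n, large, None, True, 1, 0, False)

    def test_negative_exam_exits(self):
        assert surveillance_interval(self.mk(0, False)) is None

    def test_one_large_adenoma_short_interval(self):
        assert surveillance_interval(self.mk(1, True)) == 3

    def test_two_small_adenomas_long_interval(self):
        assert surveillance_interval(self.mk(2, False)) == 5

    def test_three_small_adenomas_short_interval(self):
        assert surveillance_interval(self.mk(3, False)) == 3


class TestRunStrategy:
    def test_positive_stool_triggers_same_epoch_colonoscopy(self):
        ind, hist = one_lesion(40, 8)          # advanced adenoma from 48
        sh = run_strategy(
            ind, hist, STRATEGY_FIT, flat_arms(1.0), PARAMS,
            stool_profile=PERFECT_STOOL, colo_profile=NEVER_COMPLICATE,
        )
        stool_pos = [e for e in sh.events if e[1] == "stool+"]
        colos = [e for e in sh.events if e[1] == "colonoscopy"]
        assert stool_pos and colos
        assert colos[0][0] == stool_pos[0][0] == 50
        assert colos[0][2] == "followup"
        assert sh.first_followup_age == 50
        assert sh.first_followup_detected
        # detected (removed) -> surveillance; the lesion is gone so the
        # next exam is negative and screening returns to stool testing
        assert sh.crc_diagnosis_age is None

    def test_removal_prevents_cancer(self):
        """A lesion destined to transform at 65 is removed at the age-60
        colonoscopy under perfect sensitivity: no CRC ever occurs."""
        ind, hist = one_lesion(50, 9, transition=65.0, sojourn=3.0, death=90.0)
        sh = run_strategy(
            ind, hist, STRATEGY_COLONOSCOPY, flat_arms(1.0), PARAMS,
            colo_profile=NEVER_COMPLICATE,
        )
        assert sh.crc_diagnosis_age is None
        assert sh.death_age == 90.0
        # while with zero sensitivity the cancer surfaces clinically at 68
        sh0 = run_strategy(
            ind, hist, STRATEGY_COLONOSCOPY, flat_arms(0.0), PARAMS,
            colo_profile=NEVER_COMPLICATE,
        )
        assert sh0.crc_diagnosis_age == pytest.approx(68.0)

    def test_scenario1_arm_label_invariance(self):
        """When both arms are equal (scenario 1), flipping the FIT
        arm-assignment switch changes nothing."""
        cohort = sample_cohort(300, seed=41)
        for ind in cohort:
            hist = natural_course(ind, PARAMS)
            a = run_strategy(ind, hist, STRATEGY_FIT, SCEN[1], PARAMS,
                             fit_screening_arm=False, record_events=False)
            b = run_strategy(ind, hist, STRATEGY_FIT, SCEN[1], PARAMS,
                             fit_screening_arm=True, record_events=False)
            assert (a.death_age, a.crc_diagnosis_age, a.n_colonoscopies) == (
                b.death_age, b.crc_diagnosis_age, b.n_colonoscopies
            )

    def test_sensitivity_dominance(self):
        """Raising colonoscopy sensitivity (paired substreams) never
        decreases total detections and never increases CRC cases."""
        cohort = sample_cohort(2000, seed=43)
        hists = [natural_course(ind, PARAMS) for ind in cohort]
        det = {}
        cases = {}
        for p in (0.5, 0.9):
            arms = flat_arms(p)
            d = c = 0
            for ind, hist in zip(cohort, hists):
                sh = run_strategy(ind, hist, STRATEGY_COLONOSCOPY, arms,
                                  PARAMS, record_events=False)
                d += sum(f.n_detected for f in sh.exams)
                c += sh.crc_diagnosis_age is not None
            det[p], cases[p] = d, c
        assert det[0.9] >= det[0.5]
        assert cases[0.9] <= cases[0.5]

    def test_surveillance_capped_at_stop_age(self):
        """Exams never occur after the surveillance stop age."""
        cohort = sample_cohort(500, seed=47)
        for ind in cohort:
            hist = natural_course(ind, PARAMS)
            sh = run_strategy(ind, hist, STRATEGY_COLONOSCOPY, SCEN[5],
                              PARAMS, record_events=False)
            assert all(f.age <= DEFAULT_POLICY.stop_age for f in sh.exams)

    def test_no_events_after_death(self):
        cohort = sample_cohort(500, seed=53)
        for ind in cohort:
            hist = natural_course(ind, PARAMS)
            sh = run_strategy(ind, hist, STRATEGY_MTSDNA, SCEN[5], PARAMS)
            for e in sh.events:
                assert e[0] <= sh.death_age + 1e-9


def test_strategy_validation():
    with pytest.raises(Exception):
        Strategy("FIT", 1, start_age=80, stop_age=75)
    with pytest.raises(Exception):
        Strategy("FIT", 1, adherence=0.8)
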