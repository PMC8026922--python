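"""Screening strategies applied to latent disease histories.

Three strategies are modeled at 100% adherence between ages 50 and 75:
colonoscopy every 10 years, annual FIT, and triennial mt-sDNA.  Stool
tests are one Bernoulli draw per exam keyed to the person's most advanced
lesion (preclinical CRC > advanced adenoma (>=10 mm) > non-advanced
adenoma > none, the last giving the false-positive draw).  A positive
stool test always triggers a follow-up colonoscopy at the same decision
epoch.  Colonoscopy detects each in-reach lesion independently with a
size-class sensitivity that depends on the exam's *indication arm*:
primary screening exams use the screening arm, follow-up and surveillance
exams the follow-up/surveillance arm.  Detected adenomas are removed
(cancelling any later transformation); detected preclinical cancers are
diagnosed with a screen-detected stage.  Findings drive guideline-style
surveillance intervals (3 y / 5 y / exit) until age 85.

The latent history is never mutated: removals and diagnoses live in
per-run state, so one history serves every strategy and scenario with
common random numbers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

from . import natural_history as nh
from .population import ConfigError, Individual
from .rng import (
    P_COMPLICATION,
    P_DETECT,
    P_FALSEPOS,
    P_REACH,
    P_STOOL,
    u01,
)
from .scenarios import SensitivityArms, SizeClass

COLONOSCOPY = "colonoscopy"
FIT = "FIT"
MTSDNA = "mt-sDNA"

SCREENING = "screening"
FOLLOWUP = "followup"
SURVEILLANCE = "surveillance"


@dataclass(frozen=True)
class TestProfile:
    """Per-person stool-test characteristics.

    ``sens_by_size_location`` and ``specificity_by_age`` are optional
    refinements (size- and segment-specific sensitivity, age-banded
    specificity) used by the updated-inputs analysis schema; when absent
    the scalar fields apply.
    """

    name: str
    sens_crc: float
    sens_advanced_adenoma: float
    sens_nonadvanced_adenoma: float
    specificity: float
    interval_years: int
    sens_by_size_location: Optional[dict] = None   # {(size, segment): p}
    specificity_by_age: Optional[Sequence] = None  # [[age_from, spec], ...]

    def specificity_at(self, age: float) -> float:
        if not self.specificity_by_age:
            return self.specificity
        spec = self.specificity_by_age[0][1]
        for a0, s in self.specificity_by_age:
            if age >= a0:
                spec = s
        return spec


FIT_PROFILE = TestProfile(FIT, 0.738, 0.238, 0.076, 0.964, 1)
MTSDNA_PROFILE = TestProfile(MTSDNA, 0.923, 0.424, 0.172, 0.898, 3)


@dataclass(frozen=True)
class ColonoscopyProfile:
    """Per-lesion colonoscopy characteristics (arm sensitivity aside)."""

    sens_crc_within_reach: float = 0.95
    specificity: float = 0.86           # 1-spec -> unnecessary polypectomy
    full_reach_prob: float = 0.95
    # age-based complication risk per exam: base * exp(slope*(age-ref))
    complication_base: float = 0.0025
    complication_log_slope: float = 0.03
    complication_ref_age: float = 50.0

    def complication_risk(self, age: float) -> float:
        return min(
            1.0,
            self.complication_base
            * math.exp(self.complication_log_slope * (age - self.complication_ref_age)),
        )


DEFAULT_COLONOSCOPY = ColonoscopyProfile()


@dataclass(frozen=True)
class Strategy:
    modality: str
    interval_years: int
    start_age: int = 50
    stop_age: int = 75
    adherence: float = 1.0

    def __post_init__(self):
        if self.start_age >= self.stop_age:
            raise ConfigError("start_age must precede stop_age")
        if self.adherence != 1.0:
            raise ConfigError("only 100% adherence is modeled")

    def exam_ages(self) -> list[int]:
        return list(range(self.start_age, self.stop_age + 1, self.interval_years))


STRATEGY_COLONOSCOPY = Strategy(COLONOSCOPY, 10)
STRATEGY_FIT = Strategy(FIT, 1)
STRATEGY_MTSDNA = Strategy(MTSDNA, 3)


@dataclass(frozen=True)
class SurveillancePolicy:
    """Findings -> next-interval mapping (guideline-style default).

    >=1 large (>=10 mm) adenoma or >= ``many_threshold`` adenomas -> short
    interval; 1-2 non-large adenomas -> long interval; no adenomas -> exit
    surveillance (the stool-test schedule resumes 10 years later).
    """

    interval_high_risk: int = 3
    interval_low_risk: int = 5
    many_threshold: int = 3
    stop_age: int = 85

    def next_interval(self, n_adenomas: int, any_large: bool) -> Optional[int]:
        if n_adenomas <= 0:
            return None
        if any_large or n_adenomas >= self.many_threshold:
            return self.interval_high_risk
        return self.interval_low_risk


DEFAULT_POLICY = SurveillancePolicy()


def surveillance_interval(findings: "ColonoscopyFindings",
                          policy: SurveillancePolicy = DEFAULT_POLICY) -> Optional[int]:
    """Years until the next surveillance exam, or None to exit surveillance."""
    return policy.next_interval(findings.n_detected, findings.any_large_detected)


@dataclass
class ColonoscopyFindings:
    age: int
    indication: str
    n_present: int                      # adenomas present (latent truth)
    n_detected: int
    any_large_detected: bool
    crc_lesion: Optional[nh.Adenoma]    # preclinical cancer found, if any
    reach_full_first_pass: bool
    n_exams: int                        # 1, or 2 after a partial-reach repeat
    n_complications: int
    false_positive_polypectomy: bool


@dataclass
class ScreenedHistory:
    """Dated event log plus the outcome of one strategy pass."""

    individual_id: int
    events: list = field(default_factory=list)   # (age, type, indication)
    exams: list[ColonoscopyFindings] = field(default_factory=list)
    n_stool_tests: int = 0
    n_colonoscopies: int = 0
    n_complications: int = 0
    crc_diagnosis_age: Optional[float] = None
    crc_stage: Optional[str] = None
    crc_screen_detected: bool = False
    crc_death_age: Optional[float] = None
    death_age: float = 0.0
    first_followup_age: Optional[int] = None
    first_followup_detected: Optional[bool] = None


def stool_test(
    ind: Individual,
    history: nh.DiseaseHistory,
    removed: dict,
    age: int,
    profile: TestProfile,
) -> bool:
    """One per-person stool-test draw at ``age`` (True = positive).

    Sensitivity follows the most advanced lesion present; with no lesion
    the draw is a false positive with probability 1 - specificity.
    """
    has_crc = False
    has_advanced = False
    has_adenoma = False
    for a in history.adenomas:
        r = removed.get(a.id)
        if a.is_preclinical_at(age, r):
            has_crc = True
            break
        if a.is_adenoma_at(age, r):
            has_adenoma = True
            if a.diameter(age) >= 10.0:
                has_advanced = True
    if has_crc:
        p = profile.sens_crc
    elif has_advanced:
        p = profile.sens_advanced_adenoma
    elif has_adenoma:
        p = profile.sens_nonadvanced_adenoma
    else:
        p = 1.0 - profile.specificity_at(age)
    return u01(ind.key, P_STOOL, age) < p


def colonoscopy(
    ind: Individual,
    history: nh.DiseaseHistory,
    removed: dict,
    age: int,
    sens_by_size: dict,
    profile: ColonoscopyProfile,
    indication: str,
) -> ColonoscopyFindings:
    """Perform one colonoscopy; updates ``removed`` in place.

    Partial reach (probability 1 - full_reach_prob) triggers an immediate
    completed repeat: both exams are counted, detection is evaluated once
    at full reach.  Each adenoma present is an independent Bernoulli at the
    arm's size-class sensitivity; a preclinical cancer is found with the
    within-reach CRC sensitivity.  With probability 1 - specificity a
    non-adenomatous polypectomy occurs (complication exposure only).
    """
    if indication not in (SCREENING, FOLLOWUP, SURVEILLANCE):
        raise ConfigError(f"unknown colonoscopy indication: {indication}")
    key = ind.key
    full = u01(key, P_REACH, age) < profile.full_reach_prob
    n_exams = 1 if full else 2
    n_present = 0
    n_detected = 0
    any_large = False
    crc_lesion = None
    for a in history.adenomas:
        r = removed.get(a.id)
        if a.is_preclinical_at(age, r):
            if crc_lesion is None and u01(key, P_DETECT, a.id, age) < profile.sens_crc_within_reach:
                crc_lesion = a
            continue
        if not a.is_adenoma_at(age, r):
            continue
        n_present += 1
        d = a.diameter(age)
        if u01(key, P_DETECT, a.id, age) < sens_by_size[SizeClass.of_diameter(d)]:
            n_detected += 1
            removed[a.id] = float(age)
            if d >= 10.0:
                any_large = True
    false_pos = u01(key, P_FALSEPOS, age) < 1.0 - profile.specificity
    n_compl = 0
    risk = profile.complication_risk(age)
    for k in range(n_exams):
        if u01(key, P_COMPLICATION, age, k) < risk:
            n_compl += 1
    return ColonoscopyFindings(
        age=age,
        indication=indication,
        n_present=n_present,
        n_detected=n_detected,
        any_large_detected=any_large,
        crc_lesion=crc_lesion,
        reach_full_first_pass=full,
        n_exams=n_exams,
        n_complications=n_compl,
        false_positive_polypectomy=false_pos,
    )


def _earliest_clinical(history: nh.DiseaseHistory, removed: dict,
                       after: float) -> tuple[Optional[nh.Adenoma], float]:
    """Earliest clinical presentation strictly after ``after`` among lesions
    whose transformation was not prevented by removal."""
    best, best_age = None, math.inf
    for a in history.adenomas:
        ca = a.clinical_age
        if ca is None or ca <= after or ca >= best_age:
            continue
        r = removed.get(a.id)
        if r is not None and r < a.transition_age:
            continue
        best, best_age = a, ca
    return best, best_age


def run_strategy(
    ind: Individual,
    history: nh.DiseaseHistory,
    strategy: Strategy,
    arms: SensitivityArms,
    params: nh.NaturalHistoryParams,
    policy: SurveillancePolicy = DEFAULT_POLICY,
    stool_profile: Optional[TestProfile] = None,
    colo_profile: ColonoscopyProfile = DEFAULT_COLONOSCOPY,
    fit_screening_arm: bool = False,
    record_events: bool = True,
) -> ScreenedHistory:
    """Simulate one strategy for one person against their latent history.

    Exams fall on integer ages from ``start_age`` in steps of the strategy
    interval (100% adherence); all screening stops at CRC diagnosis, death,
    or the surveillance stop age.  ``fit_screening_arm=True`` is the
    arm-reassignment switch: FIT-triggered colonoscopies then use the
    screening arm instead of the follow-up/surveillance arm.
    """
    if stool_profile is None and strategy.modality == FIT:
        stool_profile = FIT_PROFILE
    elif stool_profile is None and strategy.modality == MTSDNA:
        stool_profile = MTSDNA_PROFILE

    sh = ScreenedHistory(individual_id=ind.id)
    removed: dict[int, float] = {}
    is_stool = strategy.modality in (FIT, MTSDNA)
    followup_arm = (
        arms.screening
        if (fit_screening_arm and strategy.modality == FIT)
        else arms.followup
    )
    ocd = ind.other_cause_death_age
    ev = sh.events.append if record_events else (lambda e: None)

    def do_colonoscopy(age: int, indication: str, sens: dict) -> ColonoscopyFindings:
        f = colonoscopy(ind, history, removed, age, sens, colo_profile, indication)
        sh.n_colonoscopies += f.n_exams
        sh.n_complications += f.n_complications
        sh.exams.append(f)
        ev((age, "colonoscopy", indication))
        if f.n_exams == 2:
            ev((age, "colonoscopy", indication))
        if f.n_detected > 0 or f.false_positive_polypectomy:
            ev((age, "polypectomy", indication))
        for _ in range(f.n_complications):
            ev((age, "complication", indication))
        if indication == FOLLOWUP and sh.first_followup_age is None:
            sh.first_followup_age = age
            sh.first_followup_detected = f.n_detected > 0
        return f

    def screen_diagnose(age: int, lesion: nh.Adenoma):
        stage, crc_death = nh.diagnose(ind, history, lesion, float(age), True, params)
        sh.crc_diagnosis_age = float(age)
        sh.crc_stage = stage
        sh.crc_screen_detected = True
        sh.crc_death_age = crc_death
        ev((age, "crc_dx", "screen"))

    age = strategy.start_age
    mode = "routine"
    last_time = 0.0
    while sh.crc_diagnosis_age is None:
        if mode == "routine" and age > strategy.stop_age:
            break
        if mode == "surveillance" and age > policy.stop_age:
            break
        # clinical presentation before this exam pre-empts it
        lesion, ca = _earliest_clinical(history, removed, last_time)
        if ca < min(age, ocd):
            stage, crc_death = nh.diagnose(ind, history, lesion, ca, False, params)
            sh.crc_diagnosis_age = ca
            sh.crc_stage = stage
            sh.crc_death_age = crc_death
            ev((ca, "crc_dx", "clinical"))
            break
        if age >= ocd:
            break
        last_time = float(age)

        if mode == "routine" and is_stool:
            sh.n_stool_tests += 1
            pos = stool_test(ind, history, removed, age, stool_profile)
            ev((age, "stool+" if pos else "stool-", SCREENING))
            if not pos:
                age += strategy.interval_years
                continue
            f = do_colonoscopy(age, FOLLOWUP, followup_arm)
            if f.crc_lesion is not None:
                screen_diagnose(age, f.crc_lesion)
                break
            iv = surveillance_interval(f, policy)
            if iv is None:
                age += 10                      # negative follow-up: resume stool testing
            else:
                mode = "surveillance"
                age += iv
        elif mode == "routine":                # colonoscopy as primary modality
            f = do_colonoscopy(age, SCREENING, arms.screening)
            if f.crc_lesion is not None:
                screen_diagnose(age, f.crc_lesion)
                break
            iv = surveillance_interval(f, policy)
            if iv is None:
                age += strategy.interval_years
            else:
                mode = "surveillance"
                age += iv
        else:                                  # surveillance (any modality)
            f = do_colonoscopy(age, SURVEILLANCE, followup_arm)
            if f.crc_lesion is not None:
                screen_diagnose(age, f.crc_lesion)
                break
            iv = surveillance_interval(f, policy)
            if iv is None:
                mode = "routine"
                age += 10
            else:
                age += iv

    # clinical presentation after screening ends
    if sh.crc_diagnosis_age is None:
        lesion, ca = _earliest_clinical(history, removed, last_time)
        if ca < ocd:
            stage, crc_death = nh.diagnose(ind, history, lesion, ca, False, params)
            sh.crc_diagnosis_age = ca
            sh.crc_stage = stage
            sh.crc_death_age = crc_death
            ev((ca, "crc_dx", "clinical"))

    sh.death_age = min(
        ocd, sh.crc_death_age if sh.crc_death_age is not None else math.inf
    )
    ev((sh.death_age, "death", ""))
    return sh


def export_event_log(histories: Sequence[ScreenedHistory], path) -> None:
    """Event log as CSV: one row per event (id, age, type, indication)."""
    import pandas as pd

    rows = [
        {"id": h.individual_id, "age": e[0], "type": e[1], "indication": e[2]}
        for h in histories
        for e in h.events
    ]
    pd.DataFrame(rows, columns=["id", "age", "type", "indication"]).to_csv(
        path, index=False
    )
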