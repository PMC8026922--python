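"""Per-1000 outcome aggregation: LYG, reductions, resource use, AMR, ADR.

All outcomes are normalised per 1000 individuals alive and free of
diagnosed CRC at exact age 40 (the eligibility condition), and compare a
screened pass against the paired no-screening counterfactual of the same
cohort (common random numbers).  Life-years gained are undiscounted
within-person differences in death age.

The adenoma miss rate (AMR) is a weighted mean of single-year-of-age
cross-sections: at each age, missed adenomas over adenomas present among
all colonoscopies performed at that age (all indications pooled by
default), weighted by the number of colonoscopies at that age.  The
adenoma detection rate (ADR) for stool-test strategies is the fraction of
first follow-up colonoscopies finding at least one adenoma.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

from .natural_history import DiseaseHistory
from .screening import ScreenedHistory, SCREENING


@dataclass
class OutcomeTable:
    """Aggregate metrics for one strategy x scenario cell (per 1000
    eligible unless a field name says otherwise)."""

    strategy: str
    scenario: int
    n_eligible: int
    lyg: float = math.nan
    crc_cases: float = math.nan
    crc_deaths: float = math.nan
    incidence_reduction_pct: Optional[float] = None
    mortality_reduction_pct: Optional[float] = None
    stool_tests: float = 0.0
    colonoscopies: float = 0.0
    complications: float = 0.0
    life_years_with_crc: float = 0.0
    weighted_amr_pct: Optional[float] = None
    adr_first_followup_pct: Optional[float] = None
    mean_age_first_followup: Optional[float] = None
    pct_lyg_vs_colonoscopy: Optional[float] = None

    def to_dict(self) -> dict:
        return asdict(self)


def per1000(metric_sum: float, eligible_n: int) -> float:
    """Normalise a cohort sum to the per-1000-eligible scale."""
    if eligible_n <= 0:
        raise ValueError("no eligible individuals in denominator")
    return metric_sum / eligible_n * 1000.0


def lyg(screened: Sequence[ScreenedHistory],
        unscreened: Sequence[DiseaseHistory],
        eligible: Sequence[bool]) -> float:
    """Life-years gained per 1000 eligible, paired by individual."""
    if len(screened) != len(unscreened):
        raise ValueError("screened and unscreened passes are unpaired")
    total = 0.0
    n = 0
    for s, u, ok in zip(screened, unscreened, eligible):
        if s.individual_id != u.individual_id:
            raise ValueError("screened and unscreened passes are unpaired")
        if not ok:
            continue
        total += s.death_age - u.death_age
        n += 1
    return per1000(total, n)


def reductions(cases_s: float, cases_u: float,
               deaths_s: float, deaths_u: float):
    """(incidence, mortality) percent reduction vs no screening; a zero
    unscreened denominator yields None (undefined)."""
    inc = 100.0 * (1.0 - cases_s / cases_u) if cases_u > 0 else None
    mort = 100.0 * (1.0 - deaths_s / deaths_u) if deaths_u > 0 else None
    return inc, mort


def weighted_amr(screened: Sequence[ScreenedHistory],
                 eligible: Sequence[bool],
                 indication: Optional[str] = None) -> Optional[float]:
    """Weighted mean adenoma miss rate, percent.

    Cross-section = single year of age; AMR(age) = missed / present among
    the colonoscopies at that age; weights = colonoscopy count at that
    age.  ``indication`` restricts to one indication (e.g. screening-only
    exams for the colonoscopy strategy); default pools all indications.
    """
    present_by_age: dict[int, int] = {}
    missed_by_age: dict[int, int] = {}
    exams_by_age: dict[int, int] = {}
    for sh, ok in zip(screened, eligible):
        if not ok:
            continue
        for f in sh.exams:
            if indication is not None and f.indication != indication:
                continue
            exams_by_age[f.age] = exams_by_age.get(f.age, 0) + 1
            present_by_age[f.age] = present_by_age.get(f.age, 0) + f.n_present
            missed_by_age[f.age] = (
                missed_by_age.get(f.age, 0) + f.n_present - f.n_detected
            )
    num = 0.0
    den = 0.0
    for age, n_exams in exams_by_age.items():
        if present_by_age[age] == 0:
            continue
        amr_age = missed_by_age[age] / present_by_age[age]
        num += amr_age * n_exams
        den += n_exams
    if den == 0:
        return None
    return 100.0 * num / den


def adr_first_followup(screened: Sequence[ScreenedHistory],
                       eligible: Sequence[bool]):
    """(ADR percent, mean exam age) over first follow-up colonoscopies."""
    n = 0
    n_det = 0
    age_sum = 0.0
    for sh, ok in zip(screened, eligible):
        if not ok or sh.first_followup_age is None:
            continue
        n += 1
        age_sum += sh.first_followup_age
        if sh.first_followup_detected:
            n_det += 1
    if n == 0:
        return None, None
    return 100.0 * n_det / n, age_sum / n


def pct_lyg_vs_colonoscopy(lyg_strategy: float,
                           lyg_colonoscopy: float) -> Optional[float]:
    """Percent of the colonoscopy strategy's LYG achieved by a strategy."""
    if lyg_colonoscopy == 0:
        return None
    return 100.0 * lyg_strategy / lyg_colonoscopy


def aggregate(
    strategy: str,
    scenario: int,
    screened: Sequence[ScreenedHistory],
    unscreened: Sequence[DiseaseHistory],
    amr_indication: Optional[str] = None,
) -> OutcomeTable:
    """Build the full outcome table for one strategy x scenario cell."""
    eligible = [u.eligible_at_40() for u in unscreened]
    n_elig = sum(eligible)
    if n_elig == 0:
        raise ValueError("no eligible individuals")

    cases_s = deaths_s = 0.0
    cases_u = deaths_u = 0.0
    stool = colos = compl = ly_crc = 0.0
    for s, u, ok in zip(screened, unscreened, eligible):
        if not ok:
            continue
        if s.crc_diagnosis_age is not None:
            cases_s += 1
            ly_crc += s.death_age - s.crc_diagnosis_age
            if s.crc_death_age is not None and s.crc_death_age <= s.death_age:
                deaths_s += 1
        if u.crc_diagnosis_age is not None:
            cases_u += 1
            if u.crc_death_age is not None and u.crc_death_age <= u.death_age:
                deaths_u += 1
        stool += s.n_stool_tests
        colos += s.n_colonoscopies
        compl += s.n_complications

    inc_red, mort_red = reductions(cases_s, cases_u, deaths_s, deaths_u)
    adr, adr_age = adr_first_followup(screened, eligible)
    return OutcomeTable(
        strategy=strategy,
        scenario=scenario,
        n_eligible=n_elig,
        lyg=lyg(screened, unscreened, eligible),
        crc_cases=per1000(cases_s, n_elig),
        crc_deaths=per1000(deaths_s, n_elig),
        incidence_reduction_pct=inc_red,
        mortality_reduction_pct=mort_red,
        stool_tests=per1000(stool, n_elig),
        colonoscopies=per1000(colos, n_elig),
        complications=per1000(compl, n_elig),
        life_years_with_crc=per1000(ly_crc, n_elig),
        weighted_amr_pct=weighted_amr(screened, eligible, amr_indication),
        adr_first_followup_pct=adr,
        mean_age_first_followup=adr_age,
    )


def unscreened_rates(unscreened: Sequence[DiseaseHistory]):
    """(cases, deaths) per 1000 eligible in the no-screening arm."""
    eligible = [u.eligible_at_40() for u in unscreened]
    n = sum(eligible)
    cases = sum(
        1 for u, ok in zip(unscreened, eligible)
        if ok and u.crc_diagnosis_age is not None
    )
    deaths = sum(
        1 for u, ok in zip(unscreened, eligible)
        if ok and u.crc_death_age is not None and u.crc_death_age <= u.death_age
    )
    return per1000(cases, n), per1000(deaths, n)
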