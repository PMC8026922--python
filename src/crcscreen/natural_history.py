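"""Latent disease engine: the adenoma–carcinoma sequence without screening.

Each person accrues adenomas from a non-homogeneous Poisson process whose
intensity is a piecewise-constant baseline age curve times the person's
frailty.  An adenoma starts at 1 mm and grows exponentially in diameter,
reaching 10 mm after a lognormally distributed time; its hazard of
malignant transformation rises as a power of current diameter.  A
transformed lesion is a preclinical (screen-detectable, asymptomatic)
cancer for a lognormal sojourn time, after which it surfaces clinically.
Stage at diagnosis is drawn from a categorical distribution that is
shifted toward earlier stages when the cancer is screen-detected, and
stage drives a cure-fraction-plus-exponential survival model.

The module is parameter-agnostic: every distribution above is set by a
``NaturalHistoryParams`` config that round-trips through plain dicts
(YAML/JSON).  The shipped defaults are this package's own placeholder
calibration producing an epidemiologically plausible unscreened cohort;
they are a documented slot, not an estimate of any published model's
values.

All sampling is counter-based per individual (see :mod:`crcscreen.rng`),
so a history is bit-identical whenever re-generated for the same person
and parameters — the counterfactual-stability contract paired comparisons
rely on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

from . import rng
from .rng import (
    CounterStream,
    P_GROWTH,
    P_ONSET,
    P_SEGMENT,
    P_SOJOURN,
    P_STAGE,
    P_SURVIVAL,
    P_TRANSITION,
    u01,
)
from .population import ConfigError, Individual

STAGES = ("I", "II", "III", "IV")

SEGMENTS = ("rectum", "distal", "proximal", "cecum")
# marginal location distribution of adenomas along the colorectum
SEGMENT_PROBS = (0.20, 0.40, 0.30, 0.10)


DEFAULT_PARAMS_DICT = {
    "onset": {
        # piecewise-constant baseline intensity (events/person-year):
        # [start_age, rate]; zero before the first segment
        "segments": [
            [20, 0.002],
            [30, 0.005],
            [40, 0.012],
            [50, 0.022],
            [60, 0.032],
            [70, 0.038],
            [80, 0.040],
        ],
        "scale": 1.0,
        "use_frailty": True,
    },
    "growth": {
        # lognormal time from 1 mm to 10 mm, years
        "t10_mu": math.log(25.0),
        "t10_sigma": 0.8,
        "d_max_mm": 30.0,
    },
    "transition": {
        # hazard k * (d/10mm)^power per year, flat above d_max
        "k_at_10mm": 0.003,
        "size_power": 2.0,
    },
    "sojourn": {
        # lognormal preclinical dwell, years
        "mu": 1.25,
        "sigma": 0.55,
    },
    "stage": {
        "symptomatic": [0.18, 0.30, 0.28, 0.24],
        "screen": [0.48, 0.30, 0.15, 0.07],
    },
    "survival": {
        "cure": {"I": 0.92, "II": 0.78, "III": 0.55, "IV": 0.08},
        "mean_years": {"I": 10.0, "II": 7.0, "III": 4.5, "IV": 1.6},
    },
}


@dataclass
class NaturalHistoryParams:
    """Config container; ``from_dict``/``to_dict`` round-trip losslessly."""

    onset: dict
    growth: dict
    transition: dict
    sojourn: dict
    stage: dict
    survival: dict
    schema_version: int = 1

    @classmethod
    def default(cls) -> "NaturalHistoryParams":
        import copy

        return cls.from_dict(copy.deepcopy(DEFAULT_PARAMS_DICT))

    @classmethod
    def from_dict(cls, d: dict) -> "NaturalHistoryParams":
        p = cls(
            onset=d["onset"],
            growth=d["growth"],
            transition=d["transition"],
            sojourn=d["sojourn"],
            stage=d["stage"],
            survival=d["survival"],
            schema_version=d.get("schema_version", 1),
        )
        p.validate()
        return p

    def to_dict(self) -> dict:
        return asdict(self)

    def validate(self):
        for _, rate in self.onset["segments"]:
            if rate < 0:
                raise ConfigError("onset intensity must be non-negative")
        if self.transition["k_at_10mm"] < 0:
            raise ConfigError("transition hazard must be non-negative")
        for name in ("symptomatic", "screen"):
            probs = self.stage[name]
            if len(probs) != len(STAGES) or any(p < 0 for p in probs):
                raise ConfigError(f"invalid stage distribution: {name}")
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ConfigError(f"stage distribution {name} must sum to 1")


@dataclass
class Adenoma:
    """One adenoma and, if it transforms, the cancer it becomes.

    ``transition_age`` is the age of malignant transformation (None if the
    lesion never transforms before the host's other-cause death);
    ``clinical_age = transition_age + sojourn`` is when the cancer would
    surface symptomatically.  Removal is tracked per screening pass, not
    here: the latent history is immutable and shared across strategies.
    """

    id: int
    segment: str
    onset_age: float
    time_to_10mm: float
    transition_age: Optional[float] = None
    sojourn: Optional[float] = None
    d_max_mm: float = 50.0
    # scripted-fixture overrides (bypass sampled stage/survival)
    scripted_stage_symptomatic: Optional[str] = None
    scripted_stage_screen: Optional[str] = None
    scripted_survival_years: Optional[float] = None
    scripted_cured_if_screen: Optional[bool] = None

    @property
    def clinical_age(self) -> Optional[float]:
        if self.transition_age is None:
            return None
        return self.transition_age + self.sojourn

    def diameter(self, age: float) -> float:
        """Diameter in mm at ``age``: exponential growth, 1 mm at onset,
        10 mm at onset + time_to_10mm, capped at ``d_max_mm``."""
        if age < self.onset_age:
            raise ValueError("diameter queried before onset")
        g = math.log(10.0) / self.time_to_10mm
        return min(math.exp(g * (age - self.onset_age)), self.d_max_mm)

    def is_adenoma_at(self, age: float, removed_age: Optional[float]) -> bool:
        """Still a (benign) adenoma at ``age``?"""
        if age < self.onset_age:
            return False
        if removed_age is not None and age >= removed_age:
            return False
        return self.transition_age is None or age < self.transition_age

    def is_preclinical_at(self, age: float, removed_age: Optional[float]) -> bool:
        """A preclinical cancer at ``age``?  (Removal before transformation
        prevents the cancer; removal is impossible afterwards.)"""
        if self.transition_age is None or age < self.transition_age:
            return False
        if removed_age is not None and removed_age < self.transition_age:
            return False
        return age < self.clinical_age


@dataclass
class DiseaseHistory:
    """The latent (no-intervention) timeline of one person, plus the
    no-screening counterfactual outcome fields filled by
    :func:`natural_course`."""

    individual_id: int
    adenomas: Sequence[Adenoma]
    other_cause_death_age: float
    scripted: bool = False
    # no-screening counterfactual (set by natural_course)
    crc_diagnosis_age: Optional[float] = None
    crc_stage: Optional[str] = None
    crc_death_age: Optional[float] = None
    death_age: float = field(default=0.0)

    def eligible_at_40(self) -> bool:
        """Alive and free of diagnosed CRC at exact age 40 — the
        denominator condition for all per-1000 outcomes."""
        if self.other_cause_death_age <= 40.0:
            return False
        return self.crc_diagnosis_age is None or self.crc_diagnosis_age > 40.0


# ---------------------------------------------------------------------------
# sampling


def _poisson_inverse(mean: float, stream: CounterStream) -> int:
    """Poisson sample by CDF inversion from one stream uniform."""
    if mean <= 0.0:
        return 0
    u = stream.u()
    p = math.exp(-mean)
    cdf = p
    k = 0
    while u > cdf and k < 1000:
        k += 1
        p *= mean / k
        cdf += p
    return k


def sample_adenoma_onsets(
    ind: Individual,
    params: NaturalHistoryParams,
    stream: CounterStream | None = None,
    truncate_age: float | None = None,
) -> list[float]:
    """Onset ages from the NHPP with intensity baseline(age) x frailty.

    Truncated at ``truncate_age`` (defaults to the individual's other-cause
    death age).  Sampling is per piecewise-constant segment: a Poisson
    count then uniform placement, which is exact for this intensity.
    """
    if stream is None:
        stream = CounterStream(ind.key, P_ONSET)
    stop = ind.other_cause_death_age if truncate_age is None else truncate_age
    scale = params.onset.get("scale", 1.0)
    frailty = ind.frailty if params.onset.get("use_frailty", True) else 1.0
    segs = params.onset["segments"]
    onsets: list[float] = []
    for i, (a0, rate) in enumerate(segs):
        a1 = segs[i + 1][0] if i + 1 < len(segs) else 1e9
        lo, hi = a0, min(a1, stop)
        if hi <= lo:
            break
        mean = rate * scale * frailty * (hi - lo)
        k = _poisson_inverse(mean, stream)
        for _ in range(k):
            onsets.append(lo + stream.u() * (hi - lo))
    onsets.sort()
    return onsets


def cumulative_onset_intensity(params: NaturalHistoryParams, age: float) -> float:
    """Integral of the baseline (frailty-1) intensity from birth to ``age``.

    The exposure measure used by the calibration hook: expected lifetime
    adenoma count for a person dying at ``age`` is scale x frailty x this.
    """
    segs = params.onset["segments"]
    scale = params.onset.get("scale", 1.0)
    total = 0.0
    for i, (a0, rate) in enumerate(segs):
        a1 = segs[i + 1][0] if i + 1 < len(segs) else 1e9
        total += rate * max(0.0, min(a1, age) - a0)
    return scale * total


def sample_transition_offset(
    t10: float, params: NaturalHistoryParams, u: float
) -> float:
    """Years from adenoma onset to malignant transformation (may be inf).

    The hazard k*(d/10)^p is integrated in closed form along the
    exponential growth curve d(t) = exp(ln(10) t / t10), flat once the
    diameter caps at d_max.
    """
    k = params.transition["k_at_10mm"]
    p = params.transition["size_power"]
    if k <= 0.0:
        return math.inf
    target = -math.log(u)                     # exp(1) cumulative-hazard target
    g = math.log(10.0) / t10
    d_max = params.growth.get("d_max_mm", 50.0)
    t_cap = math.log(d_max) / g               # age offset at which d hits cap
    a = k * 10.0 ** (-p)                      # hazard at t=0 (d = 1 mm)
    if p == 0.0:
        h_flat = k
        H_cap = k * t_cap
    else:
        pg = p * g
        H_cap = a / pg * (math.exp(pg * t_cap) - 1.0)
        h_flat = k * (d_max / 10.0) ** p
        if target < H_cap:
            return math.log(target * pg / a + 1.0) / pg
        return t_cap + (target - H_cap) / h_flat
    # p == 0: constant hazard
    return target / h_flat


def _lognormal_from_u(mu: float, sigma: float, u: float) -> float:
    from scipy.special import ndtri

    if sigma == 0.0:
        return math.exp(mu)
    return math.exp(mu + sigma * ndtri(u))


def _categorical_from_u(probs: Sequence[float], u: float) -> int:
    acc = 0.0
    for i, p in enumerate(probs):
        acc += p
        if u < acc:
            return i
    return len(probs) - 1


def sample_lesion(
    ind: Individual,
    lesion_id: int,
    onset_age: float,
    params: NaturalHistoryParams,
) -> Adenoma:
    """Growth, location, transformation and sojourn for one new adenoma.

    Uniforms are keyed by (individual, purpose, lesion id), so the lesion's
    fate is identical in every pass that generates it.
    """
    key = ind.key
    t10 = _lognormal_from_u(
        params.growth["t10_mu"], params.growth["t10_sigma"],
        u01(key, P_GROWTH, lesion_id),
    )
    seg = SEGMENTS[_categorical_from_u(SEGMENT_PROBS, u01(key, P_SEGMENT, lesion_id))]
    offset = sample_transition_offset(
        t10, params, u01(key, P_TRANSITION, lesion_id)
    )
    transition_age = onset_age + offset
    if transition_age >= ind.other_cause_death_age:
        transition_age = None
    sojourn = None
    if transition_age is not None:
        sojourn = _lognormal_from_u(
            params.sojourn["mu"], params.sojourn["sigma"],
            u01(key, P_SOJOURN, lesion_id),
        )
    return Adenoma(
        id=lesion_id,
        segment=seg,
        onset_age=onset_age,
        time_to_10mm=t10,
        transition_age=transition_age,
        sojourn=sojourn,
        d_max_mm=params.growth.get("d_max_mm", 50.0),
    )


def sample_history(ind: Individual, params: NaturalHistoryParams) -> DiseaseHistory:
    """The full latent history (no diagnosis fields filled)."""
    onsets = sample_adenoma_onsets(ind, params)
    adenomas = [
        sample_lesion(ind, j, onset, params) for j, onset in enumerate(onsets)
    ]
    return DiseaseHistory(
        individual_id=ind.id,
        adenomas=adenomas,
        other_cause_death_age=ind.other_cause_death_age,
    )


def diagnose(
    ind: Individual,
    history: DiseaseHistory,
    lesion: Adenoma,
    age_dx: float,
    screen_detected: bool,
    params: NaturalHistoryParams,
) -> tuple[str, Optional[float]]:
    """Stage at diagnosis and CRC death age (None if cured) for one cancer.

    The stage uniform is shared between the symptomatic and screen-detected
    distributions, and the survival uniforms are shared across stages, so
    screen detection is pathwise coupled to (never worse than) symptomatic
    presentation of the same lesion — the stage-shift benefit of screening
    with minimal Monte Carlo noise in paired comparisons.
    """
    if history.scripted:
        stage = (
            lesion.scripted_stage_screen
            if screen_detected
            else lesion.scripted_stage_symptomatic
        ) or "II"
        if screen_detected and lesion.scripted_cured_if_screen:
            return stage, None
        return stage, age_dx + (lesion.scripted_survival_years or 2.0)

    u_stage = u01(ind.key, P_STAGE, lesion.id)
    dist = params.stage["screen" if screen_detected else "symptomatic"]
    stage = STAGES[_categorical_from_u(dist, u_stage)]
    return stage, crc_survival(
        stage, age_dx, ind.sex, params, key=ind.key, lesion_id=lesion.id
    )


def crc_survival(
    stage: str,
    age_dx: float,
    sex: str,
    params: NaturalHistoryParams,
    key: int = 0,
    lesion_id: int = 0,
) -> Optional[float]:
    """CRC death age, or None if cured of this cancer.

    Cure-fraction + exponential residual survival; cure probabilities and
    mean survivals are stage-monotone, and both draws reuse the same
    uniforms across stages, so later stage gives pathwise shorter survival.
    ``age_dx`` and ``sex`` are accepted for config extensions; the default
    parameters do not vary by them.
    """
    if stage not in STAGES:
        raise ConfigError(f"unknown stage: {stage}")
    cure = params.survival["cure"][stage]
    if u01(key, P_SURVIVAL, lesion_id, 0) < cure:
        return None
    mean = params.survival["mean_years"][stage]
    t = -mean * math.log(u01(key, P_SURVIVAL, lesion_id, 1))
    return age_dx + t


def natural_course(
    ind: Individual,
    params: NaturalHistoryParams,
    history: DiseaseHistory | None = None,
) -> DiseaseHistory:
    """The no-screening counterfactual: latent history plus its outcome.

    The first cancer to surface clinically before other-cause death is the
    diagnosed CRC (one diagnosed CRC per person); death age is the minimum
    of the CRC and other-cause death ages.  Life-years lived equal
    ``death_age``.
    """
    if history is None:
        history = sample_history(ind, params)
    first = None
    for a in history.adenomas:
        ca = a.clinical_age
        if ca is not None and ca < ind.other_cause_death_age:
            if first is None or ca < first.clinical_age:
                first = a
    if first is not None:
        dx = first.clinical_age
        stage, crc_death = diagnose(ind, history, first, dx, False, params)
        history.crc_diagnosis_age = dx
        history.crc_stage = stage
        history.crc_death_age = crc_death
    history.death_age = min(
        ind.other_cause_death_age,
        history.crc_death_age if history.crc_death_age is not None else math.inf,
    )
    return history
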