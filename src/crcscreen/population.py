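"""Synthetic birth cohort: demographics, other-cause mortality, frailty.

The simulated population is a single birth cohort (default birth year 1975)
followed from birth.  Each individual carries

* an age at death from causes other than colorectal cancer, sampled from a
  cohort life table of annual death probabilities ``qx``;
* a positive frailty — a multiplicative factor on the adenoma-onset
  intensity capturing between-person risk heterogeneity (lognormal with
  mean 1 by default);
* a 64-bit substream key, so that the same person sees identical random
  numbers under every screening strategy and sensitivity scenario
  (common random numbers).

A packaged life table is shipped as a plain CSV (columns ``age,qx``); it is
a synthetic Gompertz–Makeham-style cohort table standing in for an
all-cause-minus-CRC 1975 cohort table, and any real table in the same
format can be dropped in.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import ndtri

from . import rng
from .rng import P_DEATH, P_FRAILTY, P_SEX


class ConfigError(ValueError):
    """Invalid or incomplete configuration."""


@dataclass(frozen=True)
class LifeTable:
    """Annual other-cause death probabilities by integer age.

    ``ages`` must be contiguous from 0 and the terminal entry must have
    ``qx == 1`` so every sampled lifetime is finite.
    """

    ages: np.ndarray
    qx: np.ndarray
    survival: np.ndarray = field(init=False, repr=False)  # S(k), len = n+1

    def __post_init__(self):
        ages = np.asarray(self.ages, dtype=int)
        qx = np.asarray(self.qx, dtype=float)
        if ages.size == 0 or ages[0] != 0 or np.any(np.diff(ages) != 1):
            raise ConfigError("life table ages must be contiguous from 0")
        if np.any((qx < 0) | (qx > 1)):
            raise ConfigError("life table qx must lie in [0,1]")
        if qx[-1] != 1.0:
            raise ConfigError("terminal life-table age must have qx = 1")
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "qx", qx)
        surv = np.concatenate([[1.0], np.cumprod(1.0 - qx)])
        object.__setattr__(self, "survival", surv)

    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        import pandas as pd

        df = pd.read_csv(path, comment="#")
        missing = {"age", "qx"} - set(df.columns)
        if missing:
            raise ConfigError(f"life table CSV missing columns: {missing}")
        df = df.sort_values("age")
        return cls(df["age"].to_numpy(), df["qx"].to_numpy())

    def survival_at(self, age: int) -> float:
        """P(other-cause death age >= age)."""
        if age <= 0:
            return 1.0
        return float(self.survival[min(age, len(self.qx))])


def default_life_table() -> LifeTable:
    """The packaged synthetic 1975-cohort-style life table."""
    with importlib.resources.as_file(
        importlib.resources.files("crcscreen.data") / "life_table_1975.csv"
    ) as p:
        return LifeTable.from_csv(p)


def make_default_life_table_arrays(max_age: int = 110):
    """Generate the synthetic cohort ``qx`` curve (Gompertz–Makeham shape).

    Infant mortality bump, a flat background hazard, and an exponentially
    rising senescent term; terminal age forced to 1.  This is synthetic
    plumbing — parameters were chosen once to give a cohort life expectancy
    near 78 years, not fit to any published table.
    """
    ages = np.arange(max_age + 1)
    qx = 4e-4 + 2.7e-5 * np.exp(0.095 * ages)
    qx[0] += 0.008
    qx[1:5] += 0.0004
    qx = np.clip(qx, 0.0, 1.0)
    qx[-1] = 1.0
    return ages, qx


@dataclass
class Individual:
    """A simulated person; ``key`` seeds all of their random substreams."""

    id: int
    sex: str                      # "F" | "M"
    birth_year: int
    frailty: float
    other_cause_death_age: float
    key: int

    def __post_init__(self):
        if self.frailty <= 0:
            raise ValueError("frailty must be positive")
        if self.other_cause_death_age <= 0:
            raise ValueError("other-cause death age must be positive")


def sample_other_cause_death(life_table: LifeTable, u: float) -> float:
    """Invert one uniform against the life-table survival curve.

    The death year is the k with S(k) > u >= S(k+1); the within-year timing
    reuses the same uniform's conditional position, so it is uniform on the
    year and the whole map u -> age is monotone (useful for coupling).
    """
    s = life_table.survival
    # searchsorted on the decreasing survival curve
    k = int(np.searchsorted(-s, -u, side="right")) - 1
    k = min(max(k, 0), len(s) - 2)
    denom = s[k] - s[k + 1]
    frac = (s[k] - u) / denom if denom > 0 else 0.5
    return float(life_table.ages[k] + min(max(frac, 0.0), 1.0 - 1e-12))


DEFAULT_FRAILTY = {"distribution": "lognormal", "sigma": 1.1}


def _frailty_from_u(u: float, params: dict) -> float:
    dist = params.get("distribution", "lognormal")
    if dist != "lognormal":
        raise ConfigError(f"unsupported frailty distribution: {dist}")
    sigma = float(params.get("sigma", DEFAULT_FRAILTY["sigma"]))
    if sigma < 0:
        raise ConfigError("frailty sigma must be >= 0")
    if sigma == 0.0:
        return 1.0
    # mean-1 parametrisation: mu = -sigma^2/2
    return float(np.exp(-0.5 * sigma * sigma + sigma * ndtri(u)))


def sample_cohort(
    n: int,
    life_table: LifeTable | None = None,
    frailty_params: dict | None = None,
    seed: int = 0,
    birth_year: int = 1975,
) -> list[Individual]:
    """Sample a reproducible cohort of ``n`` individuals.

    Each person's attributes come from counter-based uniforms under their
    own substream key, so cohorts are identical for a fixed seed and each
    person's randomness is stable across strategies and scenarios.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    lt = life_table if life_table is not None else default_life_table()
    fp = frailty_params if frailty_params is not None else DEFAULT_FRAILTY
    out = []
    for i in range(n):
        key = rng.individual_key(seed, i)
        death = sample_other_cause_death(lt, rng.u01(key, P_DEATH))
        frailty = _frailty_from_u(rng.u01(key, P_FRAILTY), fp)
        sex = "F" if rng.u01(key, P_SEX) < 0.5 else "M"
        out.append(Individual(i, sex, birth_year, frailty, death, key))
    return out


# ---------------------------------------------------------------------------
# Scripted (deterministic) histories for tests


@dataclass
class ScriptedLesion:
    """One adenoma fixed by the test author (no sampling downstream)."""

    onset_age: float
    time_to_10mm: float
    transition_age: float | None = None   # age of malignant transformation
    sojourn: float | None = None          # preclinical dwell if transitioned
    segment: str = "distal"

    def validate(self):
        if self.time_to_10mm <= 0:
            raise ValueError("time_to_10mm must be positive")
        if self.transition_age is not None:
            if self.transition_age <= self.onset_age:
                raise ValueError("transition must follow onset")
            if self.sojourn is None or self.sojourn <= 0:
                raise ValueError("transitioned lesion needs a positive sojourn")


@dataclass
class ScriptedHistory:
    """A fully scripted disease history (fixture; bypasses all sampling)."""

    lesions: Sequence[ScriptedLesion] = ()
    other_cause_death_age: float = 90.0
    frailty: float = 1.0
    sex: str = "F"
    stage_symptomatic: str = "III"
    stage_screen: str = "I"
    crc_survival_years: float = 2.0       # post-diagnosis survival if not cured
    cured_if_screen_detected: bool = True

    def validate(self):
        if self.other_cause_death_age <= 0:
            raise ValueError("death age must be positive")
        for les in self.lesions:
            les.validate()


def make_scripted_individual(spec: ScriptedHistory, individual_id: int = 0):
    """Build an (Individual, DiseaseHistory) pair from a script.

    Downstream modules treat the result identically to sampled histories;
    screening-side randomness still flows from the individual's key, so a
    scripted person is deterministic in natural history but not necessarily
    in test outcomes unless test probabilities are 0/1.
    """
    from . import natural_history as nh

    spec.validate()
    ind = Individual(
        id=individual_id,
        sex=spec.sex,
        birth_year=1975,
        frailty=spec.frailty,
        other_cause_death_age=spec.other_cause_death_age,
        key=rng.individual_key(0, individual_id),
    )
    adenomas = []
    for j, les in enumerate(spec.lesions):
        adenomas.append(
            nh.Adenoma(
                id=j,
                segment=les.segment,
                onset_age=les.onset_age,
                time_to_10mm=les.time_to_10mm,
                transition_age=les.transition_age,
                sojourn=les.sojourn,
                scripted_stage_symptomatic=spec.stage_symptomatic,
                scripted_stage_screen=spec.stage_screen,
                scripted_survival_years=spec.crc_survival_years,
                scripted_cured_if_screen=spec.cured_if_screen_detected,
            )
        )
    history = nh.DiseaseHistory(
        individual_id=individual_id,
        adenomas=adenomas,
        other_cause_death_age=spec.other_cause_death_age,
        scripted=True,
    )
    return ind, history
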