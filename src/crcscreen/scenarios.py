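"""Screening-vs-follow-up colonoscopy sensitivity scenarios.

Colonoscopy adenoma sensitivity is specified per lesion-size class
(small 1-5 mm, medium 6-9 mm, large >=10 mm).  The base case uses the
CISNET-convention values 75% / 85% / 95% identically for screening and for
follow-up/surveillance colonoscopies.  The scenario grid splits each base
sensitivity symmetrically on the log-odds scale: for a size class with
log odds ratio ``lnOR`` between the follow-up and screening arms,

    screening  = expit(logit(base) - lnOR / 2)
    follow-up  = expit(logit(base) + lnOR / 2)

so the two arms keep the base value as their logit midpoint while their
log-odds difference equals ``lnOR``.  Scenarios are generated from an
anchor ``lnOR`` for large adenomas (0, 1 or 2 — "no/small", "medium",
"large" impact) and a constant slope (0.15, 0.30 or 0.60) added per size
step down from large to medium to small.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping, Sequence

from scipy.special import expit, logit


class SizeClass(enum.Enum):
    """Adenoma diameter class: small 1-5 mm, medium 6-9 mm, large >=10 mm."""

    SMALL = "small"
    MEDIUM = "medium"
    LARGE = "large"

    @staticmethod
    def of_diameter(mm: float) -> "SizeClass":
        if mm >= 10.0:
            return SizeClass.LARGE
        if mm >= 6.0:
            return SizeClass.MEDIUM
        return SizeClass.SMALL


#: base-case per-lesion colonoscopy sensitivity by size class
BASE_SENSITIVITY: Mapping[SizeClass, float] = {
    SizeClass.SMALL: 0.75,
    SizeClass.MEDIUM: 0.85,
    SizeClass.LARGE: 0.95,
}

GRID_ANCHORS: Sequence[float] = (0.0, 1.0, 2.0)
GRID_SLOPES: Sequence[float] = (0.15, 0.30, 0.60)

_GROUP_BY_ANCHOR = {0.0: "small", 1.0: "medium", 2.0: "large"}


@dataclass(frozen=True)
class ScenarioDefinition:
    """One cell of the scenario grid: anchor/slope and derived per-size lnOR."""

    id: int
    group: str                              # no | small | medium | large impact
    anchor_lnOR: float
    slope: float
    lnOR_by_size: Mapping[SizeClass, float]


@dataclass(frozen=True)
class SensitivityArms:
    """Arm-specific per-lesion colonoscopy sensitivity by size class."""

    base: Mapping[SizeClass, float]
    screening: Mapping[SizeClass, float]
    followup: Mapping[SizeClass, float]


def adjusted_pair(base: float, lnOR: float) -> tuple[float, float]:
    """Split ``base`` sensitivity into (screening, follow-up) arms.

    The pair is the symmetric logit split: its log-odds difference equals
    ``lnOR`` and its logit midpoint equals ``logit(base)``.

    Raises
    ------
    ValueError
        If ``base`` is not strictly inside (0, 1).
    """
    if not 0.0 < base < 1.0:
        raise ValueError(f"base sensitivity must be in (0,1), got {base}")
    lb = logit(base)
    return float(expit(lb - lnOR / 2.0)), float(expit(lb + lnOR / 2.0))


def build_scenarios(
    base: Mapping[SizeClass, float] = BASE_SENSITIVITY,
    anchors: Sequence[float] = GRID_ANCHORS,
    slopes: Sequence[float] = GRID_SLOPES,
) -> list[tuple[ScenarioDefinition, SensitivityArms]]:
    """Build the scenario grid: a no-impact base case plus anchors x slopes.

    Scenario 1 has lnOR = 0 for every size class (both arms equal the base
    case); scenarios 2..1+len(anchors)*len(slopes) sweep the anchor
    (large-adenoma lnOR) and the per-size-step slope.  With the default
    grid this yields the canonical 10 scenarios.
    """
    out: list[tuple[ScenarioDefinition, SensitivityArms]] = []

    def arms_for(lnor: Mapping[SizeClass, float]) -> SensitivityArms:
        pairs = {sc: adjusted_pair(base[sc], lnor[sc]) for sc in SizeClass}
        return SensitivityArms(
            base=dict(base),
            screening={sc: p[0] for sc, p in pairs.items()},
            followup={sc: p[1] for sc, p in pairs.items()},
        )

    zero = {sc: 0.0 for sc in SizeClass}
    out.append(
        (ScenarioDefinition(1, "no", 0.0, 0.0, zero), arms_for(zero))
    )
    sid = 2
    for anchor in anchors:
        for slope in slopes:
            lnor = {
                SizeClass.LARGE: anchor,
                SizeClass.MEDIUM: anchor + slope,
                SizeClass.SMALL: anchor + 2.0 * slope,
            }
            out.append(
                (
                    ScenarioDefinition(
                        sid, _GROUP_BY_ANCHOR.get(anchor, "custom"),
                        anchor, slope, lnor,
                    ),
                    arms_for(lnor),
                )
            )
            sid += 1
    return out


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round with ties away from zero (the convention of printed tables)."""
    import decimal

    q = decimal.Decimal(10) ** -decimals
    return float(
        decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP)
    )


def scenario_table(
    scenarios: Sequence[tuple[ScenarioDefinition, SensitivityArms]] | None = None,
):
    """Scenario grid as a tidy DataFrame (percent values, one decimal)."""
    import pandas as pd

    if scenarios is None:
        scenarios = build_scenarios()
    rows = []
    for sdef, arms in scenarios:
        for sc in (SizeClass.SMALL, SizeClass.MEDIUM, SizeClass.LARGE):
            rows.append(
                {
                    "scenario": sdef.id,
                    "group": sdef.group,
                    "size_class": sc.value,
                    "lnOR": sdef.lnOR_by_size[sc],
                    "slope": sdef.slope,
                    "screening_pct": round_half_up(100 * arms.screening[sc]),
                    "followup_pct": round_half_up(100 * arms.followup[sc]),
                }
            )
    return pd.DataFrame(rows)


def write_scenario_csv(path, scenarios=None) -> None:
    scenario_table(scenarios).to_csv(path, index=False)
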