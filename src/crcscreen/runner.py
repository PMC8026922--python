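"""Experiment orchestration: the scenario x strategy grid and both
sensitivity analyses, with reproducibility metadata.

A grid run simulates one cohort once (demographics + latent disease
histories + the no-screening counterfactual), then replays every
(scenario, strategy) cell against those shared histories.  All randomness
is counter-based per individual, so two runs with the same config are
byte-identical and every cell is paired with every other (common random
numbers).

Analyses:

* ``primary``   — follow-up/surveillance colonoscopies after a positive
  stool test use the follow-up arm for both FIT and mt-sDNA.
* ``sa1``       — FIT-triggered colonoscopies use the screening arm
  instead (mt-sDNA and colonoscopy cells are unaffected).
* ``sa2``       — alternate test-performance inputs (schema hook), with
  the large-adenoma (>=10 mm) sensitivities forced identical between arms
  in every scenario.
"""

from __future__ import annotations

import hashlib
import json
import math
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import natural_history as nh
from .outcomes import OutcomeTable, aggregate, pct_lyg_vs_colonoscopy, unscreened_rates
from .population import LifeTable, default_life_table, sample_cohort
from .scenarios import SensitivityArms, SizeClass, build_scenarios
from .screening import (
    COLONOSCOPY,
    DEFAULT_COLONOSCOPY,
    DEFAULT_POLICY,
    FIT,
    FIT_PROFILE,
    MTSDNA,
    MTSDNA_PROFILE,
    STRATEGY_COLONOSCOPY,
    STRATEGY_FIT,
    STRATEGY_MTSDNA,
    Strategy,
    TestProfile,
    run_strategy,
)

STRATEGIES = {
    COLONOSCOPY: STRATEGY_COLONOSCOPY,
    FIT: STRATEGY_FIT,
    MTSDNA: STRATEGY_MTSDNA,
}


@dataclass
class ExperimentConfig:
    """One grid run.  ``population`` defaults to a desk-scale cohort; the
    published-scale 4e6 is reachable by setting it explicitly."""

    population: int = 200_000
    seed: int = 7
    scenario_ids: Sequence[int] = tuple(range(1, 11))
    strategies: Sequence[str] = (COLONOSCOPY, MTSDNA, FIT)
    analysis: str = "primary"            # primary | sa1 | sa2
    stool_profiles: dict = field(
        default_factory=lambda: {FIT: FIT_PROFILE, MTSDNA: MTSDNA_PROFILE}
    )
    nh_params: Optional[nh.NaturalHistoryParams] = None
    life_table: Optional[LifeTable] = None
    out_dir: Optional[str] = None

    def __post_init__(self):
        if self.population < 1:
            raise ValueError("population must be >= 1")
        if self.analysis not in ("primary", "sa1", "sa2"):
            raise ValueError(f"unknown analysis: {self.analysis}")

    def config_hash(self) -> str:
        payload = {
            "population": self.population,
            "seed": self.seed,
            "scenario_ids": list(self.scenario_ids),
            "strategies": list(self.strategies),
            "analysis": self.analysis,
            "stool_profiles": {
                k: [v.sens_crc, v.sens_advanced_adenoma,
                    v.sens_nonadvanced_adenoma, v.specificity, v.interval_years]
                for k, v in sorted(self.stool_profiles.items())
            },
            "nh": (self.nh_params or nh.NaturalHistoryParams.default()).to_dict(),
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def equalize_large(arms: SensitivityArms) -> SensitivityArms:
    """Force identical large-adenoma sensitivity in both arms (the
    updated-inputs analysis constraint): both revert to the base value."""
    scr = dict(arms.screening)
    fup = dict(arms.followup)
    scr[SizeClass.LARGE] = arms.base[SizeClass.LARGE]
    fup[SizeClass.LARGE] = arms.base[SizeClass.LARGE]
    return SensitivityArms(base=dict(arms.base), screening=scr, followup=fup)


def simulate_cohort(cfg: ExperimentConfig):
    """Cohort + latent histories + the no-screening counterfactual."""
    params = cfg.nh_params or nh.NaturalHistoryParams.default()
    lt = cfg.life_table or default_life_table()
    cohort = sample_cohort(cfg.population, life_table=lt, seed=cfg.seed)
    unscreened = [nh.natural_course(ind, params) for ind in cohort]
    return cohort, unscreened, params


def run_cell(
    cohort,
    unscreened,
    params,
    strategy_name: str,
    scenario_id: int,
    arms: SensitivityArms,
    cfg: ExperimentConfig,
) -> OutcomeTable:
    """One (scenario, strategy) cell against shared histories."""
    strategy = STRATEGIES[strategy_name]
    stool = cfg.stool_profiles.get(strategy_name)
    fit_flag = cfg.analysis == "sa1" and strategy_name == FIT
    if cfg.analysis == "sa2":
        arms = equalize_large(arms)
    screened = [
        run_strategy(
            ind,
            hist,
            strategy,
            arms,
            params,
            policy=DEFAULT_POLICY,
            stool_profile=stool,
            colo_profile=DEFAULT_COLONOSCOPY,
            fit_screening_arm=fit_flag,
            record_events=False,
        )
        for ind, hist in zip(cohort, unscreened)
    ]
    return aggregate(strategy_name, scenario_id, screened, unscreened)


def run_grid(cfg: ExperimentConfig, progress: bool = False) -> dict:
    """Run every (scenario, strategy) cell; returns
    ``{(scenario_id, strategy): OutcomeTable}`` plus writes CSVs if
    ``cfg.out_dir`` is set.  Existing per-cell caches in the output
    directory are reused (partial-run resume) when their manifest matches.
    """
    out_dir = Path(cfg.out_dir) if cfg.out_dir else None
    cells_dir = None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
        cells_dir = out_dir / "cells"
        cells_dir.mkdir(exist_ok=True)
        _check_manifest(out_dir, cfg)

    scen_by_id = {sdef.id: (sdef, arms) for sdef, arms in build_scenarios()}
    cohort, unscreened, params = simulate_cohort(cfg)

    results: dict[tuple[int, str], OutcomeTable] = {}
    for sid in cfg.scenario_ids:
        _, arms = scen_by_id[sid]
        for strat in cfg.strategies:
            cache = cells_dir / f"s{sid}_{strat}.json" if cells_dir else None
            if cache is not None and cache.exists():
                results[(sid, strat)] = OutcomeTable(**json.loads(cache.read_text()))
                continue
            t0 = time.time()
            tab = run_cell(cohort, unscreened, params, strat, sid, arms, cfg)
            results[(sid, strat)] = tab
            if cache is not None:
                cache.write_text(json.dumps(tab.to_dict()))
            if progress:
                import sys

                print(
                    f"scenario {sid} {strat}: LYG={tab.lyg:.1f} "
                    f"({time.time() - t0:.1f}s)",
                    file=sys.stderr,
                )

    # percent of colonoscopy LYG, within scenario
    for sid in cfg.scenario_ids:
        col = results.get((sid, COLONOSCOPY))
        if col is None:
            continue
        for strat in cfg.strategies:
            if strat == COLONOSCOPY:
                continue
            tab = results[(sid, strat)]
            tab.pct_lyg_vs_colonoscopy = pct_lyg_vs_colonoscopy(tab.lyg, col.lyg)

    if out_dir:
        write_outputs(out_dir, cfg, results, unscreened)
    return results


def _check_manifest(out_dir: Path, cfg: ExperimentConfig):
    mf = out_dir / "manifest.json"
    payload = {
        "seed": cfg.seed,
        "population": cfg.population,
        "analysis": cfg.analysis,
        "config_hash": cfg.config_hash(),
    }
    if mf.exists():
        try:
            old = json.loads(mf.read_text())
        except json.JSONDecodeError as e:
            raise RuntimeError(f"corrupted manifest at {mf}: {e}") from e
        if old.get("config_hash") != payload["config_hash"]:
            raise RuntimeError(
                "output directory holds results from a different config; "
                "refusing to mix (delete it or change out_dir)"
            )
    mf.write_text(json.dumps(payload, indent=1, sort_keys=True))


def results_frame(results: dict) -> pd.DataFrame:
    rows = [tab.to_dict() for tab in results.values()]
    return (
        pd.DataFrame(rows)
        .sort_values(["scenario", "strategy"])
        .reset_index(drop=True)
    )


def write_outputs(out_dir: Path, cfg: ExperimentConfig, results: dict,
                  unscreened) -> None:
    """One CSV per figure/table plus the full outcome table."""
    df = results_frame(results)
    df.to_csv(out_dir / "outcomes.csv", index=False)

    def slim(value_col, name, extra_cols=()):
        cols = ["scenario", "strategy", value_col, "n_eligible", *extra_cols]
        out = df[cols].rename(columns={value_col: "value"})
        out["seed"] = cfg.seed
        out.to_csv(out_dir / name, index=False)

    slim("lyg", "fig1_lyg.csv")
    slim("incidence_reduction_pct", "fig1_incidence.csv")
    slim("mortality_reduction_pct", "fig1_mortality.csv")
    slim("weighted_amr_pct", "fig3_amr.csv")
    pct = df[df["strategy"] != COLONOSCOPY]
    pct = pct[["scenario", "strategy", "pct_lyg_vs_colonoscopy", "n_eligible"]]
    pct = pct.rename(columns={"pct_lyg_vs_colonoscopy": "value"})
    pct["seed"] = cfg.seed
    pct.to_csv(out_dir / "fig2_pct_lyg.csv", index=False)
    adr = df[df["strategy"] != COLONOSCOPY]
    adr = adr[["scenario", "strategy", "adr_first_followup_pct",
               "mean_age_first_followup", "n_eligible"]]
    adr = adr.rename(columns={"adr_first_followup_pct": "value"})
    adr["seed"] = cfg.seed
    adr.to_csv(out_dir / "adr.csv", index=False)
    res = df[["scenario", "strategy", "stool_tests", "colonoscopies",
              "complications", "life_years_with_crc", "n_eligible"]].copy()
    res["seed"] = cfg.seed
    res.to_csv(out_dir / "resource_use.csv", index=False)

    cases_u, deaths_u = unscreened_rates(unscreened)
    (out_dir / "unscreened.json").write_text(
        json.dumps(
            {"crc_cases_per_1000": cases_u, "crc_deaths_per_1000": deaths_u,
             "seed": cfg.seed, "population": cfg.population},
            indent=1,
        )
    )


def run_sensitivity_1(cfg: ExperimentConfig, progress: bool = False) -> dict:
    """The primary grid with FIT follow-up colonoscopies reassigned to the
    screening arm."""
    from dataclasses import replace

    out = None
    if cfg.out_dir:
        out = str(Path(cfg.out_dir) / "sa1")
    return run_grid(replace(cfg, analysis="sa1", out_dir=out), progress)


def run_sensitivity_2(cfg: ExperimentConfig,
                      alternate_profiles: Optional[dict] = None,
                      progress: bool = False) -> dict:
    """The grid with alternate test-performance inputs and the
    large-adenoma arms forced identical."""
    from dataclasses import replace

    out = None
    if cfg.out_dir:
        out = str(Path(cfg.out_dir) / "sa2")
    profiles = alternate_profiles or cfg.stool_profiles
    for p in profiles.values():
        if not isinstance(p, TestProfile):
            raise ValueError("alternate profiles must be TestProfile instances")
    return run_grid(
        replace(cfg, analysis="sa2", stool_profiles=profiles, out_dir=out),
        progress,
    )
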