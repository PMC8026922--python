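"""Calibration hook: recover onset-rate scale from simulated output.

The expected lifetime adenoma count of a person with frailty ``f`` who
dies at age ``d`` is ``scale * f * Lambda(d)``, where ``Lambda`` is the
cumulative baseline onset intensity.  Summing over a cohort gives a
moment estimator for the scale that is exactly linear in it:

    scale_hat = (total adenomas observed) / (sum of f_i * Lambda(d_i))

This is the documented slot for fitting a shipped or external
natural-history configuration to an incidence target: simulate (or load)
a cohort, count lesions, divide by exposure.
"""

from __future__ import annotations

from typing import Sequence

from .natural_history import (
    DiseaseHistory,
    NaturalHistoryParams,
    cumulative_onset_intensity,
)
from .population import Individual


def fit_onset_scale(
    cohort: Sequence[Individual],
    histories: Sequence[DiseaseHistory],
    params: NaturalHistoryParams,
) -> float:
    """Estimate the onset-rate scale that generated ``histories``.

    ``params`` must describe the baseline intensity *without* the scale
    being estimated (i.e. its ``onset.scale`` is treated as 1 for the
    exposure computation); frailties are taken from the cohort.
    """
    base_scale = params.onset.get("scale", 1.0)
    total = 0
    exposure = 0.0
    for ind, hist in zip(cohort, histories):
        total += len(hist.adenomas)
        lam = cumulative_onset_intensity(params, ind.other_cause_death_age)
        frailty = ind.frailty if params.onset.get("use_frailty", True) else 1.0
        exposure += frailty * lam / base_scale
    if exposure <= 0:
        raise ValueError("zero exposure: cannot identify the onset scale")
    return total / exposure
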