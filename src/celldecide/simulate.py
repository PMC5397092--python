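"""Synthetic single-cell response datasets with known statistical structure.

Real single-cell dose-response experiments yield, for each stimulus dose
and measurement time, an approximately Gaussian distribution of response
levels across cells, with the early and late readouts of the same cell
correlated.  This module generates long-format tables with exactly that
structure from fully specified parameters, so the whole analysis pipeline
can be exercised and validated against closed forms without any external
data.

The packaged :func:`tnf_nfkb_scenario` fixture mimics the qualitative
shape of TNF -> NF-kB dose-response data: well-separated low/high response
distributions at 30 minutes, heavily overlapping ones at 4 hours (negative
feedback attenuates the high-dose response), and a feedback-deficient
"A20KO" variant whose low-dose response is shifted upward and broadened.
All fixture means and variances are synthetic choices made for these
qualitative properties; they are not measurements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .models import CellDecideError

__all__ = [
    "ConditionParams",
    "ScenarioSpec",
    "generate_dataset",
    "tnf_nfkb_scenario",
    "tnf_nfkb_dataset",
    "TNF_DOSES_NG_ML",
    "EARLY_TIME_MIN",
    "LATE_TIME_MIN",
]

#: Measurement times of the packaged fixture, in minutes.
EARLY_TIME_MIN = 30.0
LATE_TIME_MIN = 240.0

#: Stimulus doses (ng/mL) of the packaged fixture, lowest first.
TNF_DOSES_NG_ML = (0.0021, 0.1, 0.2, 0.51, 3.0, 8.0)


@dataclass(frozen=True)
class ConditionParams:
    """Gaussian parameters of one (dose, time) condition."""

    mean: float
    variance: float

    def __post_init__(self) -> None:
        if self.variance <= 0:
            raise CellDecideError("condition variance must be > 0")


@dataclass(frozen=True)
class ScenarioSpec:
    """Full specification of a synthetic single-cell experiment.

    ``conditions`` maps (dose_ng_ml, time_min) to the Gaussian parameters
    of the response distribution for that condition; ``correlations`` maps
    each dose to the inter-time-point correlation of the per-cell (early,
    late) pair.  Every dose must appear at one or two time points; doses
    measured at two time points need a correlation entry.
    """

    conditions: Mapping[tuple[float, float], ConditionParams]
    correlations: Mapping[float, float] = field(default_factory=dict)
    cells_per_condition: int = 500
    seed: int = 0
    genotype: str = "WT"

    def __post_init__(self) -> None:
        if self.cells_per_condition < 10:
            raise CellDecideError("cells_per_condition must be >= 10")
        if not self.conditions:
            raise CellDecideError("scenario has no conditions")
        for dose in self.doses():
            times = self.times_for(dose)
            if len(times) > 2:
                raise CellDecideError(
                    f"dose {dose}: at most two time points are supported"
                )
            if len(times) == 2:
                rho = self.correlations.get(dose)
                if rho is None:
                    raise CellDecideError(
                        f"dose {dose}: two time points but no correlation given"
                    )
                if not -1.0 < rho < 1.0:
                    raise CellDecideError(
                        f"dose {dose}: correlation must lie in (-1, 1)"
                    )

    def doses(self) -> list[float]:
        return sorted({d for d, _ in self.conditions})

    def times_for(self, dose: float) -> list[float]:
        return sorted(t for d, t in self.conditions if d == dose)


def generate_dataset(spec: ScenarioSpec) -> pd.DataFrame:
    """Draw a long-format single-cell measurement table from a scenario.

    One row per (cell, time point).  Cells measured at two time points get
    correlated draws from the bivariate Gaussian implied by the spec, with
    the same ``cell_id`` on both rows so pairing survives the round trip.
    Deterministic under a fixed ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    frames = []
    n = spec.cells_per_condition
    for k, dose in enumerate(spec.doses()):
        times = spec.times_for(dose)
        cell_ids = [f"{spec.genotype}_d{k}_c{i:05d}" for i in range(n)]
        if len(times) == 1:
            p = spec.conditions[(dose, times[0])]
            draws = rng.normal(p.mean, math.sqrt(p.variance), size=n)
            frames.append(pd.DataFrame({
                "cell_id": cell_ids,
                "genotype": spec.genotype,
                "dose_ng_ml": dose,
                "time_min": times[0],
                "response": draws,
            }))
        else:
            pe = spec.conditions[(dose, times[0])]
            pl = spec.conditions[(dose, times[1])]
            rho = spec.correlations[dose]
            se, sl = math.sqrt(pe.variance), math.sqrt(pl.variance)
            cov = [[pe.variance, rho * se * sl], [rho * se * sl, pl.variance]]
            draws = rng.multivariate_normal([pe.mean, pl.mean], cov, size=n)
            for j, t in enumerate(times):
                frames.append(pd.DataFrame({
                    "cell_id": cell_ids,
                    "genotype": spec.genotype,
                    "dose_ng_ml": dose,
                    "time_min": t,
                    "response": draws[:, j],
                }))
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(
        ["dose_ng_ml", "time_min", "cell_id"], ignore_index=True
    )


# Fixture parameters (synthetic, chosen for qualitative realism only):
# early responses separate cleanly with dose; late responses overlap because
# negative feedback has pulled the high-dose mean back down; the deficient
# variant has an elevated, broadened low-dose response and uniformly higher
# late means.  Response units are arbitrary (nuclear-localization score).
_WT_EARLY = {0.0021: (0.25, 0.12), 0.1: (0.45, 0.15), 0.2: (0.55, 0.16),
             0.51: (0.65, 0.17), 3.0: (0.73, 0.18), 8.0: (0.75, 0.18)}
_WT_LATE = {0.0021: (0.30, 0.15), 0.1: (0.36, 0.17), 0.2: (0.40, 0.18),
            0.51: (0.45, 0.19), 3.0: (0.52, 0.20), 8.0: (0.55, 0.20)}
_KO_EARLY = {0.0021: (0.40, 0.20), 0.1: (0.52, 0.20), 0.2: (0.58, 0.20),
             0.51: (0.66, 0.20), 3.0: (0.76, 0.20), 8.0: (0.80, 0.20)}
_KO_LATE = {0.0021: (0.60, 0.20), 0.1: (0.63, 0.20), 0.2: (0.65, 0.20),
            0.51: (0.67, 0.20), 3.0: (0.70, 0.20), 8.0: (0.72, 0.20)}
_CORR = {0.0021: 0.30, 0.1: 0.35, 0.2: 0.40, 0.51: 0.45, 3.0: 0.50, 8.0: 0.50}


def tnf_nfkb_scenario(
    genotype: str = "WT",
    cells_per_condition: int = 500,
    seed: int = 2021,
) -> ScenarioSpec:
    """Packaged synthetic fixture for a two-genotype dose-response study.

    Six doses (0.0021 to 8 ng/mL) at two time points (30 min, 4 h), with
    per-cell early/late correlation.  By construction, analyzing the
    lowest-vs-highest dose pair gives a smaller overall error at 30 min
    than at 4 h, and the "A20KO" variant errs more than "WT" at both
    times.  All parameter values are synthetic stand-ins, not measured
    ones.
    """
    if genotype == "WT":
        early, late = _WT_EARLY, _WT_LATE
    elif genotype == "A20KO":
        early, late = _KO_EARLY, _KO_LATE
    else:
        raise CellDecideError(f"unknown fixture genotype {genotype!r}")
    conditions = {}
    for dose in TNF_DOSES_NG_ML:
        m, s = early[dose]
        conditions[(dose, EARLY_TIME_MIN)] = ConditionParams(m, s * s)
        m, s = late[dose]
        conditions[(dose, LATE_TIME_MIN)] = ConditionParams(m, s * s)
    return ScenarioSpec(
        conditions=conditions,
        correlations=dict(_CORR),
        cells_per_condition=cells_per_condition,
        seed=seed,
        genotype=genotype,
    )


def tnf_nfkb_dataset(
    cells_per_condition: int = 500, seed: int = 2021
) -> pd.DataFrame:
    """Generate the combined WT + A20KO fixture table in one call.

    The two genotypes use decorrelated substreams derived from ``seed``.
    """
    ss = np.random.SeedSequence(seed)
    seeds = [int(s) for s in ss.generate_state(2) >> 1]  # keep below 2^31
    wt = generate_dataset(tnf_nfkb_scenario(
        "WT", cells_per_condition=cells_per_condition, seed=seeds[0]))
    ko = generate_dataset(tnf_nfkb_scenario(
        "A20KO", cells_per_condition=cells_per_condition, seed=seeds[1]))
    return pd.concat([wt, ko], ignore_index=True)
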