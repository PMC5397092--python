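"""Closed-form radar reference model: constant signal in Gaussian noise.

The classic detection problem that motivates the cell-decision analysis:
from N noisy samples x[n], decide between

    H0: x[n] = w[n]          (noise only, no object)
    H1: x[n] = A + w[n]      (constant-amplitude signal plus noise)

with w[n] i.i.d. N(0, sigma^2).  The likelihood-ratio test reduces to
comparing the sample mean with a threshold, optimally A/2 for equal
priors, and the error probabilities have exact Q-function expressions:

    P_FA = Q(sqrt(N) * th / sigma)
    P_M  = Q(sqrt(N) * (A - th) / sigma)
    P_e  = (P_FA + P_M) / 2,   minimized at th = A/2 where P_e = Q(sqrt(N) A / (2 sigma)).

These closed forms make the scenario a handy analytic oracle for the rest
of the decision machinery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .models import CellDecideError, DecisionResult
from .gaussian import q_function

__all__ = [
    "RadarScenario",
    "radar_decide",
    "radar_error_probabilities",
    "radar_monte_carlo",
]


@dataclass(frozen=True)
class RadarScenario:
    """Constant-signal-in-noise detection scenario.

    ``threshold`` is the sample-mean decision threshold; ``None`` means the
    optimal A/2.
    """

    amplitude: float
    noise_sd: float
    n_samples: int
    threshold: Optional[float] = None

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise CellDecideError("noise_sd must be > 0")
        if self.n_samples < 1:
            raise CellDecideError("n_samples must be >= 1")
        if not math.isfinite(self.amplitude):
            raise CellDecideError("amplitude must be finite")

    @property
    def effective_threshold(self) -> float:
        return self.amplitude / 2.0 if self.threshold is None else self.threshold


def radar_decide(observations, scenario: RadarScenario) -> str:
    """Decide "H1" iff the sample mean strictly exceeds the threshold.

    An exact tie decides "H0" (measure-zero event; convention fixed to
    match the strict inequality of the likelihood-ratio rule).
    """
    obs = np.asarray(observations, dtype=float).ravel()
    if obs.size != scenario.n_samples:
        raise CellDecideError(
            f"expected {scenario.n_samples} observations, got {obs.size}"
        )
    return "H1" if float(np.mean(obs)) > scenario.effective_threshold else "H0"


def radar_error_probabilities(scenario: RadarScenario) -> DecisionResult:
    """Exact P_FA, P_M, P_e for the sample-mean detector (equal priors)."""
    a, s, n = scenario.amplitude, scenario.noise_sd, scenario.n_samples
    th = scenario.effective_threshold
    root_n = math.sqrt(n)
    p_fa = q_function(root_n * th / s)
    p_m = q_function(root_n * (a - th) / s)
    return DecisionResult(
        p_fa=p_fa,
        p_m=p_m,
        p_e=0.5 * (p_fa + p_m),
        method="closed_form",
        threshold=float(th),
        provenance={"amplitude": a, "noise_sd": s, "n_samples": n},
    )


def radar_monte_carlo(
    scenario: RadarScenario, n_trials: int, seed: int
) -> tuple[float, float]:
    """Simulated (P_FA, P_M): error rates over ``n_trials`` per hypothesis."""
    if n_trials < 10_000:
        raise CellDecideError("n_trials must be >= 10^4")
    rng = np.random.default_rng(seed)
    s = scenario.noise_sd / math.sqrt(scenario.n_samples)
    th = scenario.effective_threshold
    # Sample means under each hypothesis are Gaussian with sd sigma/sqrt(N).
    means_h0 = rng.normal(0.0, s, size=n_trials)
    means_h1 = rng.normal(scenario.amplitude, s, size=n_trials)
    p_fa = float(np.mean(means_h0 > th))
    p_m = float(np.mean(means_h1 <= th))
    return p_fa, p_m
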