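"""Core domain types shared across the package.

The binary-hypothesis vocabulary used throughout: H0 is the "stimulus low"
hypothesis, H1 the "stimulus high" hypothesis.  A *false alarm* is deciding
H1 when H0 holds; a *miss* is deciding H0 when H1 holds.  The overall error
probability is the prior-weighted mixture

    P_e = P(H0) * P_FA + P(H1) * P_M.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Optional

import numpy as np
from scipy import stats


class CellDecideError(ValueError):
    """Base class for all domain errors raised by this package."""


class DegenerateDataError(CellDecideError):
    """Raised when samples are too few or have no spread to fit a model."""


class OrientationError(CellDecideError):
    """Raised when hypothesis labels violate the mu1 >= mu0 convention."""


class NoThresholdError(CellDecideError):
    """Raised when no single decision threshold exists between the means."""


@dataclass(frozen=True)
class GaussianResponseModel:
    """Gaussian model of a response distribution under one hypothesis.

    Parameters
    ----------
    mean
        Mean response level (e.g. nuclear NF-kB, arbitrary units).
    variance
        Response variance (units squared); must be strictly positive.
    """

    mean: float
    variance: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.mean) and math.isfinite(self.variance)):
            raise CellDecideError("mean and variance must be finite")
        if self.variance <= 0:
            raise CellDecideError(f"variance must be > 0, got {self.variance}")

    @property
    def sd(self) -> float:
        return math.sqrt(self.variance)

    def pdf(self, x):
        return stats.norm.pdf(x, loc=self.mean, scale=self.sd)

    def cdf(self, x):
        return stats.norm.cdf(x, loc=self.mean, scale=self.sd)

    def sf(self, x):
        """Upper-tail mass above ``x``."""
        return stats.norm.sf(x, loc=self.mean, scale=self.sd)


@dataclass(frozen=True)
class DecisionPriors:
    """Prior probabilities P(H0), P(H1) for the two stimulus hypotheses.

    The likelihood-ratio cutoff is ``gamma = P(H0) / P(H1)``: the optimal
    rule decides H1 when p(x|H1)/p(x|H0) > gamma.  Equal priors model the
    absence of prior knowledge and are the default everywhere.
    """

    p_h0: float = 0.5
    p_h1: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.p_h0 < 1.0 and 0.0 < self.p_h1 < 1.0):
            raise CellDecideError("priors must lie strictly in (0, 1)")
        if abs(self.p_h0 + self.p_h1 - 1.0) > 1e-9:
            raise CellDecideError("priors must sum to 1")

    @property
    def gamma(self) -> float:
        """Likelihood-ratio cutoff P(H0)/P(H1)."""
        return self.p_h0 / self.p_h1


#: Equal priors, the no-prior-knowledge default.
EQUAL_PRIORS = DecisionPriors(0.5, 0.5)


@dataclass(frozen=True)
class DecisionResult:
    """Outcome of one binary decision analysis.

    ``threshold`` is the scalar decision boundary for single-threshold
    analyses and ``None`` when the decision region is defined implicitly by
    a density comparison (bivariate Monte Carlo, exact-region mode).
    ``mc_standard_error`` carries the binomial standard errors
    (se_fa, se_m) for Monte-Carlo estimates.  ``provenance`` records the
    models, priors, policy, sample counts and seeds that produced the
    numbers, so every reported probability is traceable.
    """

    p_fa: float
    p_m: float
    p_e: float
    method: str  # {"closed_form", "monte_carlo", "empirical"}
    threshold: Optional[float] = None
    mc_standard_error: Optional[tuple[float, float]] = None
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, p in (("p_fa", self.p_fa), ("p_m", self.p_m), ("p_e", self.p_e)):
            if not (-1e-12 <= p <= 1.0 + 1e-12):
                raise CellDecideError(f"{name}={p} outside [0, 1]")
        if self.method not in ("closed_form", "monte_carlo", "empirical"):
            raise CellDecideError(f"unknown method {self.method!r}")


def as_sample_array(samples, minimum: int = 2, name: str = "samples") -> np.ndarray:
    """Validate and coerce a sample collection to a 1-D float array."""
    arr = np.asarray(list(samples) if not isinstance(samples, np.ndarray) else samples,
                     dtype=float).ravel()
    if arr.size < minimum:
        raise DegenerateDataError(f"{name}: need at least {minimum} values, got {arr.size}")
    if not np.all(np.isfinite(arr)):
        raise CellDecideError(f"{name}: non-finite values present")
    return arr
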