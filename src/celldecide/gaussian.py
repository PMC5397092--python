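"""Univariate Gaussian binary-hypothesis decision analysis.

Given Gaussian response models N(mu0, sigma0^2) under H0 (stimulus low) and
N(mu1, sigma1^2) under H1 (stimulus high), the minimum-error (maximum
likelihood for equal priors) rule decides H1 where
P(H1) p(x|H1) > P(H0) p(x|H0).  Equating the prior-weighted densities and
taking logs yields the quadratic

    (s0 - s1) x^2 + 2 (s1 mu0 - s0 mu1) x
        + s0 mu1^2 - s1 mu0^2 - 2 s0 s1 [ln(sigma0/sigma1) + ln(P1/P0)] = 0

with s_i = sigma_i^2.  The single-threshold treatment uses the root between
the two means; the resulting error probabilities are Gaussian tails
expressed through the Q function (upper-tail standard normal integral):

    P_FA = Q((th - mu0)/sigma0),    P_M = Q((mu1 - th)/sigma1).

When the variances differ, the exact Bayes decide-H1 region is an interval
or the complement of an interval rather than a half-line;
:func:`exact_region_error_probabilities` integrates that exact region.
"""

from __future__ import annotations

import logging
import math
from typing import Sequence

import numpy as np
from scipy import special

from .models import (
    EQUAL_PRIORS,
    CellDecideError,
    DecisionPriors,
    DecisionResult,
    DegenerateDataError,
    GaussianResponseModel,
    NoThresholdError,
    OrientationError,
    as_sample_array,
)

logger = logging.getLogger(__name__)

__all__ = [
    "q_function",
    "fit_gaussian",
    "ml_threshold",
    "error_probabilities",
    "exact_region_error_probabilities",
    "overall_error",
    "error_vs_threshold",
    "analyze_gaussian_pair",
    "decide_h1_region",
]


def q_function(eta):
    """Upper-tail probability of the standard normal, Q(eta).

    Q(eta) = (2*pi)^{-1/2} \\int_eta^inf exp(-u^2/2) du.  Strictly
    decreasing, with Q(eta) + Q(-eta) = 1.
    """
    arr = np.asarray(eta, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise CellDecideError("q_function: input must be finite")
    out = special.ndtr(-arr)
    return float(out) if np.isscalar(eta) or arr.ndim == 0 else out


def fit_gaussian(samples) -> GaussianResponseModel:
    """Fit a Gaussian response model by sample mean and unbiased variance.

    Uses the n-1 denominator; with hundreds of cells per condition the
    difference from the biased estimator is far below the precision of any
    reported probability, but the choice is fixed for reproducibility.
    """
    arr = as_sample_array(samples, minimum=2)
    var = float(np.var(arr, ddof=1))
    if var <= 0.0:
        raise DegenerateDataError("samples have zero spread; cannot fit a Gaussian")
    return GaussianResponseModel(mean=float(np.mean(arr)), variance=var)


def _log_ratio_coeffs(
    model0: GaussianResponseModel,
    model1: GaussianResponseModel,
    priors: DecisionPriors,
) -> tuple[float, float, float]:
    """Coefficients (a2, a1, a0) of log[P1 p1(x)] - log[P0 p0(x)]."""
    s0, s1 = model0.variance, model1.variance
    m0, m1 = model0.mean, model1.mean
    a2 = 0.5 / s0 - 0.5 / s1
    a1 = m1 / s1 - m0 / s0
    a0 = (
        m0 * m0 / (2.0 * s0)
        - m1 * m1 / (2.0 * s1)
        + math.log(model0.sd / model1.sd)
        + math.log(priors.p_h1 / priors.p_h0)
    )
    return a2, a1, a0


def ml_threshold(
    model0: GaussianResponseModel,
    model1: GaussianResponseModel,
    priors: DecisionPriors = EQUAL_PRIORS,
) -> float:
    """Decision threshold where the prior-weighted densities are equal.

    Solves P(H0) p(x|H0) = P(H1) p(x|H1).  With equal variances the
    quadratic degenerates and the linear equation is solved directly
    (midpoint shifted by the prior log-ratio).  With unequal variances the
    root strictly between the two means is returned, matching the
    single-threshold treatment in which H1 is decided above the threshold.

    Raises
    ------
    NoThresholdError
        If the models are identical, or no density crossing exists between
        the means (e.g. equal means with unequal variances, or a prior so
        skewed that one hypothesis dominates over the whole interval).
    """
    s0, s1 = model0.variance, model1.variance
    m0, m1 = model0.mean, model1.mean
    if m0 == m1 and s0 == s1 and priors.p_h0 == priors.p_h1:
        raise NoThresholdError("identical models: hypotheses are indistinguishable")

    if math.isclose(s0, s1, rel_tol=1e-12, abs_tol=0.0):
        # Equal-variance case: the quadratic term vanishes.
        if m0 == m1:
            raise NoThresholdError("equal means and variances: no crossing point")
        th = 0.5 * (m0 + m1) + s0 * math.log(priors.gamma) / (m1 - m0)
    else:
        # Quadratic in x from equating prior-weighted log-densities.
        a = s0 - s1
        b = 2.0 * (s1 * m0 - s0 * m1)
        c = (
            s0 * m1 * m1
            - s1 * m0 * m0
            - 2.0 * s0 * s1 * (math.log(model0.sd / model1.sd)
                               + math.log(priors.p_h1 / priors.p_h0))
        )
        disc = b * b - 4.0 * a * c
        if disc < 0.0:
            raise NoThresholdError(
                "no real density-crossing point: the prior-weighted densities "
                "never intersect (negative discriminant)"
            )
        sq = math.sqrt(disc)
        roots = sorted(((-b - sq) / (2.0 * a), (-b + sq) / (2.0 * a)))
        lo, hi = sorted((m0, m1))
        between = [r for r in roots if lo < r < hi]
        if not between:
            raise NoThresholdError(
                f"no density crossing strictly between the means {lo} and {hi}; "
                "the decide-H1 region is not a half-line here — use "
                "exact_region_error_probabilities for the exact Bayes analysis"
            )
        th = between[0]

    # Post-condition: prior-weighted densities agree at the threshold.
    d0 = priors.p_h0 * model0.pdf(th)
    d1 = priors.p_h1 * model1.pdf(th)
    if abs(d0 - d1) > 1e-9 * max(d0, d1):
        raise CellDecideError("threshold failed the density-equality check")
    return float(th)


def error_probabilities(
    model0: GaussianResponseModel,
    model1: GaussianResponseModel,
    threshold: float,
) -> tuple[float, float]:
    """Closed-form (P_FA, P_M) for a decide-H1-above-threshold rule.

    P_FA = Q((th - mu0)/sigma0) is the H0 mass above the threshold;
    P_M = Q((mu1 - th)/sigma1) is the H1 mass at/below it.  Requires the
    orientation convention mu1 >= mu0 (H1 is the higher-mean response).
    """
    if model1.mean < model0.mean:
        raise OrientationError(
            "model1 mean < model0 mean: relabel the hypotheses so that H1 "
            "has the higher mean response"
        )
    if math.isnan(threshold):
        raise CellDecideError("threshold must not be NaN")
    if math.isinf(threshold):
        return (0.0, 1.0) if threshold > 0 else (1.0, 0.0)
    p_fa = q_function((threshold - model0.mean) / model0.sd)
    p_m = q_function((model1.mean - threshold) / model1.sd)
    return float(p_fa), float(p_m)


def decide_h1_region(
    model0: GaussianResponseModel,
    model1: GaussianResponseModel,
    priors: DecisionPriors = EQUAL_PRIORS,
) -> list[tuple[float, float]]:
    """Exact decide-H1 region {x : P(H1)p(x|H1) > P(H0)p(x|H0)}.

    Returned as a list of disjoint open intervals (possibly unbounded).
    The log prior-weighted likelihood ratio is a quadratic in x, so the
    region is a half-line, an interval, or the complement of an interval.
    """
    a2, a1, a0 = _log_ratio_coeffs(model0, model1, priors)
    inf = math.inf
    if abs(a2) < 1e-300:  # equal variances: linear boundary
        if a1 == 0.0:
            return [(-inf, inf)] if a0 > 0 else []
        x = -a0 / a1
        return [(x, inf)] if a1 > 0 else [(-inf, x)]
    disc = a1 * a1 - 4.0 * a2 * a0
    if disc <= 0.0:
        # No sign change: region is everywhere or nowhere by leading term.
        return [(-inf, inf)] if a2 > 0 else []
    sq = math.sqrt(disc)
    r1, r2 = sorted(((-a1 - sq) / (2.0 * a2), (-a1 + sq) / (2.0 * a2)))
    if a2 > 0:  # positive outside the roots
        return [(-inf, r1), (r2, inf)]
    return [(r1, r2)]  # positive between the roots


def exact_region_error_probabilities(
    model0: GaussianResponseModel,
    model1: GaussianResponseModel,
    priors: DecisionPriors = EQUAL_PRIORS,
) -> tuple[float, float]:
    """(P_FA, P_M) integrating the exact Bayes decide-H1 region.

    P_FA is the H0 mass of the region, P_M the H1 mass of its complement;
    both reduce to the single-threshold formulas when the region is a
    half-line.
    """
    region = decide_h1_region(model0, model1, priors)
    mass0 = sum(float(model0.cdf(b) - model0.cdf(a)) for a, b in region)
    mass1 = sum(float(model1.cdf(b) - model1.cdf(a)) for a, b in region)
    return mass0, 1.0 - mass1


def overall_error(
    p_fa: float, p_m: float, priors: DecisionPriors = EQUAL_PRIORS
) -> float:
    """Prior-weighted overall error P_e = P(H0) P_FA + P(H1) P_M."""
    for name, p in (("p_fa", p_fa), ("p_m", p_m)):
        if not (0.0 <= p <= 1.0):
            raise CellDecideError(f"{name}={p} outside [0, 1]")
    return priors.p_h0 * p_fa + priors.p_h1 * p_m


def error_vs_threshold(
    model0: GaussianResponseModel,
    model1: GaussianResponseModel,
    priors: DecisionPriors,
    threshold_grid: Sequence[float],
) -> np.ndarray:
    """Overall error P_e evaluated at each threshold of a sorted grid.

    Returns an array of shape (n, 2) with columns (threshold, P_e).
    """
    grid = np.asarray(threshold_grid, dtype=float)
    if grid.size == 0:
        raise CellDecideError("threshold grid is empty")
    if not np.all(np.isfinite(grid)):
        raise CellDecideError("threshold grid must be finite")
    if np.any(np.diff(grid) < 0):
        raise CellDecideError("threshold grid must be sorted ascending")
    p_fa = q_function((grid - model0.mean) / model0.sd)
    p_m = q_function((model1.mean - grid) / model1.sd)
    p_e = priors.p_h0 * np.asarray(p_fa) + priors.p_h1 * np.asarray(p_m)
    return np.column_stack([grid, p_e])


def analyze_gaussian_pair(
    model0: GaussianResponseModel,
    model1: GaussianResponseModel,
    priors: DecisionPriors = EQUAL_PRIORS,
    threshold: float | None = None,
    mode: str = "single_threshold",
) -> DecisionResult:
    """Full closed-form analysis of one Gaussian model pair.

    ``threshold=None`` uses the optimal crossing point; a supplied value
    models a cell applying a previously learned (possibly wrong) threshold.
    ``mode="exact_region"`` additionally reports the exact Bayes-region
    probabilities in the provenance (only meaningful with the optimal
    rule).
    """
    if mode not in ("single_threshold", "exact_region"):
        raise CellDecideError(f"unknown mode {mode!r}")
    prov: dict = {
        "model0": model0,
        "model1": model1,
        "priors": (priors.p_h0, priors.p_h1),
        "mode": mode,
    }
    if threshold is None:
        threshold = ml_threshold(model0, model1, priors)
        prov["threshold_policy"] = "optimal"
    else:
        prov["threshold_policy"] = "fixed"
    p_fa, p_m = error_probabilities(model0, model1, threshold)
    if mode == "exact_region":
        pfa_x, pm_x = exact_region_error_probabilities(model0, model1, priors)
        prov["exact_region"] = {
            "p_fa": pfa_x,
            "p_m": pm_x,
            "p_e": overall_error(pfa_x, pm_x, priors),
        }
    return DecisionResult(
        p_fa=p_fa,
        p_m=p_m,
        p_e=overall_error(p_fa, p_m, priors),
        method="closed_form",
        threshold=float(threshold),
        provenance=prov,
    )
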