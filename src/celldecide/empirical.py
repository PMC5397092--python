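"""Distribution-free decision analysis from histograms or raw samples.

When the response distributions are not well described by a Gaussian, the
threshold and the false-alarm / miss probabilities can be estimated
directly from empirical histograms: the threshold is the cut minimizing
the prior-weighted empirical error, P_FA is the H0 histogram mass above
the cut and P_M the H1 mass at or below it.  Thresholds falling inside a
bin split the bin mass by linear interpolation (i.e. mass is treated as
uniform within a bin), which removes bin-width discontinuities from the
reported probabilities.

When raw samples are available the tail fractions are computed from the
samples directly, avoiding binning loss; histogram mode exists for
pre-binned input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .models import (
    EQUAL_PRIORS,
    CellDecideError,
    DecisionPriors,
    DecisionResult,
    DegenerateDataError,
    as_sample_array,
)
from .gaussian import overall_error

logger = logging.getLogger(__name__)

__all__ = [
    "EmpiricalResponseModel",
    "build_histogram",
    "empirical_threshold",
    "empirical_error",
    "empirical_error_from_samples",
    "empirical_threshold_from_samples",
]


@dataclass(frozen=True)
class EmpiricalResponseModel:
    """Normalized histogram of response levels under one hypothesis."""

    bin_edges: np.ndarray
    bin_masses: np.ndarray
    n_source_samples: int
    binning_policy: str = "fd"

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        masses = np.asarray(self.bin_masses, dtype=float)
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "bin_masses", masses)
        if edges.ndim != 1 or masses.ndim != 1 or edges.size != masses.size + 1:
            raise CellDecideError("need len(bin_edges) == len(bin_masses) + 1")
        if np.any(np.diff(edges) <= 0):
            raise CellDecideError("bin edges must be strictly increasing")
        if np.any(masses < -1e-15):
            raise CellDecideError("bin masses must be nonnegative")
        if abs(masses.sum() - 1.0) > 1e-12:
            raise CellDecideError("bin masses must sum to 1 (tol 1e-12)")

    def cdf(self, x: float) -> float:
        """Mass at or below ``x``, interpolated linearly within a bin."""
        cum = np.concatenate([[0.0], np.cumsum(self.bin_masses)])
        return float(np.interp(x, self.bin_edges, cum, left=0.0, right=1.0))

    def mass_above(self, x: float) -> float:
        return 1.0 - self.cdf(x)


def build_histogram(samples, binning_policy="fd") -> EmpiricalResponseModel:
    """Build a normalized histogram model from raw samples.

    ``binning_policy`` is anything :func:`numpy.histogram_bin_edges`
    accepts: a rule name (default Freedman-Diaconis, ``"fd"``), a bin
    count, or explicit edges.  The policy is recorded in the model for
    reproducibility.
    """
    arr = as_sample_array(samples, minimum=10)
    edges = np.histogram_bin_edges(arr, bins=binning_policy)
    counts, edges = np.histogram(arr, bins=edges)
    total = counts.sum()
    if total == 0:
        raise DegenerateDataError("all samples fell outside the provided bins")
    masses = counts / total
    # Remove the sub-1e-12 float drift so the sum-to-1 invariant holds exactly.
    masses = masses / masses.sum()
    return EmpiricalResponseModel(
        bin_edges=edges,
        bin_masses=masses,
        n_source_samples=int(arr.size),
        binning_policy=str(binning_policy),
    )


def _rebin(model: EmpiricalResponseModel, edges: np.ndarray) -> EmpiricalResponseModel:
    """Re-express a histogram on new edges via its interpolated CDF."""
    cdf_vals = np.array([model.cdf(e) for e in edges])
    masses = np.diff(cdf_vals)
    masses = np.clip(masses, 0.0, None)
    s = masses.sum()
    if s <= 0:
        raise CellDecideError("rebinning produced an empty histogram")
    return EmpiricalResponseModel(
        bin_edges=edges,
        bin_masses=masses / s,
        n_source_samples=model.n_source_samples,
        binning_policy=f"rebinned({model.binning_policy})",
    )


def _common_grid(
    model0: EmpiricalResponseModel, model1: EmpiricalResponseModel
) -> tuple[EmpiricalResponseModel, EmpiricalResponseModel, np.ndarray]:
    edges = np.union1d(model0.bin_edges, model1.bin_edges)
    return _rebin(model0, edges), _rebin(model1, edges), edges


def empirical_threshold(
    model0: EmpiricalResponseModel,
    model1: EmpiricalResponseModel,
    priors: DecisionPriors = EQUAL_PRIORS,
) -> float:
    """Bin edge minimizing the empirical prior-weighted error.

    The two histograms are rebinned onto the union of their edges; every
    edge is a candidate threshold and the lowest edge wins ties.  Disjoint
    supports yield a separating edge with zero error (logged, since any
    edge in the gap would do).
    """
    m0, m1, edges = _common_grid(model0, model1)
    cum0 = np.concatenate([[0.0], np.cumsum(m0.bin_masses)])
    cum1 = np.concatenate([[0.0], np.cumsum(m1.bin_masses)])
    p_fa = 1.0 - cum0  # H0 mass above each edge
    p_m = cum1         # H1 mass at/below each edge
    p_e = priors.p_h0 * p_fa + priors.p_h1 * p_m
    i = int(np.argmin(p_e))  # argmin takes the first (lowest) edge on ties
    if p_e[i] <= 0.0:
        logger.info(
            "disjoint empirical supports: threshold %g separates with zero "
            "error; any edge in the gap is equivalent", edges[i]
        )
    return float(edges[i])


def empirical_error(
    model0: EmpiricalResponseModel,
    model1: EmpiricalResponseModel,
    threshold: float,
    priors: DecisionPriors = EQUAL_PRIORS,
) -> DecisionResult:
    """(P_FA, P_M, P_e) from histogram masses at a given threshold."""
    if not np.isfinite(threshold):
        raise CellDecideError("threshold must be finite")
    p_fa = model0.mass_above(threshold)
    p_m = model1.cdf(threshold)
    return DecisionResult(
        p_fa=p_fa,
        p_m=p_m,
        p_e=overall_error(p_fa, p_m, priors),
        method="empirical",
        threshold=float(threshold),
        provenance={
            "n0": model0.n_source_samples,
            "n1": model1.n_source_samples,
            "binning": (model0.binning_policy, model1.binning_policy),
            "priors": (priors.p_h0, priors.p_h1),
        },
    )


def empirical_threshold_from_samples(
    samples0, samples1, priors: DecisionPriors = EQUAL_PRIORS
) -> float:
    """Threshold minimizing the empirical error computed from raw samples.

    Candidates are the pooled sample values; the empirical error at cut t
    is P(H0) * frac(s0 > t) + P(H1) * frac(s1 <= t).  The lowest optimal
    cut is returned.
    """
    s0 = as_sample_array(samples0, minimum=2, name="samples0")
    s1 = as_sample_array(samples1, minimum=2, name="samples1")
    cand = np.unique(np.concatenate([s0, s1]))
    p_fa = 1.0 - np.searchsorted(np.sort(s0), cand, side="right") / s0.size
    p_m = np.searchsorted(np.sort(s1), cand, side="right") / s1.size
    p_e = priors.p_h0 * p_fa + priors.p_h1 * p_m
    return float(cand[int(np.argmin(p_e))])


def empirical_error_from_samples(
    samples0,
    samples1,
    threshold: float,
    priors: DecisionPriors = EQUAL_PRIORS,
) -> DecisionResult:
    """(P_FA, P_M, P_e) as raw tail fractions, with no binning loss."""
    s0 = as_sample_array(samples0, minimum=2, name="samples0")
    s1 = as_sample_array(samples1, minimum=2, name="samples1")
    if not np.isfinite(threshold):
        raise CellDecideError("threshold must be finite")
    p_fa = float(np.mean(s0 > threshold))
    p_m = float(np.mean(s1 <= threshold))
    return DecisionResult(
        p_fa=p_fa,
        p_m=p_m,
        p_e=overall_error(p_fa, p_m, priors),
        method="empirical",
        threshold=float(threshold),
        provenance={
            "n0": int(s0.size),
            "n1": int(s1.size),
            "binning": "none (raw samples)",
            "priors": (priors.p_h0, priors.p_h1),
        },
    )
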