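"""Analysis pipelines over measurement tables.

These functions connect the long-format single-cell tables to the decision
machinery: fit per-condition response models, resolve the decision
threshold (optimal, or deliberately fixed — e.g. a mutant cell applying
the threshold learned before the mutation), and report false-alarm / miss
/ overall error probabilities with full provenance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from . import empirical
from .bivariate import (
    BivariateResponseModel,
    MCSettings,
    estimate_correlation,
    mc_error_probabilities,
)
from .gaussian import (
    analyze_gaussian_pair,
    exact_region_error_probabilities,
    fit_gaussian,
    ml_threshold,
    overall_error,
)
from .models import (
    EQUAL_PRIORS,
    CellDecideError,
    DecisionPriors,
    DecisionResult,
    GaussianResponseModel,
    NoThresholdError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ThresholdPolicy",
    "OPTIMAL_POLICY",
    "condition_samples",
    "analyze_condition_pair",
    "dose_sweep",
    "joint_analysis",
    "rho_sensitivity",
    "format_report",
]


@dataclass(frozen=True)
class ThresholdPolicy:
    """How the decision threshold is chosen.

    ``optimal`` solves for the prior-weighted density crossing of the
    analyzed pair.  ``fixed`` applies either a literal value
    (``fixed_value``) or the optimal threshold of another genotype's same
    condition pair (``source_condition``, e.g. ``"WT"`` to make deficient
    cells reuse the wild-type threshold).
    """

    mode: str = "optimal"
    fixed_value: Optional[float] = None
    source_condition: Optional[str] = None

    def __post_init__(self) -> None:
        if self.mode not in ("optimal", "fixed"):
            raise CellDecideError(f"unknown policy mode {self.mode!r}")
        if self.mode == "fixed" and self.fixed_value is None \
                and self.source_condition is None:
            raise CellDecideError(
                "fixed policy needs fixed_value or source_condition"
            )


OPTIMAL_POLICY = ThresholdPolicy("optimal")


def condition_samples(
    table: pd.DataFrame, dose: float, time: float, genotype: str = "WT"
) -> np.ndarray:
    """Response values of one (genotype, dose, time) condition."""
    mask = (
        (table["genotype"] == genotype)
        & np.isclose(table["dose_ng_ml"], dose)
        & np.isclose(table["time_min"], time)
    )
    vals = table.loc[mask, "response"].to_numpy(dtype=float)
    if vals.size == 0:
        raise CellDecideError(
            f"no cells for condition (genotype={genotype}, dose={dose} ng/mL, "
            f"time={time} min)"
        )
    return vals


def _oriented_fits(
    table: pd.DataFrame, dose_low: float, dose_high: float, time: float,
    genotype: str,
) -> tuple[GaussianResponseModel, GaussianResponseModel, np.ndarray, np.ndarray]:
    s0 = condition_samples(table, dose_low, time, genotype)
    s1 = condition_samples(table, dose_high, time, genotype)
    m0, m1 = fit_gaussian(s0), fit_gaussian(s1)
    if m1.mean < m0.mean:
        logger.warning(
            "condition pair (%g, %g ng/mL) at %g min violates the mu1 >= mu0 "
            "orientation; relabeling hypotheses", dose_low, dose_high, time,
        )
        m0, m1, s0, s1 = m1, m0, s1, s0
    return m0, m1, s0, s1


def _resolve_threshold(
    table: pd.DataFrame, dose_low: float, dose_high: float, time: float,
    priors: DecisionPriors, policy: ThresholdPolicy, genotype: str,
    model0: GaussianResponseModel, model1: GaussianResponseModel,
) -> tuple[float, str]:
    if policy.mode == "optimal":
        return ml_threshold(model0, model1, priors), "optimal"
    if policy.fixed_value is not None:
        return float(policy.fixed_value), "fixed(value)"
    src = policy.source_condition
    sm0, sm1, _, _ = _oriented_fits(table, dose_low, dose_high, time, src)
    return (
        ml_threshold(sm0, sm1, priors),
        f"fixed(optimal threshold of genotype {src!r})",
    )


def analyze_condition_pair(
    table: pd.DataFrame,
    dose_low: float,
    dose_high: float,
    time: float,
    priors: DecisionPriors = EQUAL_PRIORS,
    policy: ThresholdPolicy = OPTIMAL_POLICY,
    method: str = "gaussian",
    genotype: str = "WT",
) -> DecisionResult:
    """Decision-error analysis of one low/high dose pair at one time point.

    Fits per-condition response models (Gaussian, or empirical tail
    fractions with ``method="empirical"``), resolves the threshold per the
    policy, and returns P_FA / P_M / P_e with the fitted models, sample
    counts, threshold and policy recorded in the provenance.
    """
    if method not in ("gaussian", "empirical"):
        raise CellDecideError(f"unknown method {method!r}")
    m0, m1, s0, s1 = _oriented_fits(table, dose_low, dose_high, time, genotype)
    try:
        threshold, policy_desc = _resolve_threshold(
            table, dose_low, dose_high, time, priors, policy, genotype, m0, m1
        )
    except NoThresholdError as exc:
        # Near-identical fitted distributions: no single between-means
        # threshold exists, so report the exact Bayes-region probabilities.
        logger.warning("falling back to exact-region analysis: %s", exc)
        p_fa, p_m = exact_region_error_probabilities(m0, m1, priors)
        return DecisionResult(
            p_fa=p_fa, p_m=p_m, p_e=overall_error(p_fa, p_m, priors),
            method="closed_form", threshold=None,
            provenance={
                "genotype": genotype, "dose_low": dose_low,
                "dose_high": dose_high, "time_min": time,
                "n_cells": (int(s0.size), int(s1.size)),
                "model0": m0, "model1": m1,
                "threshold_policy": "exact_region (no single threshold)",
                "priors": (priors.p_h0, priors.p_h1),
            },
        )
    logger.info(
        "pair (%g, %g ng/mL) @ %g min [%s]: n=(%d, %d), "
        "fit0=(%.4g, %.4g), fit1=(%.4g, %.4g), threshold=%.4g (%s)",
        dose_low, dose_high, time, genotype, s0.size, s1.size,
        m0.mean, m0.variance, m1.mean, m1.variance, threshold, policy_desc,
    )
    if method == "gaussian":
        result = analyze_gaussian_pair(m0, m1, priors, threshold=threshold)
    else:
        if policy.mode == "optimal":
            threshold = empirical.empirical_threshold_from_samples(s0, s1, priors)
            policy_desc = "optimal(empirical)"
        result = empirical.empirical_error_from_samples(s0, s1, threshold, priors)
    prov = dict(result.provenance)
    prov.update({
        "genotype": genotype,
        "dose_low": dose_low,
        "dose_high": dose_high,
        "time_min": time,
        "n_cells": (int(s0.size), int(s1.size)),
        "model0": m0,
        "model1": m1,
        "threshold_policy": policy_desc,
        "priors": (priors.p_h0, priors.p_h1),
    })
    return DecisionResult(
        p_fa=result.p_fa, p_m=result.p_m, p_e=result.p_e,
        method=result.method, threshold=result.threshold,
        mc_standard_error=result.mc_standard_error, provenance=prov,
    )


def dose_sweep(
    table: pd.DataFrame,
    reference_dose: float,
    time: float,
    priors: DecisionPriors = EQUAL_PRIORS,
    policy: ThresholdPolicy = OPTIMAL_POLICY,
    method: str = "gaussian",
    genotype: str = "WT",
) -> pd.DataFrame:
    """Overall error for the reference dose against every higher dose.

    One row per non-reference dose (ascending), with columns
    (dose_ng_ml, p_fa, p_m, p_e, threshold).  Quantifies how decision
    fidelity improves as the distinguishing dose grows.
    """
    mask = (table["genotype"] == genotype) & np.isclose(table["time_min"], time)
    doses = sorted(table.loc[mask, "dose_ng_ml"].unique())
    if not any(np.isclose(d, reference_dose) for d in doses):
        raise CellDecideError(
            f"reference dose {reference_dose} ng/mL absent at {time} min "
            f"for genotype {genotype!r} (available: {doses})"
        )
    others = [d for d in doses if not np.isclose(d, reference_dose)]
    if not others:
        raise CellDecideError("need at least two doses at this time point")
    rows = []
    for d in others:
        res = analyze_condition_pair(
            table, reference_dose, d, time, priors, policy, method, genotype
        )
        rows.append({
            "dose_ng_ml": d, "p_fa": res.p_fa, "p_m": res.p_m,
            "p_e": res.p_e, "threshold": res.threshold,
        })
    return pd.DataFrame(rows)


def _paired_responses(
    table: pd.DataFrame, dose: float, times: tuple[float, float], genotype: str
) -> np.ndarray:
    """(n, 2) per-cell (early, late) pairs, or empty if cells are unpaired."""
    sub = table[
        (table["genotype"] == genotype) & np.isclose(table["dose_ng_ml"], dose)
    ]
    wide = sub.pivot_table(index="cell_id", columns="time_min",
                           values="response", aggfunc="first")
    cols = []
    for t in times:
        match = [c for c in wide.columns if np.isclose(c, t)]
        if not match:
            return np.empty((0, 2))
        cols.append(match[0])
    paired = wide[cols].dropna()
    return paired.to_numpy(dtype=float)


def joint_analysis(
    table: pd.DataFrame,
    dose_low: float,
    dose_high: float,
    priors: DecisionPriors = EQUAL_PRIORS,
    correlation_source: float | str = "paired",
    settings: MCSettings | None = None,
    genotype: str = "WT",
    times: tuple[float, float] = (30.0, 240.0),
) -> DecisionResult:
    """Joint early/late decision analysis for one dose pair.

    Builds a bivariate Gaussian response model per hypothesis from the
    per-condition fits at the two time points plus a correlation, then
    estimates the error probabilities by Monte Carlo.  The correlation
    source precedence is: an explicit number (applied to both hypotheses)
    takes priority; ``"paired"`` estimates a per-dose Pearson correlation
    from cells measured at both time points; anything else is an error.
    """
    if settings is None:
        raise CellDecideError("MCSettings with an explicit seed are required")
    t_early, t_late = times
    models = {}
    rho_used = {}
    for hyp, dose in (("H0", dose_low), ("H1", dose_high)):
        fe = fit_gaussian(condition_samples(table, dose, t_early, genotype))
        fl = fit_gaussian(condition_samples(table, dose, t_late, genotype))
        if isinstance(correlation_source, (int, float)):
            rho = float(correlation_source)
            src = "user-supplied"
        elif correlation_source == "paired":
            pairs = _paired_responses(table, dose, times, genotype)
            if pairs.shape[0] < 3:
                raise CellDecideError(
                    f"dose {dose} ng/mL: no paired per-cell (early, late) "
                    "measurements; supply the correlation explicitly"
                )
            rho = estimate_correlation(pairs)
            src = f"estimated from {pairs.shape[0]} paired cells"
        else:
            raise CellDecideError(
                "correlation_source must be a number or 'paired'"
            )
        models[hyp] = BivariateResponseModel(
            mean_early=fe.mean, mean_late=fl.mean,
            var_early=fe.variance, var_late=fl.variance, correlation=rho,
        )
        rho_used[hyp] = (rho, src)
    result = mc_error_probabilities(models["H0"], models["H1"], priors, settings)
    prov = dict(result.provenance)
    prov.update({
        "genotype": genotype,
        "dose_low": dose_low,
        "dose_high": dose_high,
        "times_min": times,
        "correlation": rho_used,
    })
    return DecisionResult(
        p_fa=result.p_fa, p_m=result.p_m, p_e=result.p_e,
        method=result.method, threshold=None,
        mc_standard_error=result.mc_standard_error, provenance=prov,
    )


def rho_sensitivity(
    table: pd.DataFrame,
    dose_low: float,
    dose_high: float,
    rho_grid,
    priors: DecisionPriors = EQUAL_PRIORS,
    settings: MCSettings | None = None,
    genotype: str = "WT",
    times: tuple[float, float] = (30.0, 240.0),
) -> pd.DataFrame:
    """Joint P_FA / P_M across a grid of assumed correlations.

    When the true early/late correlation is unknown (e.g. it came from an
    external simulator), this sweep shows how sensitive the joint decision
    probabilities are to the assumed value.  The same correlation is
    applied to both hypotheses at each grid point.
    """
    if settings is None:
        raise CellDecideError("MCSettings with an explicit seed are required")
    rows = []
    for rho in np.asarray(rho_grid, dtype=float):
        res = joint_analysis(
            table, dose_low, dose_high, priors,
            correlation_source=float(rho), settings=settings,
            genotype=genotype, times=times,
        )
        se_fa, se_m = res.mc_standard_error
        rows.append({
            "rho": float(rho), "p_fa": res.p_fa, "p_m": res.p_m,
            "p_e": res.p_e, "se_fa": se_fa, "se_m": se_m,
        })
    return pd.DataFrame(rows)


def format_report(result: DecisionResult, title: str = "decision analysis") -> str:
    """Render a DecisionResult as a deterministic key-value text report."""
    lines = [f"# {title}"]
    lines.append(f"method: {result.method}")
    if result.threshold is not None:
        lines.append(f"threshold: {result.threshold:.6g}")
    else:
        lines.append("threshold: density-comparison region (no scalar threshold)")
    lines.append(f"p_fa: {result.p_fa:.6g}")
    lines.append(f"p_m: {result.p_m:.6g}")
    lines.append(f"p_e: {result.p_e:.6g}")
    if result.mc_standard_error is not None:
        se_fa, se_m = result.mc_standard_error
        lines.append(f"mc_se_fa: {se_fa:.3g}")
        lines.append(f"mc_se_m: {se_m:.3g}")
    for key in sorted(result.provenance):
        val = result.provenance[key]
        if isinstance(val, GaussianResponseModel):
            val = f"Gaussian(mean={val.mean:.6g}, variance={val.variance:.6g})"
        elif isinstance(val, BivariateResponseModel):
            val = (
                f"BivariateGaussian(mean=({val.mean_early:.6g}, "
                f"{val.mean_late:.6g}), var=({val.var_early:.6g}, "
                f"{val.var_late:.6g}), rho={val.correlation:.6g})"
            )
        lines.append(f"provenance.{key}: {val}")
    return "\n".join(lines) + "\n"
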