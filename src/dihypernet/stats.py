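"""Summary statistics and the sweep harness.

Power-law fitting of hyperdegree distributions (log-log least squares
and the continuous maximum-likelihood / Hill estimator), trajectory
feature extraction (peak and steady state), and a driver that sweeps a
single generator or contagion parameter over an ensemble per value.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .contagion import ContagionConfig, EnsembleSummary, run_ensemble
from .generators import ConfigError, GrowthConfig
from .hypergraph import DirectedHypergraph

__all__ = [
    "FitMethod",
    "PowerLawFit",
    "CurveFeatures",
    "fit_powerlaw",
    "exponential_fit_r2",
    "curve_features",
    "steady_step",
    "SweepSpec",
    "run_sweep",
]


class FitMethod(Enum):
    LOGLOG_REGRESSION = "loglog_regression"
    MLE = "mle"


@dataclass
class PowerLawFit:
    """Fitted exponent of P(k) ~ k^-gamma over [k_min, k_max].

    ``r_squared`` is reported for the regression method and
    ``loglikelihood`` for the MLE; the method tag is always carried
    because the two estimators answer slightly different questions.
    """

    exponent: float
    k_min: int
    k_max: int
    method: FitMethod
    r_squared: float | None = None
    loglikelihood: float | None = None


def _support(distribution: Mapping[int, float], k_min: int) -> tuple[np.ndarray, np.ndarray]:
    ks = np.array([k for k, p in sorted(distribution.items()) if p > 0 and k >= k_min])
    ps = np.array([distribution[int(k)] for k in ks])
    return ks, ps


def fit_powerlaw(
    distribution: Mapping[int, float],
    method: FitMethod = FitMethod.LOGLOG_REGRESSION,
    k_min: int = 1,
) -> PowerLawFit:
    """Fit a power-law exponent to a hyperdegree distribution.

    LOGLOG_REGRESSION: least squares on (log k, log P(k)) over the
    nonzero buckets with k >= k_min.  MLE: continuous maximum-likelihood
    exponent  1 + n / sum(ln(k / (k_min - 1/2)))  with the bucket
    probabilities as frequency weights; the half-shift is the standard
    correction when the continuous estimator is applied to integer
    degrees and is accurate for k_min of a few and up.
    """
    ks, ps = _support(distribution, k_min)
    if len(ks) < 5:
        raise ConfigError(
            f"power-law fit needs >= 5 support points, got {len(ks)}"
        )
    if method is FitMethod.LOGLOG_REGRESSION:
        x, y = np.log(ks.astype(float)), np.log(ps)
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (slope * x + intercept)
        ss_tot = ((y - y.mean()) ** 2).sum()
        r2 = 1.0 - (resid**2).sum() / ss_tot if ss_tot > 0 else 0.0
        return PowerLawFit(-slope, int(ks[0]), int(ks[-1]), method, r_squared=r2)
    # weighted continuous MLE (Hill estimator, half-shifted for integer data)
    wsum = ps.sum()
    mean_log = float((ps * np.log(ks / (k_min - 0.5))).sum() / wsum)
    if mean_log <= 0:
        raise ConfigError("degenerate support for MLE fit")
    exponent = 1.0 + 1.0 / mean_log
    ll = float(wsum * (np.log(exponent - 1) - np.log(k_min)) - exponent * wsum * mean_log)
    return PowerLawFit(exponent, int(ks[0]), int(ks[-1]), method, loglikelihood=ll)


def exponential_fit_r2(distribution: Mapping[int, float], k_min: int = 1) -> float:
    """r² of the exponential alternative log P(k) = a - b k (for model
    comparison against the power-law regression)."""
    ks, ps = _support(distribution, k_min)
    x, y = ks.astype(float), np.log(ps)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = ((y - y.mean()) ** 2).sum()
    return 1.0 - (resid**2).sum() / ss_tot if ss_tot > 0 else 0.0


@dataclass
class CurveFeatures:
    peak_step: int
    peak_value: float
    steady_step: int
    final_r: float
    steady_flag: bool   # False when the horizon ended before steadiness


def steady_step(curve: np.ndarray, tol: float = 1e-4, window: int = 3) -> tuple[int, bool]:
    """First step from which ``curve`` changes by less than ``tol`` over
    ``window`` consecutive steps; (horizon, False) when never steady."""
    diffs = np.abs(np.diff(curve))
    horizon = len(curve) - 1
    for tau in range(0, horizon - window + 1):
        if (diffs[tau : tau + window] < tol).all():
            return tau, True
    return horizon, False


def curve_features(
    summary: EnsembleSummary, tol: float = 1e-4, window: int = 3
) -> CurveFeatures:
    """Peak of the mean infectious curve (earliest argmax) and the first
    step where all four mean densities are steady."""
    i_mean = summary.i_mean
    peak = int(np.argmax(i_mean))
    diffs = np.abs(np.diff(summary.mean, axis=0)).max(axis=1)
    horizon = len(i_mean) - 1
    tau, flag = horizon, False
    for cand in range(0, horizon - window + 1):
        if (diffs[cand : cand + window] < tol).all():
            tau, flag = cand, True
            break
    return CurveFeatures(
        peak_step=peak,
        peak_value=float(i_mean[peak]),
        steady_step=tau,
        final_r=float(summary.r_mean[-1]),
        steady_flag=flag,
    )


@dataclass
class SweepSpec:
    """One-parameter sweep: ``parameter`` must name a field of either the
    growth config or the contagion config (growth wins on a tie)."""

    parameter: str
    values: Sequence[float]
    n_reps: int
    growth: GrowthConfig
    contagion: ContagionConfig
    seeds: Sequence[int] | None = None   # per-replicate seeds, shared across values


def run_sweep(spec: SweepSpec) -> pd.DataFrame:
    """One row per swept value with the ensemble curve features.

    Deterministic given the seed list: the same per-replicate seeds are
    reused at every value so that differences reflect the parameter, not
    the draw."""
    rows = []
    growth_fields = {f.name for f in dataclasses.fields(GrowthConfig)}
    contagion_fields = {f.name for f in dataclasses.fields(ContagionConfig)}
    if spec.parameter not in growth_fields | contagion_fields:
        raise ConfigError(f"unknown sweep parameter {spec.parameter!r}")
    seeds = spec.seeds
    if seeds is None:
        ss = np.random.SeedSequence(spec.contagion.seed)
        seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(spec.n_reps)]
    for value in spec.values:
        growth = dataclasses.replace(spec.growth)
        contagion = dataclasses.replace(spec.contagion)
        if spec.parameter in growth_fields:
            setattr(growth, spec.parameter, value)
        else:
            setattr(contagion, spec.parameter, value)
        summary = run_ensemble(growth, contagion, spec.n_reps, seeds=list(seeds))
        feats = curve_features(summary)
        rows.append(
            {
                "value": value,
                "peak_step": feats.peak_step,
                "peak_i": feats.peak_value,
                "steady_step": feats.steady_step,
                "final_r": feats.final_r,
                "final_s": float(summary.mean[-1, 0]),
                "steady": feats.steady_flag,
            }
        )
    return pd.DataFrame(rows)
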