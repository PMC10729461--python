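"""Average calibration: calibration curve, miscalibration area, Z tests.

If the predicted uncertainties are correct and the errors Gaussian, the
Z-scores Z_i = eps_i/sigma_i follow a standard normal.  The calibration curve
compares, for a grid of expected fractions q, the fraction of |Z| that falls
below the standard-normal quantile containing probability q, to q itself;
the miscalibration area A_mis is the area between this curve and the
diagonal.  At the |Z|=2 threshold a calibrated model leaves a 0.045 tail,
at |Z|=3 a 0.003 tail.

Because A_mis assumes Gaussian errors, the distribution-free alternatives
Var(Z) =? 1 and mu(Z) =? 0 are also provided: a BCa bootstrap confidence
interval is built for the sample variance (or mean) of Z and the test passes
when the target is inside the interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import ndtri

from .dataset import ZScores

__all__ = [
    "CalibrationCurve",
    "IntervalTestResult",
    "calibration_curve",
    "miscalibration_area",
    "bca_interval",
    "z_variance_test",
    "z_mean_test",
]


def _z_values(z) -> np.ndarray:
    return np.asarray(getattr(z, "values", z), dtype=float)


@dataclass(frozen=True)
class CalibrationCurve:
    """Observed vs. expected fraction of |Z| below normal-quantile thresholds."""

    expected_fractions: np.ndarray
    observed_fractions: np.ndarray

    def __post_init__(self):
        exp = np.asarray(self.expected_fractions, dtype=float)
        obs = np.asarray(self.observed_fractions, dtype=float)
        object.__setattr__(self, "expected_fractions", exp)
        object.__setattr__(self, "observed_fractions", obs)
        if exp.shape != obs.shape or exp.ndim != 1:
            raise ValueError("fraction sequences must be 1-D of equal length")
        if not (exp[0] == 0.0 and exp[-1] == 1.0 and obs[0] == 0.0 and obs[-1] == 1.0):
            raise ValueError("curves must start at 0 and end at 1")
        if np.any(np.diff(exp) <= 0):
            raise ValueError("expected fractions must be strictly increasing")
        if np.any((obs < 0) | (obs > 1)):
            raise ValueError("observed fractions must lie in [0, 1]")


def calibration_curve(z, grid_size: int = 100) -> CalibrationCurve:
    """Build the calibration curve on a uniform expected-fraction grid.

    The grid has ``grid_size`` points plus the two endpoints 0 and 1.  For
    each expected fraction q the threshold is the standard-normal quantile
    z_q = Phi^{-1}((1+q)/2), so that P(|Z| <= z_q) = q under N(0,1); the
    observed fraction is the proportion of |Z_i| <= z_q (non-strict).
    """
    if grid_size < 2:
        raise ValueError("grid size must be >= 2")
    zv = np.abs(_z_values(z))
    if zv.size < 2:
        raise ValueError("need at least 2 Z-scores")
    q = np.linspace(0.0, 1.0, grid_size + 2)
    thresholds = ndtri((1.0 + q[:-1]) / 2.0)  # q=1 -> inf handled below
    observed = np.empty_like(q)
    observed[:-1] = (zv[None, :] <= thresholds[:, None]).mean(axis=1)
    observed[0] = 0.0  # |Z| <= 0 can retain exact zeros; the curve anchors at 0
    observed[-1] = 1.0
    return CalibrationCurve(expected_fractions=q, observed_fractions=observed)


def miscalibration_area(curve: CalibrationCurve) -> float:
    """Trapezoidal area between the calibration curve and the diagonal."""
    gap = np.abs(curve.observed_fractions - curve.expected_fractions)
    return float(np.trapezoid(gap, curve.expected_fractions))


def bca_interval(
    samples,
    statistic,
    level: float = 0.95,
    reps: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Bias-corrected and accelerated bootstrap interval for a statistic.

    Bias correction comes from the fraction of bootstrap statistics below the
    point estimate; acceleration from jackknife skewness.  Degenerate samples
    (all identical) give a zero-width interval at the point estimate; a
    degenerate acceleration denominator falls back to the plain percentile
    interval with a warning.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    point = float(statistic(x))
    if np.all(x == x[0]):
        return (point, point)
    rng = np.random.default_rng(seed)

    # use the statistic's own axis support when it has it (much faster);
    # otherwise fall back to row-by-row evaluation
    probe = np.array([[1.0, 2.0, 3.0], [2.0, 3.0, 5.0]])
    try:
        vectorized = np.shape(statistic(probe, axis=-1)) == (2,)
    except TypeError:
        vectorized = False
    if vectorized:
        stat = statistic
    else:

        def stat(sample, axis=-1):
            return np.apply_along_axis(statistic, axis, np.asarray(sample))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.bootstrap(
            (x,),
            stat,
            n_resamples=reps,
            confidence_level=level,
            method="BCa",
            vectorized=True,
            rng=rng,
        )
        lo, hi = float(res.confidence_interval.low), float(res.confidence_interval.high)
    # BCa can collapse for lattice-valued / bounded statistics (the bias
    # correction diverges when nearly all bootstrap values sit below the
    # point estimate); fall back to the plain percentile interval then
    if not (np.isfinite(lo) and np.isfinite(hi)) or lo == hi:
        warnings.warn(
            "BCa interval degenerate; falling back to percentile interval",
            stacklevel=2,
        )
        res = stats.bootstrap(
            (x,),
            stat,
            n_resamples=reps,
            confidence_level=level,
            method="percentile",
            vectorized=True,
            rng=np.random.default_rng(seed),
        )
        lo, hi = float(res.confidence_interval.low), float(res.confidence_interval.high)
    # bootstrap endpoints can straddle the point estimate only one way for
    # very skewed statistics; clamp so the reported interval contains it
    return (min(lo, point), max(hi, point))


@dataclass(frozen=True)
class IntervalTestResult:
    """Outcome of an interval test: does the CI contain the target value?"""

    statistic: str
    estimate: float
    ci_low: float
    ci_high: float
    level: float
    target: float
    passed: bool

    def __post_init__(self):
        if not self.ci_low <= self.estimate <= self.ci_high:
            raise ValueError("point estimate must lie inside the interval")
        if self.passed != (self.ci_low <= self.target <= self.ci_high):
            raise ValueError("passed flag inconsistent with interval and target")


def _interval_test(
    z, name: str, statistic, target: float, level: float, reps: int, seed: int
) -> IntervalTestResult:
    zv = _z_values(z)
    if zv.size < 2:
        raise ValueError("need at least 2 Z-scores")
    est = float(statistic(zv))
    lo, hi = bca_interval(zv, statistic, level=level, reps=reps, seed=seed)
    return IntervalTestResult(
        statistic=name,
        estimate=est,
        ci_low=lo,
        ci_high=hi,
        level=level,
        target=target,
        passed=bool(lo <= target <= hi),
    )


def z_variance_test(
    z, level: float = 0.95, reps: int = 1000, seed: int = 0
) -> IntervalTestResult:
    """Var(Z) =? 1 average-calibration test (unbiased n-1 variance)."""
    return _interval_test(
        z, "Var(Z)", lambda s, axis=-1: np.var(s, ddof=1, axis=axis), 1.0, level, reps, seed
    )


def z_mean_test(
    z, level: float = 0.95, reps: int = 1000, seed: int = 0
) -> IntervalTestResult:
    """mu(Z) =? 0 bias test."""
    return _interval_test(z, "mean(Z)", np.mean, 0.0, level, reps, seed)
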