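"""Ranking and likelihood metrics with simulated reference values.

Spearman's rank correlation between absolute errors and uncertainties and the
average Gaussian negative log likelihood (NLL) are standard UQ scores, but
their raw values are hard to interpret: the value a *perfect* uncertainty
model would attain depends entirely on the predicted uncertainty
distribution.  The simulated reference fixes this: errors are repeatedly
resampled from the predicted uncertainties (eps_i ~ N(0, sigma_i^2)), the
metric is recomputed on each resample, and the mean and standard deviation
over replicates define the value the metric *should* take if the
uncertainties were exactly right.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .dataset import UQDataset

__all__ = [
    "MetricError",
    "SimulatedReference",
    "spearman_rank",
    "nll",
    "gaussian_nll",
    "expected_nll",
    "simulate_reference",
]

_LN_2PI = float(np.log(2.0 * np.pi))


class MetricError(ValueError):
    """Raised when a metric is undefined for the given input."""


@dataclass(frozen=True)
class SimulatedReference:
    """Mean and spread of a metric under resampling from the uncertainties."""

    metric: str
    mean: float
    sd: float
    reps: int
    seed: int

    def __post_init__(self):
        if self.reps < 2:
            raise MetricError("simulated reference needs reps >= 2")
        if self.sd < 0:
            raise MetricError("sd must be non-negative")

    def z_distance(self, observed: float) -> float:
        """(observed - mean)/sd — how many simulated sd's the observation is off.

        Reported without a pass/fail verdict; a large discrepancy is a
        diagnostic, not a test.
        """
        if self.sd == 0:
            return float("inf") if observed != self.mean else 0.0
        return (observed - self.mean) / self.sd

    def __format__(self, spec: str) -> str:
        spec = spec or ".2f"
        return f"{self.mean:{spec}} ({self.sd:{spec}})"

    def __str__(self) -> str:
        return format(self)


def spearman_rank(abs_errors, uncertainties) -> float:
    """Spearman's rank correlation of |errors| against uncertainties.

    Both lists are replaced by their ranks (average ranks for ties) and the
    Pearson correlation of the rank lists is returned.
    """
    ae = np.asarray(abs_errors, dtype=float)
    sig = np.asarray(uncertainties, dtype=float)
    if ae.shape != sig.shape:
        raise MetricError("abs_errors and uncertainties must have equal length")
    if ae.size < 2:
        raise MetricError("need at least 2 samples for a rank correlation")
    if np.all(ae == ae[0]) or np.all(sig == sig[0]):
        raise MetricError("rank correlation undefined for a constant input list")
    return float(stats.spearmanr(ae, sig).statistic)


def gaussian_nll(errors, uncertainties) -> float:
    """Average Gaussian NLL: (1/2N) * sum[ln(2*pi) + ln(sigma_i^2) + eps_i^2/sigma_i^2]."""
    eps = np.asarray(errors, dtype=float)
    sig = np.asarray(uncertainties, dtype=float)
    return float(0.5 * np.mean(_LN_2PI + np.log(sig**2) + (eps / sig) ** 2))


def nll(data: UQDataset) -> float:
    """Average NLL of the dataset's errors under its predicted uncertainties."""
    return gaussian_nll(data.errors, data.uncertainties)


def expected_nll(uncertainties) -> float:
    """Closed-form expectation of the NLL for exactly calibrated errors.

    With eps_i ~ N(0, sigma_i^2), E[eps_i^2/sigma_i^2] = 1, so
    E[NLL] = (1/2) * (ln 2*pi + mean(ln sigma_i^2) + 1).
    """
    sig = np.asarray(uncertainties, dtype=float)
    return float(0.5 * (_LN_2PI + np.mean(np.log(sig**2)) + 1.0))


def _spearman_rows(abs_err_rows: np.ndarray, sigma_ranks: np.ndarray) -> np.ndarray:
    """Row-wise Spearman of each row of |errors| against one fixed sigma rank list."""
    r = stats.rankdata(abs_err_rows, axis=1)
    r = r - r.mean(axis=1, keepdims=True)
    s = sigma_ranks - sigma_ranks.mean()
    num = r @ s
    den = np.sqrt((r**2).sum(axis=1) * (s**2).sum())
    return num / den


def simulate_reference(
    uncertainties,
    metric: str = "spearman",
    reps: int = 1000,
    seed: int = 0,
) -> SimulatedReference:
    """Simulated reference value of a metric for a given uncertainty list.

    For each replicate, errors are drawn as eps_i ~ N(0, sigma_i^2) and the
    metric is computed against the fixed sigma list; the mean and standard
    deviation over replicates are returned.  The NLL branch depends only on
    the sigma list; the spearman branch converts the signed draws to |eps|
    internally, so both branches share one sampling path.
    """
    sig = np.asarray(uncertainties, dtype=float)
    if sig.size < 2:
        raise MetricError("need at least 2 uncertainties")
    if np.any(sig <= 0):
        raise MetricError("uncertainties must be strictly positive")
    if reps < 2:
        raise MetricError("reps must be >= 2")
    if metric not in ("spearman", "nll"):
        raise MetricError(f"unknown metric {metric!r}; expected 'spearman' or 'nll'")

    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, sig, size=(reps, sig.size))
    if metric == "spearman":
        sigma_ranks = stats.rankdata(sig)
        if np.ptp(sigma_ranks) == 0:
            # a fully tied uncertainty list carries no ranking information;
            # the resampled errors are exchangeable, so correlate against
            # input order, which averages to ~0 over replicates
            sigma_ranks = np.arange(1.0, sig.size + 1.0)
        vals = _spearman_rows(np.abs(eps), sigma_ranks)
    else:
        vals = 0.5 * np.mean(_LN_2PI + np.log(sig**2) + (eps / sig) ** 2, axis=1)
    return SimulatedReference(
        metric=metric,
        mean=float(vals.mean()),
        sd=float(vals.std(ddof=1)),
        reps=reps,
        seed=seed,
    )
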