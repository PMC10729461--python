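"""Error-based calibration: RMSE vs RMV across uncertainty-ordered bins.

Samples are ordered by predicted uncertainty and cut into equal-count bins.
For each bin the root mean square error RMSE = sqrt(mean eps_i^2) and the
root mean variance RMV = sqrt(mean sigma_i^2) are computed; for calibrated
uncertainties the RMSE-vs-RMV scatter follows the identity line, and an
ordinary least-squares fit (slope a, intercept b, R^2) summarises the
deviation.  Per-bin BCa bootstrap confidence intervals on the RMSE show
whether a bin's departure from the identity line is significant.

The identity line, not the fit, is the calibration reference.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .calibration import bca_interval
from .dataset import UQDataset

__all__ = [
    "LinearFit",
    "CalibrationBin",
    "BinnedCalibration",
    "bin_by_uncertainty",
    "binned_rmse_rmv",
    "fit_calibration_line",
    "binned_rmse_intervals",
    "error_based_calibration",
]


@dataclass(frozen=True)
class LinearFit:
    """OLS summary of RMSE against RMV: slope, intercept (property units), R^2."""

    slope: float
    intercept: float
    r_squared: float

    def __post_init__(self):
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError(f"R^2 must be in [0, 1], got {self.r_squared}")


@dataclass(frozen=True)
class CalibrationBin:
    n: int
    rmv: float
    rmse: float
    rmse_ci: tuple[float, float] | None = None

    def __post_init__(self):
        if self.rmse_ci is not None:
            lo, hi = self.rmse_ci
            if not lo <= self.rmse <= hi:
                raise ValueError("rmse_ci must contain the bin RMSE")


@dataclass(frozen=True)
class BinnedCalibration:
    """Ordered uncertainty bins with RMV, RMSE, optional CIs and linear fit."""

    bins: tuple[CalibrationBin, ...]
    fit: LinearFit | None = None

    def __post_init__(self):
        rmvs = [b.rmv for b in self.bins]
        if any(b2 < b1 for b1, b2 in zip(rmvs, rmvs[1:])):
            raise ValueError("bins must be ordered by non-decreasing RMV")

    @property
    def rmv(self) -> np.ndarray:
        return np.array([b.rmv for b in self.bins])

    @property
    def rmse(self) -> np.ndarray:
        return np.array([b.rmse for b in self.bins])

    @property
    def total_n(self) -> int:
        return sum(b.n for b in self.bins)


def bin_by_uncertainty(data: UQDataset, bin_size: int = 250) -> list[np.ndarray]:
    """Sort samples by uncertainty (ascending) and cut into equal-count bins.

    Returns index arrays into the original dataset.  A final remainder of at
    least ``bin_size/2`` samples is kept as its own bin, otherwise merged
    into the previous one.  Ties in sigma are broken by stable input order so
    binning is reproducible.
    """
    if bin_size <= 0:
        raise ValueError("bin size must be positive")
    if bin_size > data.n:
        raise ValueError(f"bin size {bin_size} exceeds dataset size {data.n}")
    order = np.argsort(data.uncertainties, kind="stable")
    n_full = data.n // bin_size
    remainder = data.n - n_full * bin_size
    cuts = [bin_size * i for i in range(n_full + 1)]
    if remainder >= bin_size / 2:
        cuts.append(data.n)
    else:
        cuts[-1] = data.n  # merge the short remainder into the last full bin
    return [order[a:b] for a, b in zip(cuts, cuts[1:])]


def binned_rmse_rmv(data: UQDataset, bins: list[np.ndarray]) -> BinnedCalibration:
    """Per-bin RMSE = sqrt(mean eps^2) and RMV = sqrt(mean sigma^2)."""
    out = []
    for idx in bins:
        if len(idx) == 0:
            raise ValueError("empty bin")
        out.append(
            CalibrationBin(
                n=len(idx),
                rmv=float(np.sqrt(np.mean(data.uncertainties[idx] ** 2))),
                rmse=float(np.sqrt(np.mean(data.errors[idx] ** 2))),
            )
        )
    return BinnedCalibration(bins=tuple(out))


def fit_calibration_line(binned: BinnedCalibration) -> LinearFit:
    """Unweighted OLS of bin RMSE on bin RMV."""
    rmv, rmse = binned.rmv, binned.rmse
    if np.unique(rmv).size < 2:
        raise ValueError("need at least 2 bins with distinct RMV for a fit")
    res = stats.linregress(rmv, rmse)
    return LinearFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=min(float(res.rvalue**2), 1.0),
    )


def _rmse_stat(e, axis=-1):
    return np.sqrt(np.mean(np.asarray(e) ** 2, axis=axis))


def binned_rmse_intervals(
    data: UQDataset,
    bins: list[np.ndarray],
    level: float = 0.95,
    reps: int = 1000,
    seed: int = 0,
) -> list[tuple[float, float]]:
    """BCa bootstrap interval of the RMSE within each bin (errors resampled)."""
    seeds = np.random.SeedSequence(seed).generate_state(len(bins)) % (2**31)
    return [
        bca_interval(data.errors[idx], _rmse_stat, level=level, reps=reps, seed=int(s))
        for idx, s in zip(bins, seeds)
    ]


def error_based_calibration(
    data: UQDataset,
    bin_size: int = 250,
    with_ci: bool = False,
    level: float = 0.95,
    reps: int = 1000,
    seed: int = 0,
) -> BinnedCalibration:
    """One-call pipeline: bin, compute RMSE/RMV, fit, optionally attach CIs."""
    bins = bin_by_uncertainty(data, bin_size)
    binned = binned_rmse_rmv(data, bins)
    if with_ci:
        cis = binned_rmse_intervals(data, bins, level=level, reps=reps, seed=seed)
        binned = BinnedCalibration(
            bins=tuple(
                replace(b, rmse_ci=ci) for b, ci in zip(binned.bins, cis)
            )
        )
    fit = None
    if len(binned.bins) >= 2 and np.unique(binned.rmv).size >= 2:
        fit = fit_calibration_line(binned)
    return BinnedCalibration(bins=binned.bins, fit=fit)
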