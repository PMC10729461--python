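"""Seeded synthetic scenarios for exercising every calibration metric.

The generators emulate three toy constructions:

* a sigma grid with one or more Gaussian errors drawn per sigma
  (eps ~ N(0, sigma^2), uncertainty recorded as the generating sigma) —
  exactly calibrated by construction, so it drives the null behaviour of
  every metric: Var(Z) -> 1, A_mis -> 0, error-based fit -> (1, 0, R^2~1);
* a deliberate scale mismatch: errors below a sigma threshold inflated by
  1.25 (25% too large for their stated uncertainties) and errors above it
  deflated by 0.8, which each half's miscalibration area detects (~0.07)
  while the pooled area nearly cancels;
* the cubic extrapolation toy y = x^3 + eps with aleatoric noise
  eps ~ N(0, 3^2), training range [-4, 4], test ranges [-4, 4] (in
  distribution) or [-6, 6] (one third out of distribution).

The default sigma grid is 0.5 to 10 in steps of 0.01 (951 values).  The
0.01 spacing and the 0.5-1.5 highlighted subrange are fixed by the toy
construction; the 0.5 and 10 end points are inferred from the half-grid NLL
values they reproduce (closed-form expectations 2.28 and 3.42 on [0.5, 5]
and (5, 10]).  Every generator is a pure function of its arguments,
including the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .dataset import UQDataset

__all__ = [
    "ScalingRule",
    "SyntheticScenario",
    "sigma_grid",
    "sample_gaussian_errors",
    "apply_error_scaling",
    "cubic_toy_data",
    "calibrated_grid_scenario",
    "scale_mismatch_scenario",
    "scenario_from_config",
    "DEFAULT_GRID",
    "DEFAULT_SCALING",
]

DEFAULT_GRID = (0.5, 10.0, 0.01)
DEFAULT_SCALING = {"threshold": 5.0, "factor_low": 1.25, "factor_high": 0.8}


@dataclass(frozen=True)
class ScalingRule:
    """Multiply errors by factor_low below the sigma threshold, factor_high above."""

    threshold: float
    factor_low: float
    factor_high: float

    def __post_init__(self):
        if self.factor_low <= 0 or self.factor_high <= 0:
            raise ValueError("scaling factors must be strictly positive")


@dataclass(frozen=True)
class SyntheticScenario:
    """A reproducible scenario: sigma values, draws per sigma, optional scaling."""

    name: str
    sigma_values: tuple[float, ...]
    draws_per_sigma: int = 1
    scaling: ScalingRule | None = None
    seed: int = 0

    def generate(self) -> UQDataset:
        data = sample_gaussian_errors(
            np.asarray(self.sigma_values), self.draws_per_sigma, seed=self.seed
        )
        if self.scaling is not None:
            data = apply_error_scaling(
                data,
                self.scaling.threshold,
                self.scaling.factor_low,
                self.scaling.factor_high,
            )
        return data


def sigma_grid(low: float, high: float, step: float) -> np.ndarray:
    """Arithmetic grid low, low+step, ..., inclusive of high when it lands on
    the grid within half a step."""
    if not (low > 0 and high > low and step > 0):
        raise ValueError("need 0 < low < high and step > 0")
    if step > high - low:
        raise ValueError("step must not exceed high - low")
    n_intervals = int(round((high - low) / step))
    if low + n_intervals * step > high + step / 2:
        n_intervals -= 1
    return low + step * np.arange(n_intervals + 1)


def sample_gaussian_errors(
    sigmas, draws_per_sigma: int = 1, seed: int = 0
) -> UQDataset:
    """Draw eps ~ N(0, sigma^2) per sigma; uncertainties are the generating sigmas.

    With ``draws_per_sigma > 1`` each sigma is repeated that many times, so
    the output stays a flat (error, uncertainty) dataset.
    """
    sig = np.asarray(sigmas, dtype=float)
    if np.any(sig <= 0):
        raise ValueError("sigmas must be strictly positive")
    if draws_per_sigma < 1:
        raise ValueError("draws per sigma must be >= 1")
    rng = np.random.default_rng(seed)
    rep = np.repeat(sig, draws_per_sigma)
    return UQDataset(errors=rng.normal(0.0, rep), uncertainties=rep)


def apply_error_scaling(
    data: UQDataset, threshold: float, factor_low: float, factor_high: float
) -> UQDataset:
    """Scale errors by factor_low where sigma <= threshold, factor_high above.

    Uncertainties are left unchanged — the point is to create a mismatch
    between the stated and the actual error scale.  Samples exactly at the
    threshold take factor_low.
    """
    ScalingRule(threshold, factor_low, factor_high)  # validate factors
    factors = np.where(data.uncertainties <= threshold, factor_low, factor_high)
    return UQDataset(errors=data.errors * factors, uncertainties=data.uncertainties)


def cubic_toy_data(
    n: int,
    x_low: float = -4.0,
    x_high: float = 4.0,
    noise_sd: float = 3.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """x uniform on [x_low, x_high]; y = x^3 + eps, eps ~ N(0, noise_sd^2).

    Defaults follow the cubic extrapolation toy: training range [-4, 4],
    aleatoric noise sd 3; an out-of-distribution test set uses [-6, 6], where
    one third of the samples fall outside the training interval.
    """
    if x_low >= x_high:
        raise ValueError("x_low must be below x_high")
    if noise_sd <= 0:
        raise ValueError("noise sd must be positive")
    rng = np.random.default_rng(seed)
    x = rng.uniform(x_low, x_high, size=n)
    y = x**3 + rng.normal(0.0, noise_sd, size=n)
    return x, y


def calibrated_grid_scenario(
    draws_per_sigma: int = 1, seed: int = 0, grid: tuple[float, float, float] = DEFAULT_GRID
) -> SyntheticScenario:
    """The exactly calibrated sigma-grid scenario (0.5 to 10, step 0.01)."""
    return SyntheticScenario(
        name="calibrated-grid",
        sigma_values=tuple(sigma_grid(*grid)),
        draws_per_sigma=draws_per_sigma,
        seed=seed,
    )


def scale_mismatch_scenario(
    draws_per_sigma: int = 1, seed: int = 0, grid: tuple[float, float, float] = DEFAULT_GRID
) -> SyntheticScenario:
    """The scale-mismatch scenario: x1.25 below sigma=5, x0.8 above."""
    return SyntheticScenario(
        name="scale-mismatch",
        sigma_values=tuple(sigma_grid(*grid)),
        draws_per_sigma=draws_per_sigma,
        scaling=ScalingRule(**DEFAULT_SCALING),
        seed=seed,
    )


def scenario_from_config(path) -> SyntheticScenario:
    """Read a scenario definition from a small JSON file.

    Keys: ``name``; either ``sigma_values`` (list) or ``grid``
    ([low, high, step]); optional ``draws_per_sigma``, ``seed`` and
    ``scaling`` ({threshold, factor_low, factor_high}).
    """
    with open(path) as fh:
        cfg = json.load(fh)
    if "sigma_values" in cfg:
        sig = tuple(float(s) for s in cfg["sigma_values"])
    else:
        sig = tuple(sigma_grid(*cfg["grid"]))
    scaling = ScalingRule(**cfg["scaling"]) if "scaling" in cfg else None
    return SyntheticScenario(
        name=cfg.get("name", "scenario"),
        sigma_values=sig,
        draws_per_sigma=int(cfg.get("draws_per_sigma", 1)),
        scaling=scaling,
        seed=int(cfg.get("seed", 0)),
    )
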