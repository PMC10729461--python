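"""Post-hoc re-calibration of predicted uncertainties.

Three linear re-calibration families are provided, all fitted on a
validation set and applied to test uncertainties:

* ``rmv_linear`` — sigma_cal = slope_val * sigma + intercept_val, where slope
  and intercept come from the validation set's error-based calibration fit
  (RMSE vs RMV).  Makes no Gaussian assumption.
* ``nll_linear`` — the same linear form on sigma, but with parameters chosen
  to minimise the Gaussian NLL of the validation (error, sigma) pairs.
* ``distance_variance`` — maps latent-space k-NN distances d to variances via
  V(d) = theta0^2 + theta1^2 * d (non-negative by construction) or the more
  flexible V(d) = theta0 + theta1^2 * d, which permits a negative offset;
  any V(d) < 0 is clipped to the floor 0.0001 before use.  Parameters
  minimise the validation NLL.

Every model guarantees strictly positive output uncertainties via the
variance floor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from sklearn.neighbors import NearestNeighbors

from .binning import LinearFit
from .metrics import _LN_2PI

__all__ = [
    "RecalibrationModel",
    "LatentConfig",
    "load_embedding",
    "knn_latent_distance",
    "fit_distance_variance",
    "apply_distance_variance",
    "recalibrate_from_fit",
    "nll_minimizing_recalibration",
]

VARIANCE_FLOOR = 1e-4


@dataclass(frozen=True)
class RecalibrationModel:
    """A fitted linear re-calibration transform.

    ``rmv_linear`` and ``nll_linear`` use (slope, intercept) acting on sigma;
    ``distance_variance`` uses (theta0, theta1) acting on distances, with
    ``flexible`` selecting the signed-offset variance form.
    """

    kind: str  # {rmv_linear, distance_variance, nll_linear}
    slope: float | None = None
    intercept: float | None = None
    theta0: float | None = None
    theta1: float | None = None
    flexible: bool = False
    clip_floor: float = VARIANCE_FLOOR
    converged: bool = True

    def __post_init__(self):
        if self.kind in ("rmv_linear", "nll_linear"):
            if self.slope is None or self.intercept is None:
                raise ValueError(f"{self.kind} needs slope and intercept")
            if self.theta0 is not None or self.theta1 is not None:
                raise ValueError(f"{self.kind} must not carry theta parameters")
        elif self.kind == "distance_variance":
            if self.theta0 is None or self.theta1 is None:
                raise ValueError("distance_variance needs theta0 and theta1")
            if self.slope is not None or self.intercept is not None:
                raise ValueError("distance_variance must not carry slope/intercept")
        else:
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.clip_floor <= 0:
            raise ValueError("clip floor must be positive")

    def apply(self, values) -> np.ndarray:
        """Apply to sigmas (linear kinds) or distances (distance_variance)."""
        if self.kind == "distance_variance":
            return apply_distance_variance(self, values)
        sig = np.asarray(values, dtype=float)
        out = self.slope * sig + self.intercept
        return np.maximum(out, np.sqrt(self.clip_floor))

    def to_text(self, path) -> None:
        """Serialise as a small key=value text file."""
        lines = [f"kind={self.kind}", f"flexible={self.flexible}",
                 f"clip_floor={self.clip_floor!r}"]
        for name in ("slope", "intercept", "theta0", "theta1"):
            val = getattr(self, name)
            if val is not None:
                lines.append(f"{name}={val!r}")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")

    @classmethod
    def from_text(cls, path) -> "RecalibrationModel":
        kw: dict = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                key, val = line.split("=", 1)
                if key == "kind":
                    kw[key] = val
                elif key == "flexible":
                    kw[key] = val == "True"
                else:
                    kw[key] = float(val)
        return cls(**kw)


@dataclass(frozen=True)
class LatentConfig:
    """k-NN configuration for latent-space distance uncertainties (k=10 default)."""

    k: int = 10
    metric: str = "euclidean"

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")


def load_embedding(path, delimiter: str = ",") -> np.ndarray:
    """Read an embedding matrix from a delimited text table, one vector per row."""
    arr = np.atleast_2d(np.loadtxt(path, delimiter=delimiter, dtype=float))
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"non-finite values in embedding file {path}")
    return arr


def knn_latent_distance(
    train_vectors, query_vectors, config: LatentConfig = LatentConfig()
) -> np.ndarray:
    """Mean distance of each query to its k nearest training vectors."""
    train = np.atleast_2d(np.asarray(train_vectors, dtype=float))
    query = np.atleast_2d(np.asarray(query_vectors, dtype=float))
    if train.shape[1] != query.shape[1]:
        raise ValueError(
            f"dimension mismatch: train has {train.shape[1]} features, "
            f"query has {query.shape[1]}"
        )
    if config.k > train.shape[0]:
        raise ValueError(f"k={config.k} exceeds training-set size {train.shape[0]}")
    nn = NearestNeighbors(n_neighbors=config.k, metric=config.metric).fit(train)
    dists, _ = nn.kneighbors(query)
    return dists.mean(axis=1)


def _variances(theta: np.ndarray, d: np.ndarray, flexible: bool, floor: float):
    v = (theta[0] + theta[1] ** 2 * d) if flexible else (theta[0] ** 2 + theta[1] ** 2 * d)
    return np.maximum(v, floor)


def _nll_of_var(var: np.ndarray, err2: np.ndarray) -> float:
    return float(0.5 * np.mean(_LN_2PI + np.log(var) + err2 / var))


def _multistart_minimize(objective, starts) -> tuple[np.ndarray, bool]:
    """Deterministic multi-start Nelder-Mead; returns best point and convergence."""
    best, converged = None, False
    for x0 in starts:
        res = optimize.minimize(
            objective,
            np.asarray(x0, dtype=float),
            method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-8, "maxiter": 4000},
        )
        if best is None or res.fun < best.fun:
            best, converged = res, bool(res.success)
        elif res.fun == best.fun:
            converged = converged or bool(res.success)
    return best.x, converged


def fit_distance_variance(
    distances_val, errors_val, flexible: bool = False
) -> RecalibrationModel:
    """Fit V(d) parameters by minimising the validation-set Gaussian NLL.

    Start points are moment based (OLS of eps^2 on d) plus fixed
    perturbations; non-convergence is reported on the returned model, which
    still carries the best point found.
    """
    d = np.asarray(distances_val, dtype=float)
    e = np.asarray(errors_val, dtype=float)
    if d.shape != e.shape:
        raise ValueError("distances and errors must have equal length")
    if d.size < 2:
        raise ValueError("need at least 2 validation samples")
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    err2 = e**2

    # moment guess: E[eps^2 | d] = offset + slope*d
    if np.ptp(d) > 0:
        slope, offset = np.polyfit(d, err2, 1)
    else:
        slope, offset = 0.0, float(np.mean(err2))
    t1 = np.sqrt(max(slope, 1e-6))
    t0 = offset if flexible else np.sqrt(max(offset, 1e-6))
    starts = [(t0, t1)]
    for f0, f1 in ((0.5, 2.0), (2.0, 0.5), (1.0, 0.1)):
        starts.append((t0 * f0, t1 * f1))
    base = np.sqrt(np.mean(err2))
    starts.append((base if not flexible else base**2, 1e-3))

    def objective(theta):
        return _nll_of_var(_variances(theta, d, flexible, VARIANCE_FLOOR), err2)

    theta, converged = _multistart_minimize(objective, starts)
    return RecalibrationModel(
        kind="distance_variance",
        theta0=float(theta[0]),
        theta1=float(theta[1]),
        flexible=flexible,
        converged=converged,
    )


def apply_distance_variance(model: RecalibrationModel, distances) -> np.ndarray:
    """sigma_i = sqrt(max(V(d_i), clip floor))."""
    if model.kind != "distance_variance":
        raise ValueError(f"expected a distance_variance model, got {model.kind!r}")
    d = np.asarray(distances, dtype=float)
    theta = np.array([model.theta0, model.theta1])
    return np.sqrt(_variances(theta, d, model.flexible, model.clip_floor))


def recalibrate_from_fit(
    uncertainties, fit: LinearFit, clip_floor: float = VARIANCE_FLOOR
) -> np.ndarray:
    """sigma_cal = slope_val * sigma + intercept_val, from a validation RMSE/RMV fit.

    Output sigmas that would be non-positive are floored at sqrt(clip_floor)
    so downstream metrics stay defined.
    """
    sig = np.asarray(uncertainties, dtype=float)
    out = fit.slope * sig + fit.intercept
    return np.maximum(out, np.sqrt(clip_floor))


def nll_minimizing_recalibration(uncertainties_val, errors_val) -> RecalibrationModel:
    """Linear map of sigma minimising the validation Gaussian NLL.

    The map acts on sigma (not variance): sigma_cal = slope*sigma + intercept,
    floored at sqrt(clip floor) inside the objective so the likelihood stays
    defined along the search path.
    """
    sig = np.asarray(uncertainties_val, dtype=float)
    e = np.asarray(errors_val, dtype=float)
    if sig.shape != e.shape:
        raise ValueError("uncertainties and errors must have equal length")
    if np.any(sig <= 0):
        raise ValueError("validation uncertainties must be strictly positive")
    err2 = e**2
    floor_sig = np.sqrt(VARIANCE_FLOOR)

    def objective(params):
        s = np.maximum(params[0] * sig + params[1], floor_sig)
        return _nll_of_var(s**2, err2)

    # moment guess: match overall scale, zero offset; plus fixed perturbations
    scale = float(np.sqrt(np.mean(err2)) / np.sqrt(np.mean(sig**2)))
    starts = [(scale, 0.0), (1.0, 0.0), (scale * 0.5, 0.1), (scale * 2.0, -0.1)]
    params, converged = _multistart_minimize(objective, starts)
    return RecalibrationModel(
        kind="nll_linear",
        slope=float(params[0]),
        intercept=float(params[1]),
        converged=converged,
    )
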