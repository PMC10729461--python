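"""Core data model for paired prediction errors and predicted uncertainties.

Every metric in this package operates on a :class:`UQDataset`: per-sample
signed errors ``eps_i = y_pred_i - y_true_i`` together with predicted
uncertainties ``sigma_i`` interpreted as standard deviations in the same
(property) units.  Uncertainties are standard deviations at every public
boundary; variances appear only inside likelihood computations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DatasetError",
    "UQDataset",
    "ZScores",
    "compute_errors",
    "load_table",
    "save_table",
]


class DatasetError(ValueError):
    """Raised when an input table or array pair violates the data model."""


def _as_1d_float(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise DatasetError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class UQDataset:
    """Paired per-sample errors and uncertainties, optionally with y values.

    Parameters
    ----------
    errors
        Signed prediction errors, ``y_pred - y_true``, in property units.
    uncertainties
        Predicted standard deviations, strictly positive, same units.
    y_true, y_pred
        Optional underlying values; when both are given they must be
        consistent with ``errors`` to representation precision.
    """

    errors: np.ndarray
    uncertainties: np.ndarray
    y_true: np.ndarray | None = None
    y_pred: np.ndarray | None = None

    def __post_init__(self):
        errors = _as_1d_float(self.errors, "errors")
        sigmas = _as_1d_float(self.uncertainties, "uncertainties")
        object.__setattr__(self, "errors", errors)
        object.__setattr__(self, "uncertainties", sigmas)
        if errors.shape != sigmas.shape:
            raise DatasetError(
                f"errors (n={errors.size}) and uncertainties (n={sigmas.size}) "
                "must have equal length"
            )
        if errors.size < 1:
            raise DatasetError("dataset must contain at least one sample")
        if not np.all(np.isfinite(errors)):
            bad = np.flatnonzero(~np.isfinite(errors))
            raise DatasetError(f"non-finite errors at rows {bad.tolist()}")
        if not np.all(np.isfinite(sigmas)) or np.any(sigmas <= 0):
            bad = np.flatnonzero(~(np.isfinite(sigmas) & (sigmas > 0)))
            raise DatasetError(
                f"uncertainties must be strictly positive and finite; "
                f"offending rows {bad.tolist()}"
            )
        if (self.y_true is None) != (self.y_pred is None):
            raise DatasetError("y_true and y_pred must be given together")
        if self.y_true is not None:
            yt = _as_1d_float(self.y_true, "y_true")
            yp = _as_1d_float(self.y_pred, "y_pred")
            object.__setattr__(self, "y_true", yt)
            object.__setattr__(self, "y_pred", yp)
            if yt.shape != errors.shape or yp.shape != errors.shape:
                raise DatasetError("y_true/y_pred length must match errors")
            if not np.array_equal(yp - yt, errors):
                raise DatasetError("errors must equal y_pred - y_true exactly")

    @property
    def n(self) -> int:
        return self.errors.size

    def absolute_errors(self) -> np.ndarray:
        """|eps_i|, derived on demand (never stored)."""
        return np.abs(self.errors)

    def z_scores(self) -> "ZScores":
        return z_scores(self)

    def subset(self, mask) -> "UQDataset":
        """Restrict to a boolean mask or index array (y columns carried along)."""
        idx = np.asarray(mask)
        kw = {}
        if self.y_true is not None:
            kw = {"y_true": self.y_true[idx], "y_pred": self.y_pred[idx]}
        return UQDataset(self.errors[idx], self.uncertainties[idx], **kw)

    def to_frame(self) -> pd.DataFrame:
        cols = {"error": self.errors, "uncertainty": self.uncertainties}
        if self.y_true is not None:
            cols["y_true"] = self.y_true
            cols["y_pred"] = self.y_pred
        return pd.DataFrame(cols)


@dataclass(frozen=True)
class ZScores:
    """Errors expressed as fractions of their predicted uncertainty."""

    values: np.ndarray = field()

    def __post_init__(self):
        vals = _as_1d_float(self.values, "values")
        if not np.all(np.isfinite(vals)):
            raise DatasetError("Z-scores must be finite")
        object.__setattr__(self, "values", vals)

    @property
    def n(self) -> int:
        return self.values.size


def compute_errors(y_true, y_pred) -> np.ndarray:
    """Signed errors ``y_pred - y_true`` (prediction minus truth)."""
    yt = _as_1d_float(y_true, "y_true")
    yp = _as_1d_float(y_pred, "y_pred")
    if yt.shape != yp.shape:
        raise DatasetError(
            f"length mismatch: y_true has {yt.size} entries, y_pred {yp.size}"
        )
    return yp - yt


def z_scores(data: UQDataset) -> ZScores:
    """Z_i = eps_i / sigma_i."""
    return ZScores(data.errors / data.uncertainties)


def load_table(
    path,
    error_col: str = "error",
    sigma_col: str = "uncertainty",
    y_true_col: str | None = None,
    y_pred_col: str | None = None,
) -> UQDataset:
    """Read a CSV table into a :class:`UQDataset`.

    Two column sets are accepted: ``(error_col, sigma_col)``, or
    ``(y_true_col, y_pred_col, sigma_col)`` from which errors are derived.
    The dialect is fixed: comma separated, header row required, '.' decimal
    separator.  Rows with a missing value in any mapped column are rejected
    and their indices reported in a warning.

    Raises
    ------
    DatasetError
        For a missing file, missing column, non-numeric cell or non-positive
        uncertainty, each reported with row/column context.
    """
    try:
        frame = pd.read_csv(path, float_precision="round_trip")
    except FileNotFoundError:
        raise DatasetError(f"no such file: {path}") from None

    use_y = y_true_col is not None or y_pred_col is not None
    if use_y and (y_true_col is None or y_pred_col is None):
        raise DatasetError("y_true_col and y_pred_col must be given together")
    needed = [y_true_col, y_pred_col, sigma_col] if use_y else [error_col, sigma_col]
    for col in needed:
        if col not in frame.columns:
            raise DatasetError(
                f"column {col!r} not found in {path} "
                f"(available: {list(frame.columns)})"
            )

    sub = frame[needed]
    numeric = sub.apply(pd.to_numeric, errors="coerce")
    bad_cells = numeric.isna() & sub.notna()
    if bad_cells.any().any():
        r, c = np.argwhere(bad_cells.to_numpy())[0]
        raise DatasetError(
            f"non-numeric value {sub.iat[r, c]!r} in column {needed[c]!r}, row {r}"
        )
    missing = numeric.isna().any(axis=1)
    if missing.any():
        rejected = np.flatnonzero(missing.to_numpy()).tolist()
        warnings.warn(
            f"rejected {len(rejected)} row(s) with missing values: {rejected}",
            stacklevel=2,
        )
        numeric = numeric[~missing]

    sig = numeric[sigma_col].to_numpy()
    nonpos = np.flatnonzero(~(np.isfinite(sig) & (sig > 0)))
    if nonpos.size:
        raise DatasetError(
            f"non-positive uncertainty in column {sigma_col!r} "
            f"at row(s) {nonpos.tolist()}"
        )
    if use_y:
        yt = numeric[y_true_col].to_numpy()
        yp = numeric[y_pred_col].to_numpy()
        return UQDataset(compute_errors(yt, yp), sig, y_true=yt, y_pred=yp)
    return UQDataset(numeric[error_col].to_numpy(), sig)


def save_table(data: UQDataset, path) -> None:
    """Write the dataset in the CSV dialect understood by :func:`load_table`."""
    data.to_frame().to_csv(path, index=False)
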