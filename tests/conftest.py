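import numpy as np
import pytest

from uqcal import (
    UQDataset,
    apply_error_scaling,
    sample_gaussian_errors,
    sigma_grid,
)


@pytest.fixture(scope="session")
def grid():
    """The default sigma grid, 0.5 to 10 in steps of 0.01 (951 values)."""
    return sigma_grid(0.5, 10.0, 0.01)


@pytest.fixture(scope="session")
def calibrated_grid(grid):
    """One calibrated error per sigma on the default grid."""
    return sample_gaussian_errors(grid, 1, seed=11)


@pytest.fixture(scope="session")
def mismatch_grid(calibrated_grid):
    """The scale-mismatch scenario: errors x1.25 below sigma=5, x0.8 above."""
    return apply_error_scaling(calibrated_grid, 5.0, 1.25, 0.8)


@pytest.fixture(scope="session")
def calibrated_large():
    """A larger calibrated set (20 full bins of 250) with a wide sigma range."""
    rng = np.random.default_rng(21)
    sig = rng.uniform(0.5, 10.0, size=5000)
    return UQDataset(errors=rng.normal(0.0, sig), uncertainties=sig)
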