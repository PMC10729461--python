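import numpy as np
import pytest

from uqcal import (
    LatentConfig,
    RecalibrationModel,
    apply_distance_variance,
    apply_error_scaling,
    error_based_calibration,
    fit_distance_variance,
    knn_latent_distance,
    nll_minimizing_recalibration,
    recalibrate_from_fit,
    sample_gaussian_errors,
    sigma_grid,
    spearman_rank,
)
from uqcal.binning import LinearFit


class TestKnnLatentDistance:
    def test_query_on_a_training_point(self):
        d = knn_latent_distance([[0.0, 0.0], [3.0, 4.0]], [[0.0, 0.0]], LatentConfig(k=1))
        assert d[0] == 0.0

    def test_mean_over_k_neighbors(self):
        d = knn_latent_distance([[0.0], [2.0]], [[1.0]], LatentConfig(k=2))
        assert d[0] == pytest.approx(1.0)

    def test_default_k_is_ten(self):
        assert LatentConfig().k == 10

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="dimension mismatch"):
            knn_latent_distance([[0.0, 1.0]], [[0.0]], LatentConfig(k=1))

    def test_k_exceeding_training_size(self):
        with pytest.raises(ValueError, match="exceeds"):
            knn_latent_distance([[0.0]], [[0.0]], LatentConfig(k=2))


class TestFitDistanceVariance:
    @pytest.mark.parametrize("flexible", [False, True])
    def test_constant_distance_recovers_single_group_mle(self, flexible):
        # with d constant the NLL optimum is V = mean(eps^2)
        rng = np.random.default_rng(1)
        e = rng.normal(0, 1.7, size=5000)
        model = fit_distance_variance(np.full(5000, 3.0), e, flexible=flexible)
        v = apply_distance_variance(model, [3.0])[0] ** 2
        assert v == pytest.approx(np.mean(e**2), rel=1e-3)

    def test_parameter_recovery_on_synthetic_data(self):
        rng = np.random.default_rng(2)
        n = 100_000
        d = rng.uniform(0.0, 5.0, size=n)
        e = rng.normal(0, np.sqrt(0.5 + 2.0 * d))
        model = fit_distance_variance(d, e, flexible=True)
        assert model.theta0 == pytest.approx(0.5, rel=0.05)
        assert model.theta1**2 == pytest.approx(2.0, rel=0.05)
        # fitting then applying reproduces the generating variances within 5%
        v = apply_distance_variance(model, d) ** 2
        assert np.all(np.abs(v - (0.5 + 2.0 * d)) / (0.5 + 2.0 * d) < 0.05)

    def test_negative_distances_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            fit_distance_variance([-1.0, 1.0], [0.1, 0.2])


class TestApplyDistanceVariance:
    def test_constant_variance_model(self):
        m = RecalibrationModel(kind="distance_variance", theta0=1.0, theta1=0.0)
        assert np.all(apply_distance_variance(m, [0.0, 5.0, 100.0]) == 1.0)

    def test_negative_variance_clipped_to_floor(self):
        m = RecalibrationModel(
            kind="distance_variance", theta0=-1.0, theta1=0.0, flexible=True
        )
        out = apply_distance_variance(m, [0.0, 7.0])
        assert np.all(out == pytest.approx(0.01))  # sqrt(0.0001)

    def test_linear_in_distance(self):
        m = RecalibrationModel(kind="distance_variance", theta0=0.0, theta1=1.0)
        assert apply_distance_variance(m, [4.0])[0] == pytest.approx(2.0)

    def test_wrong_model_kind(self):
        m = RecalibrationModel(kind="nll_linear", slope=1.0, intercept=0.0)
        with pytest.raises(ValueError, match="distance_variance"):
            apply_distance_variance(m, [1.0])


class TestRecalibrateFromFit:
    def test_identity_fit(self):
        fit = LinearFit(slope=1.0, intercept=0.0, r_squared=1.0)
        sig = np.array([0.3, 1.0, 2.5])
        assert np.array_equal(recalibrate_from_fit(sig, fit), sig)

    def test_affine_arithmetic(self):
        fit = LinearFit(slope=0.5, intercept=0.1, r_squared=1.0)
        assert recalibrate_from_fit([1.0], fit)[0] == pytest.approx(0.6)

    def test_non_positive_output_floored(self):
        fit = LinearFit(slope=1.0, intercept=-10.0, r_squared=1.0)
        assert recalibrate_from_fit([1.0], fit)[0] == pytest.approx(0.01)

    def test_rank_correlation_unchanged_by_positive_linear_map(self, calibrated_large):
        fit = LinearFit(slope=0.7, intercept=0.2, r_squared=1.0)
        sig_cal = recalibrate_from_fit(calibrated_large.uncertainties, fit)
        ae = calibrated_large.absolute_errors()
        assert spearman_rank(ae, sig_cal) == pytest.approx(
            spearman_rank(ae, calibrated_large.uncertainties)
        )

    def test_end_to_end_improves_scale_mismatch(self):
        # validation and test sets from the same miscalibrated generator:
        # after re-calibration the test-set fit moves toward (slope 1, b 0)
        grid = np.repeat(sigma_grid(0.5, 10.0, 0.01), 6)
        val = apply_error_scaling(
            sample_gaussian_errors(grid, 1, seed=31), 5.0, 1.25, 0.8
        )
        test = apply_error_scaling(
            sample_gaussian_errors(grid, 1, seed=32), 5.0, 1.25, 0.8
        )
        val_fit = error_based_calibration(val, bin_size=250).fit
        before = error_based_calibration(test, bin_size=250).fit

        from uqcal import UQDataset

        recal = UQDataset(
            errors=test.errors,
            uncertainties=recalibrate_from_fit(test.uncertainties, val_fit),
        )
        after = error_based_calibration(recal, bin_size=250).fit
        assert abs(after.slope - 1.0) < abs(before.slope - 1.0)
        assert abs(after.intercept) < abs(before.intercept)


class TestNllMinimizingRecalibration:
    def test_calibrated_data_yields_near_identity(self):
        rng = np.random.default_rng(3)
        sig = rng.uniform(0.5, 3.0, size=20_000)
        e = rng.normal(0, sig)
        m = nll_minimizing_recalibration(sig, e)
        assert m.slope == pytest.approx(1.0, abs=0.05)
        assert m.intercept == pytest.approx(0.0, abs=0.05)

    def test_halved_uncertainties_need_slope_two(self):
        rng = np.random.default_rng(4)
        sig = rng.uniform(0.5, 3.0, size=20_000)
        e = rng.normal(0, sig)
        m = nll_minimizing_recalibration(sig / 2, e)
        assert m.slope == pytest.approx(2.0, abs=0.1)
        assert m.intercept == pytest.approx(0.0, abs=0.05)

    def test_constant_sigma_maps_to_rmse(self):
        rng = np.random.default_rng(5)
        e = rng.normal(0, 1.3, size=10_000)
        m = nll_minimizing_recalibration(np.full(10_000, 0.4), e)
        rmse = np.sqrt(np.mean(e**2))
        assert m.apply([0.4])[0] == pytest.approx(rmse, rel=0.01)

    def test_emitted_uncertainties_strictly_positive(self):
        m = RecalibrationModel(kind="nll_linear", slope=-1.0, intercept=0.0)
        assert np.all(m.apply([0.5, 1.0, 10.0]) > 0)


class TestSerialization:
    @pytest.mark.parametrize(
        "model",
        [
            RecalibrationModel(kind="nll_linear", slope=1.5, intercept=-0.25),
            RecalibrationModel(
                kind="distance_variance", theta0=0.3, theta1=1.2, flexible=True
            ),
        ],
    )
    def test_text_round_trip(self, model, tmp_path):
        path = tmp_path / "model.txt"
        model.to_text(path)
        assert RecalibrationModel.from_text(path) == model

    def test_invalid_parameter_combinations_rejected(self):
        with pytest.raises(ValueError):
            RecalibrationModel(kind="nll_linear", theta0=1.0, theta1=1.0)
        with pytest.raises(ValueError):
            RecalibrationModel(kind="unknown", slope=1.0, intercept=0.0)
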