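"""Normalized Red, Porra conversion, calibration fit/validation, mapping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from phytocloud import (
    AbsorbancePair,
    CalibrationCurve,
    CalibrationSample,
    ColoredPointCloud,
    concentration_to_areal,
    fit_calibration,
    loocv_mae,
    map_chlorophyll,
    normalized_red,
    porra_total_chlorophyll,
)
from phytocloud.chlorophyll import (
    FLAG_OK,
    FLAG_OUT_OF_RANGE,
    FLAG_UNDEFINED_COLOR,
    kfold_mae,
)
from phytocloud.errors import (
    RankDeficiencyError,
    UndefinedColorError,
    ValidationError,
)


def brute_force_loocv(samples):
    """Independent n-refit oracle for leave-one-out MAE."""
    r = np.array([s.normalized_red for s in samples])
    c = np.array([s.chlorophyll for s in samples])
    errors = []
    for i in range(len(r)):
        mask = np.ones(len(r), dtype=bool)
        mask[i] = False
        fit = stats.linregress(r[mask], c[mask])
        errors.append(abs(c[i] - (fit.slope * r[i] + fit.intercept)))
    return float(np.mean(errors))


def _line_samples(slope, intercept, r_values, noise=None):
    chl = slope * np.asarray(r_values) + intercept
    if noise is not None:
        chl = chl + noise
    return [CalibrationSample(float(r), float(max(c, 0.0)))
            for r, c in zip(r_values, chl)]


class TestNormalizedRed:
    @pytest.mark.parametrize("rgb,expected", [
        ((255, 0, 0), 1.0),
        ((100, 100, 100), 1 / 3),
        ((120, 200, 80), 0.30),
    ])
    def test_values(self, rgb, expected):
        assert normalized_red(*rgb) == pytest.approx(expected)

    def test_black_is_undefined(self):
        with pytest.raises(UndefinedColorError):
            normalized_red(0, 0, 0)

    @given(
        r=st.integers(0, 85), g=st.integers(0, 85), b=st.integers(0, 85),
        k=st.integers(2, 3),
    )
    @settings(max_examples=100, deadline=None)
    def test_invariant_under_uniform_scaling(self, r, g, b, k):
        if r + g + b == 0:
            return
        assert normalized_red(k * r, k * g, k * b) == pytest.approx(
            normalized_red(r, g, b)
        )


class TestPorra:
    @pytest.mark.parametrize("a646,a663,expected", [
        (0.0, 0.0, 0.0),
        (1.0, 0.0, 17.76),
        (0.5, 0.5, 12.55),
    ])
    def test_total_chlorophyll(self, a646, a663, expected):
        assert porra_total_chlorophyll(
            AbsorbancePair(a646, a663)
        ) == pytest.approx(expected)

    def test_negative_absorbance_rejected(self):
        with pytest.raises(ValidationError):
            AbsorbancePair(-0.1, 0.2)

    @pytest.mark.parametrize("conc,vol,area,expected", [
        (10.0, 1.0, 10.0, 1.0),
        (0.0, 5.0, 3.0, 0.0),
        (17.76, 2.0, 28.27, 17.76 * 2 / 28.27),
    ])
    def test_areal_normalization(self, conc, vol, area, expected):
        assert concentration_to_areal(conc, vol, area) == pytest.approx(expected)

    def test_nonpositive_geometry_rejected(self):
        with pytest.raises(ValidationError):
            concentration_to_areal(1.0, 0.0, 1.0)


class TestFitCalibration:
    def test_noiseless_line(self):
        samples = _line_samples(-5.0, 6.0, [0.1, 0.3, 0.5, 0.7])
        curve = fit_calibration(samples)
        assert curve.slope == pytest.approx(-5.0)
        assert curve.intercept == pytest.approx(6.0)
        assert curve.r_squared == pytest.approx(1.0)

    def test_constant_response(self):
        samples = [CalibrationSample(r, 4.2) for r in (0.1, 0.2, 0.3)]
        curve = fit_calibration(samples)
        assert curve.slope == pytest.approx(0.0)
        assert curve.intercept == pytest.approx(4.2)
        assert curve.r_squared == 0.0

    def test_rank_deficiency(self):
        samples = [CalibrationSample(0.3, c) for c in (1.0, 2.0, 3.0)]
        with pytest.raises(RankDeficiencyError):
            fit_calibration(samples)

    def test_residuals_sum_to_zero_and_r2_identity(self, rng):
        r = rng.uniform(0.1, 0.9, 30)
        samples = _line_samples(-40.0, 22.0, r, noise=rng.normal(0, 1.0, 30))
        curve = fit_calibration(samples)
        assert abs(curve.residuals.sum()) < 1e-9
        c = np.array([s.chlorophyll for s in samples])
        sse = float(np.sum(curve.residuals**2))
        sst = float(np.sum((c - c.mean()) ** 2))
        assert curve.r_squared == pytest.approx(1 - sse / sst)

    def test_fitted_r2_in_sampling_band_of_population_target(self):
        """n=30 draws from a population-R²=0.81 scheme: the fitted R² must
        land inside the pre-computed 99% Monte-Carlo band [0.60, 0.93]."""
        from phytocloud.synthetic import make_calibration_samples

        for seed in range(5):
            curve = fit_calibration(
                make_calibration_samples(n=30, r_squared=0.81, seed=seed)
            )
            assert 0.60 <= curve.r_squared <= 0.93


class TestLoocv:
    def test_noiseless_line_gives_zero(self):
        samples = _line_samples(-5.0, 6.0, [0.1, 0.2, 0.3, 0.4, 0.5])
        assert loocv_mae(samples) == pytest.approx(0.0, abs=1e-10)

    def test_hand_computed_small_case(self):
        samples = [CalibrationSample(r, c) for r, c in
                   [(0.1, 1.0), (0.2, 2.0), (0.3, 3.0), (0.4, 5.0)]]
        # frozen from the explicit 4-refit oracle: mean(|2/3, 1/7, 4/7, 1|)
        assert loocv_mae(samples) == pytest.approx(0.5952380952380952)
        assert loocv_mae(samples) == pytest.approx(brute_force_loocv(samples))

    def test_equals_brute_force_oracle_on_random_sets(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 50))
            samples = _line_samples(
                -40.0, 22.0, rng.uniform(0.1, 0.6, n),
                noise=rng.normal(0, 1.5, n),
            )
            assert loocv_mae(samples) == pytest.approx(
                brute_force_loocv(samples), abs=1e-10
            )

    def test_kfold_deterministic(self, rng):
        samples = _line_samples(-40.0, 22.0, rng.uniform(0.1, 0.6, 30),
                                noise=rng.normal(0, 1.0, 30))
        assert kfold_mae(samples, seed=7) == kfold_mae(samples, seed=7)


class TestMapChlorophyll:
    def test_negative_prediction_kept_and_flagged(self):
        curve = CalibrationCurve(slope=-5.0, intercept=3.0, r_squared=1.0, n=3)
        cloud = ColoredPointCloud(points=[[0, 0, 0]], colors=[[255, 0, 0]])
        out = map_chlorophyll(cloud, curve)
        assert out.attributes["chlorophyll"][0] == pytest.approx(-2.0)
        assert out.attributes["chlorophyll_flag"][0] == FLAG_OUT_OF_RANGE

    def test_flat_curve_constant_map(self, rng):
        curve = CalibrationCurve(slope=0.0, intercept=7.5, r_squared=0.0, n=3)
        cloud = ColoredPointCloud(
            points=rng.normal(size=(20, 3)), colors=rng.integers(1, 255, (20, 3))
        )
        out = map_chlorophyll(cloud, curve)
        np.testing.assert_allclose(out.attributes["chlorophyll"], 7.5)
        np.testing.assert_array_equal(out.attributes["chlorophyll_flag"], FLAG_OK)

    def test_black_points_masked(self):
        curve = CalibrationCurve(slope=-5.0, intercept=3.0, r_squared=1.0, n=3)
        cloud = ColoredPointCloud(
            points=[[0, 0, 0], [1, 1, 1]], colors=[[0, 0, 0], [50, 120, 60]]
        )
        out = map_chlorophyll(cloud, curve)
        assert np.isnan(out.attributes["chlorophyll"][0])
        assert out.attributes["chlorophyll_flag"][0] == FLAG_UNDEFINED_COLOR
        assert np.isfinite(out.attributes["chlorophyll"][1])

    def test_round_trip_through_synthetic_coloring(self, design_curve):
        """Coloring a leaf from a known chlorophyll field via the inverted
        line, then mapping back, recovers the field to the 8-bit
        quantization bound."""
        from phytocloud.synthetic import LeafSpec, make_leaf

        spec = LeafSpec(label=1, noise_sigma=0.0, point_density=100.0)
        cloud, truth = make_leaf(spec, design_curve, seed=5)
        out = map_chlorophyll(cloud, design_curve)
        err = np.abs(out.attributes["chlorophyll"] - truth.chlorophyll)
        assert err.max() <= abs(design_curve.slope) / 765 + 1e-9
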