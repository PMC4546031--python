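"""Savitzky–Golay filters, normalizations, region selection, Dixon screen."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from atrigg import preprocess, simulate
from atrigg.preprocess import (
    PreprocessSpec,
    apply_pipeline,
    average_replicates,
    dixon_q,
    flag_outlier_replicates,
    savgol_derivative,
    savgol_smooth,
    select_regions,
    snv,
    vector_normalize,
)
from atrigg.spectra_io import WavenumberGrid


def local_polyfit_oracle(values, window, polyorder):
    """Brute-force Savitzky–Golay: sliding local least-squares polynomial."""
    half = window // 2
    n = values.size
    out = np.empty(n)
    for i in range(half, n - half):
        idx = np.arange(i - half, i + half + 1)
        coeffs = np.polynomial.polynomial.polyfit(idx - i, values[idx], polyorder)
        out[i] = coeffs[0]
    return out[half : n - half]


class TestSavgolSmooth:
    def test_constant_unchanged(self):
        x = np.full(20, 3.7)
        np.testing.assert_allclose(savgol_smooth(x), x)

    def test_quadratic_reproduced_exactly(self):
        t = np.arange(40.0)
        y = 3 * t**2 - t + 2
        out = savgol_smooth(y, window=9, polyorder=2)
        np.testing.assert_allclose(out[4:-4], y[4:-4], rtol=1e-10)

    def test_matches_sliding_local_regression_oracle(self, rng):
        y = rng.normal(size=60)
        out = savgol_smooth(y, window=9, polyorder=2)
        np.testing.assert_allclose(out[4:-4], local_polyfit_oracle(y, 9, 2), atol=1e-10)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            savgol_smooth(np.zeros(20), window=8)

    def test_window_larger_than_spectrum_rejected(self):
        with pytest.raises(ValueError):
            savgol_smooth(np.zeros(5), window=9)


class TestSavgolDerivative:
    """Derivatives are with respect to increasing wavenumber even though the
    canonical storage order is descending."""

    def test_constant_has_zero_first_derivative(self):
        out = savgol_derivative(np.full(30, 2.0), order=1, spacing=4.0)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_linear_in_wavenumber_recovers_slope(self, coarse_grid):
        a = 0.002
        y = a * coarse_grid.values
        out = savgol_derivative(y, order=1, spacing=coarse_grid.spacing)
        np.testing.assert_allclose(out[4:-4], a, rtol=1e-8)

    def test_quadratic_second_derivative(self, coarse_grid):
        a = 3e-6
        y = a * coarse_grid.values**2
        out = savgol_derivative(y, order=2, spacing=coarse_grid.spacing)
        np.testing.assert_allclose(out[4:-4], 2 * a, rtol=1e-8)

    def test_order_above_polyorder_rejected(self):
        with pytest.raises(ValueError):
            savgol_derivative(np.zeros(30), order=2, polyorder=1)


class TestNormalizations:
    def test_snv_small_example(self):
        np.testing.assert_allclose(snv(np.array([1.0, 2.0, 3.0])), [-1.0, 0.0, 1.0])

    def test_snv_idempotent(self, rng):
        x = rng.normal(size=50)
        once = snv(x)
        np.testing.assert_allclose(snv(once), once, atol=1e-12)

    def test_snv_constant_rejected(self):
        with pytest.raises(ValueError):
            snv(np.full(10, 1.0))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_snv_postcondition(self, seed):
        x = np.random.default_rng(seed).normal(size=30)
        out = snv(x)
        assert abs(out.mean()) < 1e-10
        assert abs(out.std(ddof=1) - 1.0) < 1e-10

    def test_vector_normalize_examples(self):
        np.testing.assert_allclose(vector_normalize(np.array([3.0, 4.0])), [0.6, 0.8])
        np.testing.assert_allclose(vector_normalize(np.array([-3.0, 4.0])), [-0.6, 0.8])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_vector_normalize_postcondition_and_idempotence(self, seed):
        x = np.random.default_rng(seed).normal(size=30)
        out = vector_normalize(x)
        assert abs(np.linalg.norm(out) - 1.0) < 1e-12
        np.testing.assert_allclose(vector_normalize(out), out, atol=1e-12)

    def test_vector_normalize_zero_rejected(self):
        with pytest.raises(ValueError):
            vector_normalize(np.zeros(5))


class TestSelectRegions:
    def test_full_span_region_is_identity(self, coarse_grid, rng):
        y = rng.normal(size=len(coarse_grid))
        sub, out = select_regions(coarse_grid, y, [(4000.0, 650.0)])
        assert np.array_equal(sub.values, coarse_grid.values)
        assert np.array_equal(out, y)

    def test_default_regions_match_enumeration_oracle(self, default_grid, rng):
        y = rng.normal(size=len(default_grid))
        sub, out = select_regions(default_grid, y)
        expected = sum(
            1
            for v in default_grid.values
            if 2600 <= v <= 3700 or 1300 <= v <= 1800
        )
        assert len(sub) == expected == out.size
        assert np.all(np.diff(sub.values) < 0)
        assert sub.values[0] <= 3700 and sub.values[-1] >= 1300

    def test_region_outside_grid_rejected(self, coarse_grid):
        with pytest.raises(ValueError):
            select_regions(coarse_grid, np.zeros(len(coarse_grid)), [(500.0, 100.0)])


class TestDixonQ:
    def test_moderate_extreme_not_flagged(self):
        q_low, q_high, idx = dixon_q([1, 2, 3, 4, 10])
        assert q_high == pytest.approx(6 / 9)
        assert idx is None  # 0.667 < 0.710

    def test_gross_extreme_flagged(self):
        values = [1, 2, 3, 4, 100]
        q_low, q_high, idx = dixon_q(values)
        assert q_high == pytest.approx(96 / 99)
        assert values[idx] == 100

    def test_low_end_outlier_flagged(self):
        values = [-100.0, 2, 3, 4, 5]
        _, _, idx = dixon_q(values)
        assert values[idx] == -100.0

    def test_zero_range_reports_no_outlier(self):
        q_low, q_high, idx = dixon_q([5, 5, 5, 5, 5])
        assert np.isnan(q_low) and np.isnan(q_high) and idx is None

    @pytest.mark.parametrize("n", [2, 8])
    def test_table_range_enforced(self, n):
        with pytest.raises(ValueError):
            dixon_q(list(range(n)))

    def test_critical_value_table_anchor(self):
        assert preprocess.DIXON_Q_CRITICAL[0.95][5] == 0.710


class TestReplicateScreen:
    def test_identical_replicates_all_retained(self):
        X = np.tile(np.linspace(0, 1, 40), (5, 1))
        report = flag_outlier_replicates(X)
        assert not report.excluded.any()
        np.testing.assert_array_equal(report.flagged_fraction, 0.0)

    def test_gross_offset_replicate_excluded(self, rng):
        X = rng.normal(0.2, 0.001, size=(5, 60))
        X[2] += 0.1  # 100x the noise SD
        report = flag_outlier_replicates(X)
        assert report.excluded.tolist() == [False, False, True, False, False]
        assert report.flagged_fraction[2] > 0.5

    def test_forty_percent_anomaly_not_excluded(self, rng):
        X = rng.normal(0.2, 0.001, size=(5, 100))
        X[1, :40] += 0.1  # anomalous at exactly 40% of points
        report = flag_outlier_replicates(X)
        assert report.flagged_fraction[1] == pytest.approx(0.40, abs=0.02)
        assert not report.excluded[1]

    def test_white_noise_calibration(self, rng):
        """Exchangeable replicates are flagged at roughly the test's false
        positive rate per point and never excluded."""
        fractions = []
        for _ in range(100):
            X = rng.normal(size=(5, 120))
            report = flag_outlier_replicates(X)
            assert not report.excluded.any()
            fractions.extend(report.flagged_fraction)
        assert np.mean(fractions) < 0.05

    def test_fewer_than_three_replicates_rejected(self):
        with pytest.raises(ValueError):
            flag_outlier_replicates(np.zeros((2, 10)))

    def test_fewer_than_two_survivors_rejected(self, rng):
        # with the default >50% rule at most one replicate can be excluded
        # (flag fractions sum to <= 1); drive the threshold down to exercise
        # the survivor guard
        X = rng.normal(0.0, 0.001, size=(5, 100))
        for rep, sl in zip(range(1, 5), np.array_split(np.arange(100), 4)):
            X[rep, sl] += 1.0
        spec = PreprocessSpec(outlier_point_fraction_threshold=0.2)
        with pytest.raises(ValueError, match="fewer than 2"):
            flag_outlier_replicates(X, spec)


class TestAveraging:
    def test_simple_mean(self):
        X = np.array([[0.0, 0.0, 0.0], [2.0, 2.0, 2.0]])
        np.testing.assert_allclose(average_replicates(X), [1.0, 1.0, 1.0])

    def test_mean_over_survivors_matches_brute_force(self, rng):
        X = rng.normal(0.2, 0.001, size=(5, 50))
        X[4] -= 0.2
        report = flag_outlier_replicates(X)
        assert report.excluded[4]
        np.testing.assert_allclose(average_replicates(X, report), X[:4].mean(axis=0))


class TestApplyPipeline:
    def test_identity_spec_returns_input(self, coarse_grid):
        base = np.linspace(0.05, 0.3, len(coarse_grid))
        X = np.tile(base, (5, 1))
        spec = PreprocessSpec(regions=((4000.0, 650.0),))
        result = apply_pipeline(X, coarse_grid, spec)
        np.testing.assert_allclose(result.values, base)
        assert not result.report.excluded.any()

    def test_snv_contract_holds_per_replicate_before_averaging(self, small_dataset):
        spec = PreprocessSpec(
            smoothing="savitzky_golay",
            normalization="snv",
            regions=((4000.0, 650.0),),
        )
        reps = small_dataset.spectra[0]
        result = apply_pipeline(reps, small_dataset.grid, spec)
        for row in result.replicates:
            assert abs(row.mean()) < 1e-10
            assert abs(row.std(ddof=1) - 1.0) < 1e-10

    def test_matches_manual_stage_composition(self, small_dataset):
        spec = PreprocessSpec(smoothing="savitzky_golay", normalization="snv")
        grid = small_dataset.grid
        reps = small_dataset.spectra[1]
        result = apply_pipeline(reps, grid, spec)

        manual = snv(savgol_smooth(reps, spec.window, spec.polyorder))
        subgrid, manual = select_regions(grid, manual, spec.regions)
        report = flag_outlier_replicates(manual, spec)
        expected = average_replicates(manual, report)
        np.testing.assert_allclose(result.values, expected, atol=1e-12)
        assert np.array_equal(result.grid.values, subgrid.values)

    def test_deterministic(self, small_dataset):
        spec = PreprocessSpec(derivative="first", normalization="vector")
        a = apply_pipeline(small_dataset.spectra[2], small_dataset.grid, spec)
        b = apply_pipeline(small_dataset.spectra[2], small_dataset.grid, spec)
        assert np.array_equal(a.values, b.values)


class TestPreprocessSpecValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"window": 8},
            {"window": 3, "polyorder": 2},
            {"smoothing": "savitzky_golay", "derivative": "first"},
            {"regions": ((1300.0, 1800.0),)},
            {"regions": ((3700.0, 1500.0), (1800.0, 1300.0))},
            {"outlier_confidence": 1.5},
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            PreprocessSpec(**kwargs)

    def test_dict_round_trip(self):
        spec = PreprocessSpec(derivative="second", normalization="snv")
        assert PreprocessSpec.from_dict(spec.to_dict()) == spec
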