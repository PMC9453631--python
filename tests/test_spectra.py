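"""Wavelength grids, frame averaging, white/dark calibration, cropping."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import drsmargin as dm
from drsmargin.errors import (
    ConfigError,
    GridAlignmentError,
    GridMismatchError,
    InsufficientFramesError,
    UnusableCalibrationError,
)

from conftest import make_reflectance_dataset


def _frames(grid, arrays, site="siteA"):
    return [
        dm.Spectrum(
            grid, a, "raw_frame",
            dm.SpectrumMeta(site_id=site, timestamp_s=float(i)),
        )
        for i, a in enumerate(arrays)
    ]


class TestWavelengthGrid:
    @given(
        start=st.floats(200, 900),
        step=st.sampled_from([0.1, 0.25, 0.5, 1.0, 2.0]),
        n=st.integers(1, 2000),
    )
    @settings(max_examples=100, deadline=None)
    def test_sample_count_matches_enumeration(self, start, step, n):
        """Inclusive-endpoint count agrees with explicit point enumeration."""
        grid = dm.WavelengthGrid(start, start + n * step, step)
        enumerated = np.arange(n + 1) * step + start
        assert grid.n_samples == len(enumerated)
        np.testing.assert_allclose(grid.wavelengths(), enumerated, atol=1e-9)

    @pytest.mark.parametrize(
        "args", [(700, 500, 0.5), (500, 700, -1.0), (500, 700.3, 0.5)]
    )
    def test_invalid_grids_rejected(self, args):
        with pytest.raises(ConfigError):
            dm.WavelengthGrid(*args)

    def test_off_grid_wavelength_rejected(self, analysis_grid):
        with pytest.raises(GridAlignmentError):
            analysis_grid.index_of(468.3)


class TestAverageFrames:
    def test_identical_frames_mean(self, analysis_grid):
        frames = _frames(analysis_grid, [np.full(505, 7.0)] * 20)
        out = dm.average_frames(frames)
        assert out.kind == "site_mean"
        np.testing.assert_array_equal(out.intensities, 7.0)

    def test_alternating_constants(self, analysis_grid):
        arrays = [np.full(505, 0.0), np.full(505, 2.0)] * 10
        out = dm.average_frames(_frames(analysis_grid, arrays))
        np.testing.assert_allclose(out.intensities, 1.0)

    def test_uses_first_n_in_timestamp_order(self, analysis_grid):
        # 25 frames; frames 20..24 carry a huge value that must be ignored
        arrays = [np.full(505, 1.0)] * 20 + [np.full(505, 100.0)] * 5
        out = dm.average_frames(_frames(analysis_grid, arrays), n_required=20)
        np.testing.assert_allclose(out.intensities, 1.0)

    def test_errors(self, analysis_grid, full_grid):
        with pytest.raises(InsufficientFramesError, match="siteA"):
            dm.average_frames(_frames(analysis_grid, [np.zeros(505)] * 5))
        mixed = _frames(analysis_grid, [np.zeros(505)] * 19) + _frames(
            full_grid, [np.zeros(full_grid.n_samples)]
        )
        with pytest.raises(GridMismatchError):
            dm.average_frames(mixed)

    def test_standard_error_of_mean(self, analysis_grid):
        """Across 1000 regenerations of 20 noisy frames, the site mean
        behaves like N(mu, sigma^2/20): matching SD and 4-SE tail mass."""
        rng = np.random.default_rng(42)
        mu = 0.5 + 0.1 * np.sin(analysis_grid.wavelengths() / 30.0)
        sigma = 0.05
        draws = rng.normal(mu, sigma, size=(1000, 20, 505)).mean(axis=1)
        dev = draws - mu
        se = sigma / np.sqrt(20)
        assert abs(dev.std() / se - 1.0) < 0.1
        assert np.mean(np.abs(dev) > 4 * se) < 5e-4


class TestCalibrate:
    def test_identities(self, full_grid, flat_calibration):
        cal = flat_calibration
        w, d = cal.white.intensities, cal.dark.intensities
        for raw, expected in [(w, 1.0), (d, 0.0), ((w + d) / 2, 0.5)]:
            out = dm.calibrate(dm.Spectrum(full_grid, raw.copy()), cal)
            assert out.kind == "reflectance"
            np.testing.assert_allclose(out.intensities, expected, atol=1e-12)

    def test_affine_invariance(self, full_grid):
        rng = np.random.default_rng(0)
        n = full_grid.n_samples
        d = rng.uniform(50, 150, n)
        w = d + rng.uniform(500, 2000, n)
        s = d + rng.uniform(0, 1, n) * (w - d)
        a, b = 3.7, 250.0
        base = dm.calibrate(
            dm.Spectrum(full_grid, s),
            dm.CalibrationPair(dm.Spectrum(full_grid, w), dm.Spectrum(full_grid, d)),
        )
        scaled = dm.calibrate(
            dm.Spectrum(full_grid, a * s + b),
            dm.CalibrationPair(
                dm.Spectrum(full_grid, a * w + b), dm.Spectrum(full_grid, a * d + b)
            ),
        )
        np.testing.assert_allclose(
            scaled.intensities, base.intensities, atol=1e-12
        )

    def test_white_below_dark_rejected(self, full_grid):
        w = np.full(full_grid.n_samples, 100.0)
        d = np.full(full_grid.n_samples, 150.0)
        with pytest.raises(dm.errors.CalibrationError):
            dm.CalibrationPair(dm.Spectrum(full_grid, w), dm.Spectrum(full_grid, d))

    def test_denominator_floor_masks(self, full_grid):
        n = full_grid.n_samples
        d = np.full(n, 100.0)
        w = d + 1000.0
        w[:10] = d[:10] + 0.01  # sensitivity edge: below 1e-3 * 1000
        cal = dm.CalibrationPair(dm.Spectrum(full_grid, w), dm.Spectrum(full_grid, d))
        out = dm.calibrate(dm.Spectrum(full_grid, d + 500.0), cal)
        assert out.mask is not None
        assert not out.mask[:10].any() and out.mask[10:].all()
        np.testing.assert_array_equal(out.intensities[:10], 0.0)

    def test_unusable_calibration(self, full_grid):
        flat = np.full(full_grid.n_samples, 100.0)
        cal = dm.CalibrationPair(
            dm.Spectrum(full_grid, flat), dm.Spectrum(full_grid, flat.copy())
        )
        with pytest.raises(UnusableCalibrationError):
            dm.calibrate(dm.Spectrum(full_grid, flat), cal)

    def test_clipping(self, full_grid, flat_calibration):
        hot = np.full(full_grid.n_samples, 1e5)
        out = dm.calibrate(dm.Spectrum(full_grid, hot), flat_calibration)
        assert out.intensities.max() == 2.0

    def test_commutes_with_averaging(self, full_grid, flat_calibration):
        """Constant white/dark: calibrating the mean equals the mean of the
        calibrated frames, to numerical precision."""
        rng = np.random.default_rng(1)
        arrays = [
            100.0 + 900.0 * rng.uniform(0.1, 0.9, full_grid.n_samples)
            for _ in range(20)
        ]
        mean_then_cal = dm.calibrate(
            dm.average_frames(_frames(full_grid, arrays)), flat_calibration
        )
        cal_then_mean = np.mean(
            [
                dm.calibrate(f, flat_calibration).intensities
                for f in _frames(full_grid, arrays)
            ],
            axis=0,
        )
        np.testing.assert_allclose(
            mean_then_cal.intensities, cal_then_mean, atol=1e-12
        )


class TestCrop:
    def test_paper_analysis_range(self, full_grid):
        s = dm.Spectrum(full_grid, np.arange(full_grid.n_samples, dtype=float),
                        "reflectance")
        out = dm.crop_to_analysis_range(s)
        assert out.grid.n_samples == 505
        assert out.wavelengths[0] == 468.0 and out.wavelengths[-1] == 720.0
        # values carried over, not interpolated
        np.testing.assert_array_equal(
            out.intensities, s.intensities[full_grid.index_of(468.0):][:505]
        )

    def test_identity_and_small_crop(self, full_grid):
        s = dm.Spectrum(full_grid, np.ones(full_grid.n_samples))
        same = dm.crop_to_analysis_range(s, 420.0, 1000.0)
        assert same.grid == full_grid
        small = dm.crop_to_analysis_range(s, 468.0, 470.0)
        assert small.grid.n_samples == 5

    def test_idempotent(self, full_grid):
        s = dm.Spectrum(full_grid, np.ones(full_grid.n_samples))
        once = dm.crop_to_analysis_range(s)
        twice = dm.crop_to_analysis_range(once)
        assert once.grid == twice.grid
        np.testing.assert_array_equal(once.intensities, twice.intensities)

    def test_off_grid_bound_raises(self, full_grid):
        s = dm.Spectrum(full_grid, np.ones(full_grid.n_samples))
        with pytest.raises(GridAlignmentError):
            dm.crop_to_analysis_range(s, 468.2, 720.0)


class TestValidateDataset:
    def _ds(self, n_normal, n_tumor):
        vals = np.full((n_normal + n_tumor, 505), 0.5)
        classes = ["normal"] * n_normal + ["tumor"] * n_tumor
        return make_reflectance_dataset(vals, classes=classes)

    def test_protocol_minimum_met(self):
        assert dm.validate_dataset(self._ds(200, 200)).ok

    def test_missing_class_flagged(self):
        rep = dm.validate_dataset(self._ds(200, 0))
        assert rep.flagged == ["tumor"] and rep.counts["tumor"] == 0

    def test_boundary(self):
        assert dm.validate_dataset(self._ds(199, 200)).flagged == ["normal"]


class TestIO:
    def test_dataset_roundtrip_bit_exact(self, tmp_path):
        rng = np.random.default_rng(3)
        ds = make_reflectance_dataset(rng.random((7, 505)))
        path = tmp_path / "ds.csv"
        dm.spectra.dataset_to_csv(ds, path)
        back = dm.spectra.dataset_from_csv(path)
        np.testing.assert_array_equal(back.intensities, ds.intensities)
        pd.testing.assert_frame_equal(back.meta, ds.meta)
        assert back.kind == ds.kind and back.grid == ds.grid

    def test_calibration_roundtrip(self, tmp_path, flat_calibration):
        path = tmp_path / "cal.csv"
        dm.spectra.calibration_to_csv(flat_calibration, path)
        back = dm.spectra.calibration_from_csv(path)
        np.testing.assert_array_equal(
            back.white.intensities, flat_calibration.white.intensities
        )
        assert back.grid == flat_calibration.grid
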