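"""KDE frequency plots and the four histogram characteristics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from imflow import (
    FluorImage,
    KDEParams,
    kde_curve,
    random_crop,
    relative_changes,
    summarize_histogram,
    to_8bit,
)
from imflow.histograms import (
    DegenerateSampleError,
    silverman_bandwidth,
    summaries_to_frame,
)


class TestTo8Bit:
    @pytest.mark.parametrize("value,expected", [(1.0, 255.0), (0.0, 0.0), (0.5, 127.5)])
    def test_multiplies_by_255_without_rounding(self, value, expected):
        assert to_8bit(np.array([value]))[0] == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            to_8bit(np.array([1.2]))


class TestRandomCrop:
    def _image(self, h, w):
        return FluorImage(np.random.default_rng(0).uniform(0, 1, (h, w)), 0.37, "other", "x")

    def test_exact_size_image_returns_full_frame(self, rng):
        image = self._image(750, 1000)
        crop = random_crop(image, rng, 1000, 750)
        np.testing.assert_array_equal(crop.pixels, image.pixels)

    def test_deterministic_for_fixed_seed(self):
        image = self._image(900, 1200)
        a = random_crop(image, np.random.default_rng(4), 1000, 750)
        b = random_crop(image, np.random.default_rng(4), 1000, 750)
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_too_small_image_rejected(self, rng):
        with pytest.raises(ValueError, match="smaller"):
            random_crop(self._image(700, 900), rng, 1000, 750)

    def test_corners_uniform_over_valid_grid(self):
        # chi-square over a coarse partition of the 21x11 corner grid
        image = self._image(760, 1020)
        rng = np.random.default_rng(99)
        corners = np.array(
            [
                random_crop(image, rng, 1000, 750).image_id.split("crop")[1].split("_")
                for _ in range(4000)
            ],
            dtype=int,
        )
        from scipy.stats import chisquare

        counts = np.bincount(corners[:, 0] * 21 + corners[:, 1], minlength=11 * 21)
        assert chisquare(counts).pvalue > 1e-3


class TestKDECurve:
    def test_zero_variance_is_degenerate(self):
        with pytest.raises(DegenerateSampleError):
            kde_curve(np.full(50, 100.0))

    def test_single_value_is_degenerate(self):
        with pytest.raises(DegenerateSampleError):
            kde_curve(np.array([1.0]))

    def test_symmetric_sample_gives_symmetric_density(self):
        grid, density = kde_curve(np.array([50.0, 150.0]))
        np.testing.assert_allclose(density, density[::-1], rtol=1e-10)
        assert abs(grid[np.argmax(density)] + grid[len(grid) - 1 - np.argmax(density)] - 200) < 1e-9

    def test_density_integrates_to_one(self, rng):
        values = rng.normal(128, 20, 2000)
        grid, density = kde_curve(values)
        assert density.min() >= 0
        assert abs(np.trapezoid(density, grid) - 1.0) < 0.01

    def test_peak_recovers_location_of_normal_sample(self):
        values = np.random.default_rng(17).normal(128, 20, 10000)
        grid, density = kde_curve(values)
        assert abs(grid[np.argmax(density)] - 128) < 2.0


class TestSummarizeHistogram:
    def test_mean_median_from_raw_sample(self):
        summary = summarize_histogram(np.array([1.0, 2.0, 3.0]))
        assert summary.mean_8bit == 2.0
        assert summary.median_8bit == 2.0
        assert summary.n_cells == 3

    def test_fwhm_matches_gaussian_closed_form(self):
        # a Gaussian KDE of Gaussian data is Normal(mu, sigma^2 + h^2)
        sigma = 15.0
        values = np.random.default_rng(23).normal(128, sigma, 20000)
        h = silverman_bandwidth(values)
        summary = summarize_histogram(values)
        expected = 2.3548 * np.sqrt(sigma**2 + h**2)
        assert abs(summary.fwhm_8bit - expected) / expected < 0.03

    def test_outlier_of_negligible_mass_ignored_by_fwhm(self):
        rng = np.random.default_rng(31)
        cluster = rng.normal(100, 2.0, 5000)
        values = np.concatenate([cluster, [250.0]])
        summary = summarize_histogram(values)
        h = silverman_bandwidth(values)
        expected = 2.3548 * np.sqrt(4.0 + h**2)
        assert abs(summary.fwhm_8bit - expected) / expected < 0.05
        assert abs(summary.peak_8bit - 100) < 1.0

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(
        scale=st.floats(0.2, 1.0),
        shift=st.floats(0.0, 50.0),
    )
    def test_scale_and_shift_equivariance(self, scale, shift):
        values = np.random.default_rng(5).normal(120, 18, 800)
        base = summarize_histogram(values)
        scaled = summarize_histogram(values * scale)
        assert abs(scaled.peak_8bit - scale * base.peak_8bit) < 1e-6 * 255
        assert abs(scaled.fwhm_8bit - scale * base.fwhm_8bit) < 1e-6 * 255
        assert abs(scaled.mean_8bit - scale * base.mean_8bit) < 1e-9
        grid_step = (values.max() - values.min() + 6) / 512
        shifted = summarize_histogram(values + shift)
        assert abs(shifted.peak_8bit - (base.peak_8bit + shift)) < grid_step
        assert abs(shifted.fwhm_8bit - base.fwhm_8bit) < grid_step
        assert abs(shifted.mean_8bit - (base.mean_8bit + shift)) < 1e-9
        assert abs(shifted.median_8bit - (base.median_8bit + shift)) < 1e-9


class TestRelativeChanges:
    def _summaries(self, control_mean=100.0, group_mean=120.0):
        rng = np.random.default_rng(2)
        return [
            summarize_histogram(
                rng.normal(control_mean, 10, 500), group="control", modality="imaging"
            ),
            summarize_histogram(
                rng.normal(group_mean, 10, 500), group="treated", modality="imaging"
            ),
        ]

    def test_control_vs_itself_is_zero(self):
        summaries = self._summaries()
        summaries[1] = summarize_histogram(
            np.random.default_rng(2).normal(100, 10, 500),
            group="treated",
            modality="imaging",
        )
        # identical sample -> identical summary -> 0% on every metric
        summaries[1].peak_8bit = summaries[0].peak_8bit
        summaries[1].fwhm_8bit = summaries[0].fwhm_8bit
        summaries[1].mean_8bit = summaries[0].mean_8bit
        summaries[1].median_8bit = summaries[0].median_8bit
        rel = relative_changes(summaries, "control", "imaging")
        np.testing.assert_allclose(rel["rel_change_pct"], 0.0)

    def test_mean_arithmetic(self):
        rel = relative_changes(self._summaries(100.0, 120.0), "control", "imaging")
        mean_row = rel[rel["metric"] == "mean"].iloc[0]
        control_mean = self._summaries()[0].mean_8bit
        treated_mean = self._summaries()[1].mean_8bit
        expected = 100 * (treated_mean - control_mean) / control_mean
        assert abs(mean_row["rel_change_pct"] - expected) < 1e-9

    def test_missing_control_raises(self):
        with pytest.raises(ValueError, match="control"):
            relative_changes(self._summaries(), "mock", "imaging")

    def test_frame_input_equivalent_to_summary_list(self):
        summaries = self._summaries()
        a = relative_changes(summaries, "control", "imaging")
        b = relative_changes(summaries_to_frame(summaries), "control", "imaging")
        assert a.equals(b)
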