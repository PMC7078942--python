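"""Peak detection, Gaussian fitting, FWHM, separations, PVDR and trends."""

import numpy as np
import pytest

import microslit as ms
from microslit import frames as fr
from microslit import profiles as pr
from microslit import simulator as sim
from .conftest import make_geometry, render_dose_image


def gaussian_profile_image(centers_um, pitch=50.0, sigma=80.0, amp=50.0, base=2.0, n=None):
    """A few-row image whose rows each hold the same sum of Gaussians."""
    n = n or int((max(centers_um) + 600) / pitch)
    x = (np.arange(n) + 0.5) * pitch
    row = base + sum(amp * np.exp(-0.5 * ((x - c) / sigma) ** 2) for c in centers_um)
    return fr.DoseImage(np.tile(row, (4, 1)).T, pitch, 1.0)  # (n, 4): peaks along rows


class TestExtractProfile:
    def test_single_lane_band_is_that_lane(self):
        img = fr.DoseImage(np.arange(12.0).reshape(3, 4), 50.0, 1.0)
        p = pr.extract_profile(img, "rows", (1, 2))
        assert np.array_equal(p.values, img.dose_rate[:, 1])
        assert p.positions_um == pytest.approx((np.arange(3) + 0.5) * 50.0)

    def test_uniform_image_gives_constant_profile(self):
        img = fr.DoseImage(np.full((5, 5), 7.0), 10.0, 1.0)
        assert np.all(pr.extract_profile(img).values == 7.0)

    def test_cols_axis_transposes(self):
        img = fr.DoseImage(np.arange(12.0).reshape(3, 4), 50.0, 1.0)
        p = pr.extract_profile(img, "cols", (0, 3))
        assert p.values == pytest.approx(img.dose_rate.mean(axis=0))

    def test_band_outside_image_rejected(self):
        img = fr.DoseImage(np.zeros((3, 4)), 50.0, 1.0)
        with pytest.raises(ValueError):
            pr.extract_profile(img, "rows", (2, 9))

    def test_band_average_matches_continuous_field(self, geom_w100, collimator):
        f = ms.build_field(geom_w100, collimator, 60.0, projected_separation_um=512.0)
        img = sim.render_expected_dose_rate(f, 60, 8, 50.0)
        p = pr.extract_profile(fr.DoseImage(img, 50.0, 1.0), "rows", (2, 6))
        # oracle: average the continuous field over the same band, fine grid
        y0 = -60 * 50.0 / 2
        fine = []
        for i in range(60):
            ys = y0 + i * 50.0 + np.linspace(2.5, 47.5, 10)
            xs = -8 * 50.0 / 2 + 2 * 50.0 + np.linspace(2.5, 197.5, 40)
            fine.append(f(ys[:, None], xs[None, :]).mean())
        # abs slack covers quadrature error where a pixel straddles a profile kink
        assert p.values == pytest.approx(np.array(fine), rel=0.01, abs=0.05)


class TestDetectPeaks:
    def test_flat_profile_gives_empty_list(self):
        p = pr.Profile(np.arange(10.0) * 50, np.full(10, 3.0))
        assert pr.detect_peaks(p, 512.0).size == 0

    def test_two_gaussians_at_512_found_within_one_sample(self):
        img = gaussian_profile_image([1000.0, 1512.0])
        p = pr.extract_profile(img, "rows", (0, 4))
        pos = pr.detect_peaks(p, 512.0, 0.1)
        assert len(pos) == 2
        assert pos == pytest.approx([1000.0, 1512.0], abs=50.0)

    def test_minimum_spacing_keeps_more_prominent(self):
        x = (np.arange(60) + 0.5) * 50.0
        v = 10 * np.exp(-0.5 * ((x - 1500) / 60) ** 2)
        v += 4 * np.exp(-0.5 * ((x - 1650) / 60) ** 2)  # shoulder closer than 256 µm
        pos = pr.detect_peaks(pr.Profile(x, v), 512.0, 0.05)
        assert len(pos) == 1
        assert abs(pos[0] - 1500) < 60

    def test_closed_collimator_leakage_field_all_slits_detected(
        self, collimator, small_detector
    ):
        dose = render_dose_image(
            make_geometry(0.0), collimator, small_detector, seed=77, peak_dose_rate=6.0
        )
        p = pr.extract_profile(dose, "rows", (30, 130))
        assert len(pr.detect_peaks(p, 512.0, 0.1)) == 51

    def test_separation_must_exceed_sampling(self):
        p = pr.Profile(np.arange(10.0) * 50, np.arange(10.0))
        with pytest.raises(ValueError):
            pr.detect_peaks(p, 80.0)


class TestFitPeak:
    @pytest.mark.parametrize("sigma,expected", [(80.0, 188.3856), (10.0, 23.5482)])
    def test_noise_free_gaussian_closed_form(self, sigma, expected):
        x = np.arange(-400.0, 400.0, 5.0)
        p = pr.Profile(x, 2.0 + 5.0 * np.exp(-0.5 * (x / sigma) ** 2))
        fit = pr.fit_peak(p, 0.0, 300.0)
        assert fit.fwhm_um == pytest.approx(expected, abs=1e-3)
        assert fit.converged
        assert fit.fwhm_um / fit.sigma_um == pytest.approx(2.3548200450, abs=1e-9)

    def test_trapezoid_gaussian_bias_pinned(self, geom_w100):
        # Gaussian fit of the a=132.1 / b=128.3 trapezoid, 10 µm sampling:
        # the approximation overshoots the true 132.1 µm FWHM by ~4.6%
        x = np.arange(-400.0, 400.0, 10.0)
        p = pr.Profile(x, ms.exact_penumbra_profile(geom_w100, x))
        fit = pr.fit_peak(p, 0.0, 250.0)
        assert fit.fwhm_um == pytest.approx(138.1, abs=0.5)  # regression value
        assert abs(fit.fwhm_um / ms.trapezoid_fwhm(geom_w100) - 1) < 0.05
        # the direct crossing estimate is far closer to the trapezoid truth
        assert fit.fwhm_crossing_um == pytest.approx(ms.trapezoid_fwhm(geom_w100), rel=0.02)

    def test_too_few_samples_rejected(self):
        x = np.arange(0.0, 200.0, 50.0)
        with pytest.raises(ValueError):
            pr.fit_peak(pr.Profile(x, np.ones_like(x)), 100.0, 80.0)

    def test_hopeless_fit_returns_flagged_not_silent(self):
        x = np.arange(0.0, 500.0, 50.0)
        p = pr.Profile(x, np.full_like(x, 3.0))  # no peak at all
        fit = pr.fit_peak(p, 250.0, 250.0)
        assert not fit.converged


class TestValleysAndPVDR:
    def test_pvdr_arithmetic(self):
        peaks = [
            pr.PeakFit(0.0, 50.0, 95.0, 5.0, 0.0),
            pr.PeakFit(512.0, 50.0, 95.0, 5.0, 0.0),
        ]
        per_peak, mean = pr.pvdr(peaks, np.array([5.0]))
        assert per_peak == pytest.approx([20.0, 20.0])
        assert mean == pytest.approx(20.0)

    def test_valley_equal_to_peak_gives_unity(self):
        peaks = [pr.PeakFit(0.0, 50.0, 0.0, 7.0, 0.0), pr.PeakFit(512.0, 50.0, 0.0, 7.0, 0.0)]
        _, mean = pr.pvdr(peaks, np.array([7.0]))
        assert mean == pytest.approx(1.0)

    def test_nonpositive_valley_flags_nan(self):
        peaks = [pr.PeakFit(0.0, 50.0, 95.0, 5.0, 0.0), pr.PeakFit(512.0, 50.0, 95.0, 5.0, 0.0)]
        per_peak, mean = pr.pvdr(peaks, np.array([0.0]))
        assert np.all(np.isnan(per_peak)) and np.isnan(mean)

    def test_valley_levels_centre_of_gap(self):
        x = (np.arange(40) + 0.5) * 50.0
        v = np.where(np.abs(x - 1000) < 120, 100.0, 0.0) + np.where(
            np.abs(x - 1512) < 120, 100.0, 0.0
        )
        v[(x > 1050) & (x < 1150)] = 7.0  # clutter outside the central 20%
        levels = pr.valley_levels(pr.Profile(x, v), [1000.0, 1512.0], valley_fraction=0.2)
        assert levels == pytest.approx([0.0])

    def test_pvdr_against_continuous_field_oracle(self, collimator, small_detector):
        # fully open slits over a 5% leakage floor, no noise
        geom = make_geometry(100.0)
        coll = ms.CollimatorSpec(leakage_fraction=0.05, hole_diameter_mm=0.0)
        f = ms.build_field(geom, coll, 60.0, projected_separation_um=512.0)
        img = sim.render_expected_dose_rate(f, 620, 8, 50.0)
        an = pr.analyze_field(
            fr.DoseImage(img, 50.0, 1.0),
            coll,
            pr.AnalysisConfig(expected_separation_um=512.0, band=(0, 8)),
        )
        # oracle: continuous-field peak (pixel-averaged) over leakage valley
        tip = f(np.linspace(-25.0, 25.0, 201), np.array([0.0])).mean()
        oracle = tip / (coll.leakage_fraction * f.scale)
        assert an.pvdr_mean == pytest.approx(oracle, rel=0.03)


class TestFwhmTrend:
    def test_constant_fwhm_gives_zero_slope(self):
        slope, intercept, r2 = pr.fwhm_trend(np.array([0.0, 1000, 2000]), np.array([130.0] * 3))
        assert slope == pytest.approx(0.0, abs=1e-12)
        assert intercept == pytest.approx(130.0)

    def test_two_points_exact_interpolation(self):
        slope, intercept, _ = pr.fwhm_trend(np.array([0.0, 2000.0]), np.array([130.0, 134.0]))
        assert slope == pytest.approx(2.0)  # µm per mm
        assert intercept == pytest.approx(130.0)

    def test_simulated_heel_gradient_recovered(self, small_detector):
        coll = ms.CollimatorSpec(heel_gradient_per_mm=0.015)
        dose = render_dose_image(make_geometry(25.0), coll, small_detector, seed=55)
        an = pr.analyze_field(
            dose, coll, pr.AnalysisConfig(expected_separation_um=512.0, band=(30, 130))
        )
        recovered = an.fwhm_trend_slope_um_per_mm / an.fwhm_trend_intercept_um
        assert recovered == pytest.approx(0.015, rel=0.1)


class TestAnalyzeField:
    def test_round_trip_noise_free_separation(self, geom_w100, collimator):
        f = ms.build_field(geom_w100, collimator, 60.0, projected_separation_um=512.0)
        img = sim.render_expected_dose_rate(f, 620, 8, 50.0)
        an = pr.analyze_field(
            fr.DoseImage(img, 50.0, 1.0),
            collimator,
            pr.AnalysisConfig(expected_separation_um=512.0, band=(0, 8)),
        )
        assert len(an.peaks) == 51
        assert an.separation_mean_um == pytest.approx(512.0, abs=0.5)
        assert an.separation_sd_um < 1.0

    def test_heel_zero_fwhm_uniform(self, analysis_w50):
        vals = analysis_w50.fwhm_crossing_um
        assert np.nanstd(vals) / np.nanmean(vals) < 0.02

    def test_central_peak_index_is_26(self, analysis_w50):
        assert analysis_w50.peaks[analysis_w50.central_index].peak_index == 26
        assert analysis_w50.aligned_centers_um[analysis_w50.central_index] == 0.0

    def test_indexing_invariant_under_profile_reversal(self, dose_image_w50, collimator):
        flipped = fr.DoseImage(
            dose_image_w50.dose_rate[::-1].copy(),
            dose_image_w50.sample_pitch_um,
            dose_image_w50.calibration_gain,
        )
        cfg = pr.AnalysisConfig(expected_separation_um=512.0, band=(30, 130))
        a = pr.analyze_field(dose_image_w50, collimator, cfg)
        b = pr.analyze_field(flipped, collimator, cfg)
        assert a.peaks[a.central_index].peak_index == b.peaks[b.central_index].peak_index == 26

    def test_sample_sd_uses_n_minus_1(self):
        centers = [500.0, 1012.0, 1526.0, 2036.0]  # separations 512, 514, 510
        img = gaussian_profile_image(centers, sigma=60.0)
        an = pr.analyze_field(
            img,
            ms.CollimatorSpec(n_slits=4),
            pr.AnalysisConfig(expected_separation_um=512.0, band=(0, 4)),
        )
        seps = np.diff(sorted(p.center_um for p in an.peaks))
        hand_sd = np.sqrt(((seps - seps.mean()) ** 2).sum() / (len(seps) - 1))
        assert an.separation_sd_um == pytest.approx(hand_sd, rel=1e-9)
        assert an.separation_mean_um == pytest.approx(512.0, abs=1.0)

    def test_fewer_than_two_peaks_is_an_error(self):
        img = gaussian_profile_image([1000.0])
        with pytest.raises(ValueError):
            pr.analyze_field(
                img,
                ms.CollimatorSpec(n_slits=4),
                pr.AnalysisConfig(expected_separation_um=512.0, band=(0, 4)),
            )


class TestFwhmVsSlitWidth:
    def test_exact_model_points_recover_model_line(self, geom_w0):
        widths = np.arange(20.0, 101.0, 5.0)
        pts = [
            (w, ms.projected_beam_width(ms.BeamlineGeometry(212.0, 68.0, 0.4, w)))
            for w in widths
        ]
        fit = pr.fwhm_vs_slit_width(pts, geom=geom_w0)
        assert fit.intercept_um == pytest.approx(ms.projected_beam_width(geom_w0), abs=1e-9)
        assert fit.slope == pytest.approx(1.0 + 68.0 / 212.0, abs=1e-12)
        assert fit.model_slope == pytest.approx(fit.slope)
        assert fit.model_intercept_um == pytest.approx(fit.intercept_um)

    def test_points_below_linear_range_excluded(self):
        pts = [(5.0, 500.0), (10.0, 400.0)] + [
            (w, 100.0 + w) for w in (20.0, 40.0, 60.0, 80.0)
        ]
        fit = pr.fwhm_vs_slit_width(pts)
        assert fit.intercept_um == pytest.approx(100.0, abs=1e-9)

    def test_needs_three_distinct_widths(self):
        with pytest.raises(ValueError):
            pr.fwhm_vs_slit_width([(20.0, 130.0), (40.0, 140.0)])
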