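"""Localization engine: each stage against small arithmetic oracles."""

import math

import numpy as np
import pandas as pd
import pytest

from smnd.localization import (
    FWHM_FACTOR,
    correct_drift,
    detect_candidates,
    fit_psf,
    localization_error,
    localize_movie,
    quality_filter,
    remove_duplicates,
    subtract_background,
    theoretical_fwhm,
)
from smnd.synthetic import OligomerFieldConfig, simulate_movie, simulate_oligomer_field


class TestBackgroundSubtraction:
    def test_constant_movie_goes_to_zero(self):
        mv = np.full((20, 8, 8), 42.0)
        assert np.allclose(subtract_background(mv, window=5), 0.0)

    def test_single_frame_spike_is_retained(self):
        # the window mean excludes the target frame, so a lone spike of
        # height h on a constant background comes out at exactly h
        mv = np.full((101, 4, 4), 10.0)
        mv[50, 2, 2] += 77.0
        out = subtract_background(mv, window=50)
        assert out[50, 2, 2] == pytest.approx(77.0, abs=1e-9)
        # neighboring frames see the spike in their window mean and dip by
        # at most h / window
        others = np.delete(out, 50, axis=0)
        assert others.max() <= 1e-9
        assert others.min() >= -77.0 / 50.0 - 1e-9

    def test_short_movie_shrinks_window(self, caplog):
        import logging

        with caplog.at_level(logging.INFO, logger="smnd.localization"):
            subtract_background(np.zeros((10, 4, 4)), window=50)
        assert any("shrunk" in r.message for r in caplog.records)

    def test_single_frame_zeroed_with_warning(self):
        with pytest.warns(UserWarning):
            out = subtract_background(np.ones((1, 4, 4)), window=50)
        assert np.all(out == 0.0)


class TestDetection:
    def test_flat_frame_no_candidates(self):
        assert detect_candidates(np.full((32, 32), 5.0)) == []

    def test_single_bright_pixel_found(self, rng):
        frame = rng.normal(0.0, 1.0, (32, 32))
        frame[16, 20] = 10.0
        cands = detect_candidates(frame, min_snr=5.0)
        assert cands == [(16, 20)]

    def test_two_separated_emitters_found(self):
        mv = simulate_movie([(10 * 160, 10 * 160, 2000), (30 * 160, 30 * 160, 2000)],
                            psf_sigma=130, pixel_size=160, frames=1, shape=(40, 40),
                            noise=False, activation=np.ones((2, 1), bool))
        frame = mv[0] + np.random.default_rng(1).normal(0, 0.1, mv[0].shape)
        assert len(detect_candidates(frame, min_snr=5.0)) == 2

    def test_close_candidates_merge_to_brighter(self):
        frame = np.zeros((32, 32))
        frame[10, 10] = 8.0
        frame[12, 12] = 9.0
        frame += np.random.default_rng(2).normal(0, 0.5, frame.shape)
        cands = detect_candidates(frame, min_snr=5.0)
        assert cands == [(12, 12)]


class TestPsfFit:
    def test_exact_model_recovery(self):
        # render the fit's own model (sampled Gaussian) noiselessly
        a = 160.0
        y, x = np.mgrid[0:9, 0:9]
        xc, yc = (x + 0.5) * a, (y + 0.5) * a
        true = dict(x0=4.5 * a, y0=4.5 * a, sx=150.0, sy=150.0, amp=50.0, off=10.0)
        win = true["off"] + true["amp"] * np.exp(
            -0.5 * (((xc - true["x0"]) / true["sx"]) ** 2 + ((yc - true["y0"]) / true["sy"]) ** 2))
        fit = fit_psf(win, a)
        assert fit.valid
        assert fit.x0 == pytest.approx(true["x0"], rel=1e-3)
        assert fit.y0 == pytest.approx(true["y0"], rel=1e-3)
        assert fit.sigma_x == pytest.approx(150.0, rel=1e-3)
        assert fit.amplitude == pytest.approx(50.0, rel=1e-3)
        assert fit.photons == pytest.approx(2 * math.pi * 50 * 150 * 150 / a ** 2, rel=1e-3)

    def test_symmetric_input_centers_fit(self):
        a = 160.0
        y, x = np.mgrid[0:9, 0:9]
        win = 5.0 + 40.0 * np.exp(-0.5 * (((x - 4) / 1.2) ** 2 + ((y - 4) / 1.2) ** 2))
        fit = fit_psf(win, a)
        assert fit.x0 == pytest.approx(4.5 * a, abs=1e-6 * a)
        assert fit.y0 == pytest.approx(4.5 * a, abs=1e-6 * a)

    def test_monte_carlo_scatter_matches_error_formula(self):
        # empirical sd of the fitted center vs the predicted localization
        # error, over a small grid of photon counts and background levels
        for n_photons, bg in [(1000, 4.0), (1000, 25.0)]:
            xs, preds = [], []
            for rep in range(120):
                mv = simulate_movie([(4.5 * 160 + 13, 4.5 * 160 - 7, n_photons)],
                                    psf_sigma=130, pixel_size=160, background_level=bg,
                                    frames=1, shape=(9, 9), noise=True,
                                    activation=np.ones((1, 1), bool),
                                    seed=rep + 1000 * int(bg))
                fit = fit_psf(mv[0] - bg, 160.0)
                if fit.valid:
                    xs.append(fit.x0)
                    sigma = 0.5 * (fit.sigma_x + fit.sigma_y)
                    preds.append(localization_error(sigma, fit.photons, 160.0, fit.bg_sd))
            ratio = np.std(xs, ddof=1) / np.mean(preds)
            assert 0.75 < ratio < 1.25


class TestErrorFormula:
    def test_photon_limited_term(self):
        # sigma/sqrt(N) dominates when pixelation and background vanish
        assert localization_error(100.0, 100.0, 1e-6, 0.0) == pytest.approx(10.0, rel=1e-6)

    def test_three_term_sum_oracle(self):
        sigma, n, a, b = 130.0, 1000.0, 160.0, 5.0
        expected = math.sqrt(sigma ** 2 / n + a ** 2 / (12 * n)
                             + 8 * math.pi * sigma ** 4 * b ** 2 / (a ** 2 * n ** 2))
        assert localization_error(sigma, n, a, b) == pytest.approx(expected, rel=1e-12)

    def test_error_scales_inverse_sqrt_photons_without_background(self):
        e1 = localization_error(130.0, 500.0, 160.0, 0.0)
        e2 = localization_error(130.0, 1000.0, 160.0, 0.0)
        assert e1 / e2 == pytest.approx(math.sqrt(2.0), rel=1e-12)

    def test_zero_photons_rejected(self):
        with pytest.raises(ValueError):
            localization_error(130.0, 0.0, 160.0, 1.0)


class TestTheoreticalFwhm:
    def test_red_emission_high_na(self):
        assert theoretical_fwhm(610.0, 1.49) == pytest.approx(208.8, abs=0.05)

    def test_linearity(self):
        assert theoretical_fwhm(1220.0, 1.49) == pytest.approx(2 * theoretical_fwhm(610.0, 1.49))
        assert theoretical_fwhm(0.0, 1.49) == 0.0


def _record(sigma=150.0, err=10.0, snr=8.0):
    return {"x_nm": 0.0, "y_nm": 0.0, "frame": 0, "photons": 1000.0,
            "sigma_x_nm": sigma, "sigma_y_nm": sigma, "bg_sd": 1.0,
            "snr": snr, "loc_error_nm": err, "truth_id": -1}


class TestQualityFilter:
    def test_one_violation_per_rule_leaves_compliant_records(self):
        wide = 700.0 / FWHM_FACTOR       # FWHM 700 nm
        narrow = 100.0 / FWHM_FACTOR     # FWHM 100 nm
        table = pd.DataFrame([
            _record(),                       # compliant
            _record(sigma=wide),             # FWHM too large
            _record(sigma=narrow),           # FWHM too small
            _record(err=25.0),               # error too large
            _record(snr=2.0),                # SNR too low
        ])
        out = quality_filter(table)
        assert len(out) == 1

    def test_snr_boundary_is_strict(self):
        table = pd.DataFrame([_record(snr=3.6), _record(snr=3.601)])
        assert len(quality_filter(table)) == 1

    def test_fwhm_boundary_is_inclusive(self):
        table = pd.DataFrame([_record(sigma=117.0 / FWHM_FACTOR),
                              _record(sigma=600.0 / FWHM_FACTOR)])
        assert len(quality_filter(table)) == 2

    def test_idempotent(self):
        rng = np.random.default_rng(4)
        table = pd.DataFrame([_record(sigma=s, err=e, snr=q) for s, e, q in zip(
            rng.uniform(30, 350, 200), rng.uniform(0, 40, 200), rng.uniform(0, 12, 200))])
        once = quality_filter(table)
        twice = quality_filter(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="snr"):
            quality_filter(pd.DataFrame({"x_nm": [0.0], "y_nm": [0.0]}))


class TestRemoveDuplicates:
    def test_consecutive_frames_merge(self):
        t = pd.DataFrame([{**_record(), "frame": 3, "x_nm": 0.0},
                          {**_record(), "frame": 4, "x_nm": 10.0}])
        out = remove_duplicates(t)
        assert len(out) == 1
        assert out.photons.iloc[0] == 2000.0
        assert out.x_nm.iloc[0] == pytest.approx(5.0)   # equal photon weights

    def test_large_frame_gap_not_merged(self):
        t = pd.DataFrame([{**_record(), "frame": 3}, {**_record(), "frame": 10}])
        assert len(remove_duplicates(t)) == 2

    def test_blink_chain_merges_transitively(self):
        rows = [{**_record(), "frame": f, "x_nm": 2.0 * f} for f in (5, 6, 7, 8)]
        out = remove_duplicates(pd.DataFrame(rows))
        assert len(out) == 1
        assert out.photons.iloc[0] == 4000.0
        assert out.frame.iloc[0] == 5


class TestDriftCorrection:
    @pytest.fixture(scope="class")
    def blinky_field(self):
        cfg = OligomerFieldConfig(n_complexes=3000, p_detect=1.0, blink_mean=2.0,
                                  n_frames=200, seed=1)
        table, _ = simulate_oligomer_field(cfg)
        return table

    def test_zero_drift_recovered_as_zero(self, blinky_field):
        _, trace = correct_drift(blinky_field, bin_frames=50)
        assert np.abs(trace[["dx_nm", "dy_nm"]].to_numpy()).max() < 5.0

    def test_linear_drift_recovered(self, blinky_field):
        drifted = blinky_field.copy()
        drifted["x_nm"] += 1.0 * drifted["frame"]
        drifted["y_nm"] += 0.5 * drifted["frame"]
        corrected, trace = correct_drift(drifted, bin_frames=50)
        slope_x = np.polyfit(trace.frame, trace.dx_nm, 1)[0]
        slope_y = np.polyfit(trace.frame, trace.dy_nm, 1)[0]
        assert slope_x == pytest.approx(1.0, rel=0.2)
        assert slope_y == pytest.approx(0.5, rel=0.2)
        resid = corrected["x_nm"] - blinky_field["x_nm"]
        assert np.std(resid) < 15.0

    def test_single_bin_passes_through_with_warning(self, blinky_field):
        with pytest.warns(UserWarning):
            out, trace = correct_drift(blinky_field, bin_frames=10_000)
        pd.testing.assert_frame_equal(out, blinky_field)
        assert np.all(trace[["dx_nm", "dy_nm"]].to_numpy() == 0.0)


class TestEndToEnd:
    def test_isolated_emitters_recovered_within_predicted_error(self):
        rng = np.random.default_rng(3)
        emitters = []
        for i in range(3):
            for j in range(3):
                emitters.append(((8 + 16 * i + rng.uniform(-2, 2)) * 160,
                                 (8 + 16 * j + rng.uniform(-2, 2)) * 160, 800.0))
        act = np.zeros((9, 25), bool)
        for k in range(9):
            act[k, rng.integers(0, 25)] = True
        mv = simulate_movie(emitters, psf_sigma=130, pixel_size=160, background_level=20,
                            frames=25, shape=(64, 64), noise=True, activation=act, seed=5)
        table = localize_movie(mv, pixel_size=160, window=50)
        hits = 0
        for x, y, _ in emitters:
            d = np.hypot(table.x_nm - x, table.y_nm - y)
            i = d.idxmin()
            if d[i] <= 3 * table.loc_error_nm[i]:
                hits += 1
        assert hits == 9
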