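"""Detection, integrated-Gaussian MLE fitting, precision and filtering."""

import math

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment
from scipy.special import erf

from sptpalm import estimate_precision, filter_localizations, localization_histograms
from sptpalm.localize import (
    LocalizationSet,
    detect_candidates,
    fit_spot_mle,
    localize_stack,
)
from sptpalm.params import DetectionParams, FilterParams, FitParams
from sptpalm.simulate import render_spot


def _numerical_crlb_x_px(n_photons, background, sigma_px, side=7, center=None):
    """Independent CRLB oracle: finite-difference Fisher information of
    the integrated-Gaussian Poisson model, inverted; returns sd of x in px."""
    if center is None:
        center = (side / 2.0, side / 2.0)

    def model(theta):
        x0, y0, n, b, s = theta
        e = np.arange(side + 1, dtype=float)
        ex = 0.5 * np.diff(erf((e - x0) / (s * math.sqrt(2))))
        ey = 0.5 * np.diff(erf((e - y0) / (s * math.sqrt(2))))
        return n * np.outer(ey, ex) + b

    theta = np.array([center[0], center[1], n_photons, background, sigma_px])
    jac = []
    for k in range(5):
        h = 1e-5 * max(abs(theta[k]), 1e-3)
        tp, tm = theta.copy(), theta.copy()
        tp[k] += h
        tm[k] -= h
        jac.append((model(tp) - model(tm)).ravel() / (2 * h))
    jac = np.array(jac)
    mu = model(theta).ravel()
    fisher = (jac / mu) @ jac.T
    return math.sqrt(np.linalg.inv(fisher)[0, 0])


class TestDetection:
    def test_flat_frame_yields_nothing(self):
        cands = detect_candidates(np.full((32, 32), 7.0), 1, DetectionParams())
        assert cands == []

    def test_single_bright_spot_found(self, rng):
        frame = render_spot(1000, 10, 1.3, (40.5, 30.5), 64, rng)
        cands = detect_candidates(frame, 1, DetectionParams())
        assert len(cands) == 1
        assert abs(cands[0].row - 30) <= 1 and abs(cands[0].col - 40) <= 1

    def test_two_separated_spots_found(self, rng):
        frame = np.full((64, 64), 10.0)
        from sptpalm.simulate import _render_emitters

        _render_emitters(frame, np.array([20.5, 40.5]), np.array([32.5, 32.5]), np.array([1000.0, 1000.0]), 1.3)
        frame = rng.poisson(frame).astype(float)
        cands = detect_candidates(frame, 1, DetectionParams())
        assert len(cands) == 2

    def test_border_candidates_dropped(self, rng):
        frame = render_spot(2000, 5, 1.3, (1.5, 1.5), 32, rng)
        cands = detect_candidates(frame, 1, DetectionParams())
        assert all(c.row >= 3 and c.col >= 3 for c in cands)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            DetectionParams(threshold_factor=-1.0)


class TestFitSpot:
    def test_noiseless_centered_spot_exact(self):
        roi = render_spot(1000, 10, 1.3, (3.5, 3.5), 7)
        fit = fit_spot_mle(roi, (3, 3), FitParams(), pixel_size_nm=100.0)
        assert fit["converged"]
        assert abs(fit["x_nm"] - 350.0) < 0.1 and abs(fit["y_nm"] - 350.0) < 0.1
        assert abs(fit["photons"] - 1000.0) / 1000.0 < 0.005
        assert abs(fit["sigma_nm"] - 130.0) / 130.0 < 0.005

    def test_pixel_shift_equivariance(self):
        """Shifting the ROI crop by one pixel shifts the fitted position
        by exactly one pixel size (to <0.1 nm)."""
        img = render_spot(2000, 5, 1.3, (5.3, 5.7), 11)
        fit_a = fit_spot_mle(img[1:8, 1:8], (4, 4), FitParams(), pixel_size_nm=100.0, roi_origin=(1, 1))
        fit_b = fit_spot_mle(img[2:9, 2:9], (3, 3), FitParams(), pixel_size_nm=100.0, roi_origin=(2, 2))
        assert abs(fit_a["x_nm"] - fit_b["x_nm"]) < 0.1
        assert abs(fit_a["y_nm"] - fit_b["y_nm"]) < 0.1
        assert abs(fit_a["x_nm"] - 530.0) < 0.5 and abs(fit_a["y_nm"] - 570.0) < 0.5

    def test_scmos_zero_variance_matches_poisson_path(self, rng):
        roi = render_spot(800, 10, 1.3, (3.2, 3.6), 7, rng)
        plain = fit_spot_mle(roi, (3, 3), FitParams(), pixel_size_nm=100.0)
        scmos = fit_spot_mle(roi, (3, 3), FitParams(), calib_roi=np.zeros((7, 7)), pixel_size_nm=100.0)
        for key in ("x_nm", "y_nm", "photons", "sigma_nm"):
            assert plain[key] == pytest.approx(scmos[key], rel=1e-9)

    def test_degenerate_dim_spot_never_nan(self, rng):
        roi = rng.poisson(10.0, (7, 7)).astype(float)
        fit = fit_spot_mle(roi, (3, 3), FitParams(), pixel_size_nm=100.0)
        for key in ("x_nm", "y_nm", "photons", "sigma_nm", "background_photons"):
            assert np.isfinite(fit[key])

    def test_nonfinite_roi_rejected(self):
        roi = np.full((7, 7), np.nan)
        with pytest.raises(ValueError):
            fit_spot_mle(roi, (3, 3), FitParams())

    @pytest.mark.parametrize("n_photons", [300, 1000, 3000])
    def test_efficiency_near_crlb(self, n_photons, rng):
        """Empirical RMSE within 15% of the numerically computed CRLB."""
        errs = []
        fp = FitParams()
        for _ in range(300):
            cx = 3.5 + rng.uniform(-0.5, 0.5)
            cy = 3.5 + rng.uniform(-0.5, 0.5)
            roi = render_spot(n_photons, 10, 1.3, (cx, cy), 7, rng)
            fit = fit_spot_mle(roi, (3, 3), fp, pixel_size_nm=100.0)
            if fit["converged"]:
                errs.append(fit["x_nm"] / 100.0 - cx)
        errs = np.array(errs)
        assert len(errs) > 280
        rmse = float(np.sqrt(np.mean(errs**2)))
        crlb = _numerical_crlb_x_px(n_photons, 10, 1.3)
        assert abs(rmse - crlb) / crlb < 0.15


class TestPrecision:
    def test_closed_form_value(self):
        # sigma=130, a=100, N=1000, b=0 -> sigma_a=133.2, (4/3)*sigma_a/sqrt(N)
        prec = estimate_precision(130.0, 1000.0, 0.0, 100.0)
        sigma_a = math.sqrt(130.0**2 + 100.0**2 / 12.0)
        assert sigma_a == pytest.approx(133.2, abs=0.05)
        assert prec == pytest.approx((4.0 / 3.0) * sigma_a / math.sqrt(1000.0), rel=1e-9)
        assert prec == pytest.approx(5.6, abs=0.05)

    def test_scaling_with_photons(self):
        p1 = estimate_precision(130.0, 1000.0, 0.0, 100.0)
        p2 = estimate_precision(130.0, 2000.0, 0.0, 100.0)
        assert p1 / p2 == pytest.approx(math.sqrt(2.0), rel=1e-9)

    def test_nonpositive_photons_rejected(self):
        with pytest.raises(ValueError):
            estimate_precision(130.0, 0.0, 5.0, 100.0)

    def test_median_precision_tracks_empirical_rmse(self, rng):
        """The closed-form estimate agrees with the observed scatter."""
        errs, precs = [], []
        fp = FitParams()
        for _ in range(400):
            cx = 3.5 + rng.uniform(-0.5, 0.5)
            roi = render_spot(1000, 10, 1.3, (cx, 3.5), 7, rng)
            fit = fit_spot_mle(roi, (3, 3), fp, pixel_size_nm=100.0)
            if fit["converged"]:
                errs.append(fit["x_nm"] - cx * 100.0)
                precs.append(
                    estimate_precision(fit["sigma_nm"], fit["photons"], fit["background_photons"], 100.0)
                )
        rmse = float(np.sqrt(np.mean(np.array(errs) ** 2)))
        med = float(np.median(precs))
        assert abs(med - rmse) / rmse < 0.20


class TestLocalizeStack:
    def test_dark_movie_empty_after_filter(self, rng, default_params):
        from sptpalm import CameraCalibration, MovieStack

        frames = np.rint(rng.normal(100.0, 2.0, (30, 32, 32))).astype(np.uint16)
        movie = MovieStack(frames, 100.0, 0.05)
        calib = CameraCalibration(offset=100.0, variance=4.0, e_per_adu=0.5)
        locs = localize_stack(movie, calib, default_params)
        filtered, _ = filter_localizations(locs, default_params.filter)
        assert len(filtered) == 0

    def test_recall_against_ground_truth(self, small_movie_localized):
        """>=90% of isolated true emissions matched within 50 nm
        (Hungarian matching oracle per frame)."""
        cfg, gt, params, locs, filtered = small_movie_localized
        df = filtered.df
        matched = 0
        total = 0
        margin = (params.detection.roi_halfsize_px + 1) * cfg.pixel_size_nm
        h_nm = cfg.field_px[0] * cfg.pixel_size_nm
        w_nm = cfg.field_px[1] * cfg.pixel_size_nm
        for frame, g in gt.emissions.groupby("frame"):
            g_xy = g[["x_nm", "y_nm"]].to_numpy()
            # isolated = further than 500 nm from any other emission in the
            # frame, and inside the detectable area (ROIs cannot cross the
            # frame border)
            interior = (
                (g_xy[:, 0] > margin)
                & (g_xy[:, 0] < w_nm - margin)
                & (g_xy[:, 1] > margin)
                & (g_xy[:, 1] < h_nm - margin)
            )
            if len(g_xy) > 1:
                d = np.linalg.norm(g_xy[:, None] - g_xy[None, :], axis=2)
                np.fill_diagonal(d, np.inf)
                isolated = (d.min(axis=1) > 500.0) & interior
            else:
                isolated = interior
            l_xy = df[df["frame"] == frame][["x_nm", "y_nm"]].to_numpy()
            total += int(isolated.sum())
            if len(l_xy) == 0:
                continue
            cost = np.linalg.norm(g_xy[:, None] - l_xy[None, :], axis=2)
            rows, cols = linear_sum_assignment(cost)
            for r, c in zip(rows, cols):
                if isolated[r] and cost[r, c] <= 50.0:
                    matched += 1
        assert total > 500
        assert matched / total >= 0.90

    def test_deterministic(self, small_movie, default_params):
        cfg, movie, dark, gt = small_movie
        from sptpalm import calibrate_camera

        calib = calibrate_camera(dark, default_params.camera.e_per_adu)
        sub = movie.frames[:40]
        from sptpalm.camera import MovieStack

        m = MovieStack(sub, movie.pixel_size_nm, movie.frame_interval_s)
        a = localize_stack(m, calib, default_params)
        b = localize_stack(m, calib, default_params)
        assert a.df.equals(b.df)


class TestFilter:
    def _locs(self, sigmas):
        import pandas as pd

        df = pd.DataFrame(
            {
                "frame": np.arange(1, len(sigmas) + 1),
                "x_nm": 0.0,
                "y_nm": 0.0,
                "sigma_nm": sigmas,
                "photons": 1000.0,
                "background_photons": 5.0,
                "precision_nm": 10.0,
                "converged": True,
            }
        )
        return LocalizationSet(df=df)

    def test_sigma_window(self):
        locs = self._locs([120.0, 180.0, 400.0])
        out, counts = filter_localizations(locs, FilterParams(sigma_min_nm=80, sigma_max_nm=250, photons_min=0, precision_max_nm=None))
        assert len(out) == 2 and counts["sigma"] == 1

    def test_open_ranges_keep_converged_subset(self):
        locs = self._locs([50.0, 500.0])
        locs.df.loc[1, "converged"] = False
        out, counts = filter_localizations(
            locs, FilterParams(sigma_min_nm=0, sigma_max_nm=None, photons_min=0, photons_max=None, precision_max_nm=None)
        )
        assert len(out) == 1 and counts["not_converged"] == 1

    def test_planted_outliers_removed(self, rng):
        n = 400
        sigmas = np.full(n, 130.0) + rng.normal(0, 5, n)
        outlier = rng.random(n) < 0.05
        sigmas[outlier] *= 2.0
        locs = self._locs(sigmas)
        out, _ = filter_localizations(
            locs,
            FilterParams(sigma_min_nm=0.6 * 130, sigma_max_nm=1.6 * 130, photons_min=0, precision_max_nm=None),
        )
        kept_outliers = int(np.sum(out.df["sigma_nm"].to_numpy() > 1.6 * 130))
        assert outlier.sum() > 0
        assert kept_outliers / outlier.sum() <= 0.05


class TestHistograms:
    def test_empty_input(self):
        hists = localization_histograms(LocalizationSet.empty())
        for counts, edges in hists.values():
            assert counts.size == 0

    def test_constant_values_single_bin(self):
        import pandas as pd

        df = pd.DataFrame(
            {
                "frame": [1, 2, 3],
                "x_nm": 0.0,
                "y_nm": 0.0,
                "sigma_nm": 130.0,
                "photons": 1000.0,
                "background_photons": 5.0,
                "precision_nm": 10.0,
                "converged": True,
            }
        )
        hists = localization_histograms(LocalizationSet(df=df))
        counts, _ = hists["photons"]
        assert (counts > 0).sum() == 1

    def test_photon_mode_near_truth(self, small_movie_localized):
        cfg, gt, params, locs, filtered = small_movie_localized
        counts, edges = localization_histograms(filtered)["photons"]
        mode = 0.5 * (edges[np.argmax(counts)] + edges[np.argmax(counts) + 1])
        assert abs(mode - cfg.photons_per_frame) / cfg.photons_per_frame < 0.10
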