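"""Single-molecule detection and integrated-Gaussian MLE localization.

Each frame is converted to photons, candidate emitters are detected as
local maxima of a difference-of-Gaussians filtered image, and every
candidate ROI is fitted with a 2-D *integrated* Gaussian PSF model

    mu_k = N * dEx_k * dEy_k + b

under a Poisson likelihood, where ``dEx_k``/``dEy_k`` are the Gaussian
integrals over pixel k's extent (erf differences).  sCMOS read noise is
handled with the standard variance/gain^2 offset addition: the per-pixel
value ``var/gain^2`` is added to both data and model before evaluating
the likelihood, which folds Gaussian read noise into an approximate
Poisson channel.

The optimizer is a Levenberg–Marquardt iteration on the Poisson deviance
using the Fisher-information (expected Hessian) matrix and analytic first
derivatives; N, b and sigma are log-transformed to enforce positivity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import erf

from .camera import (
    CameraCalibration,
    MovieStack,
    adu_to_photons,
)
from .params import DetectionParams, FilterParams, FitParams, ParameterSet

__all__ = [
    "DetectionCandidate",
    "LocalizationSet",
    "detect_candidates",
    "fit_spot_mle",
    "estimate_precision",
    "localize_stack",
    "filter_localizations",
    "localization_histograms",
]

_SQRT2 = math.sqrt(2.0)
_MAD_TO_SD = 1.4826


@dataclass(frozen=True)
class DetectionCandidate:
    frame: int  # 1-based
    row: int
    col: int
    score: float


@dataclass
class LocalizationSet:
    """Fitted emitters, one per row, sorted by (frame, detection order).

    Columns: frame (1-based), x_nm, y_nm, sigma_nm, photons,
    background_photons, precision_nm, converged; plus loglik for fits
    produced in-session (not round-tripped through CSV).
    """

    df: pd.DataFrame
    source: str = ""
    params_digest: str = ""

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def empty(cls, source: str = "", params_digest: str = "") -> "LocalizationSet":
        from .camera import LOCALIZATION_COLUMNS

        df = pd.DataFrame({c: pd.Series(dtype=float) for c in LOCALIZATION_COLUMNS})
        df["frame"] = df["frame"].astype(int)
        df["converged"] = df["converged"].astype(bool)
        return cls(df=df, source=source, params_digest=params_digest)

    def positions_nm(self) -> np.ndarray:
        return self.df[["x_nm", "y_nm"]].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# Detection


def detect_candidates(
    photon_frame: np.ndarray, frame_index: int, det: DetectionParams
) -> list[DetectionCandidate]:
    """Local maxima of the DoG-filtered frame above a MAD-based threshold.

    A candidate must be an 8-neighbourhood maximum of the filtered image
    with value above ``threshold_factor * 1.4826 * MAD``; candidates whose
    ROI would cross the frame border are dropped.  Returned sorted by
    descending score (ties by row, col).
    """
    f = np.asarray(photon_frame, dtype=float)
    h = det.roi_halfsize_px
    if f.shape[0] < 2 * h + 1 or f.shape[1] < 2 * h + 1:
        raise ValueError("frame smaller than one ROI")
    dog = ndimage.gaussian_filter(f, det.dog_sigma_small_px) - ndimage.gaussian_filter(
        f, det.dog_sigma_large_px
    )
    med = np.median(dog)
    noise = _MAD_TO_SD * np.median(np.abs(dog - med))
    # absolute floor guards against spurious maxima from float rounding
    # on (near-)constant frames; negligible against any real threshold
    thr = det.threshold_factor * noise + 1e-9 * max(1.0, float(np.max(np.abs(f))))
    local_max = dog == ndimage.maximum_filter(dog, size=3, mode="nearest")
    above = local_max & (dog > thr)
    above[:h, :] = above[-h:, :] = False
    above[:, :h] = above[:, -h:] = False
    rows, cols = np.nonzero(above)
    scores = dog[rows, cols]
    order = np.lexsort((cols, rows, -scores))
    return [
        DetectionCandidate(frame=frame_index, row=int(rows[k]), col=int(cols[k]), score=float(scores[k]))
        for k in order
    ]


# ---------------------------------------------------------------------------
# Integrated-Gaussian model pieces (1-D factors over pixel indices 0..n-1)


def _pixel_integrals(n: int, center: float, sigma: float):
    """E_j, dE/dcenter, dE/dsigma for pixels j spanning [j, j+1)."""
    edges = np.arange(n + 1, dtype=float)
    a = (edges - center) / (sigma * _SQRT2)
    erfs = erf(a)
    gauss = np.exp(-a * a)
    e = 0.5 * (erfs[1:] - erfs[:-1])
    # d erf(a_j)/dcenter = -(2/sqrt(pi)) e^{-a^2} / (sigma*sqrt(2))
    c = 1.0 / (sigma * math.sqrt(2.0 * math.pi))
    de_dc = c * (gauss[:-1] - gauss[1:])
    de_ds = (1.0 / (sigma * math.sqrt(math.pi))) * (a[:-1] * gauss[:-1] - a[1:] * gauss[1:])
    return e, de_dc, de_ds


def _model_and_jac(theta: np.ndarray, n_side: int):
    """Model image and Jacobian w.r.t. eta = (x0, y0, lnN, lnb, lnsigma)."""
    x0, y0, N, b, sig = theta
    ex, dex_dx, dex_ds = _pixel_integrals(n_side, x0, sig)
    ey, dey_dy, dey_ds = _pixel_integrals(n_side, y0, sig)
    exy = np.outer(ey, ex)
    mu = N * exy + b
    jac = np.empty((5, n_side, n_side))
    jac[0] = N * np.outer(ey, dex_dx)  # d/dx0
    jac[1] = N * np.outer(dey_dy, ex)  # d/dy0
    jac[2] = N * exy  # d/dlnN
    jac[3] = b  # d/dlnb
    jac[4] = sig * N * (np.outer(ey, dex_ds) + np.outer(dey_ds, ex))  # d/dlnsigma
    return mu, jac


def _nll(mu: np.ndarray, z: np.ndarray) -> float:
    mu = np.maximum(mu, 1e-12)
    return float(np.sum(mu - z * np.log(mu)))


def fit_spot_mle(
    roi: np.ndarray,
    init: DetectionCandidate | tuple[float, float],
    fit_params: FitParams,
    calib_roi: np.ndarray | None = None,
    pixel_size_nm: float = 100.0,
    roi_origin: tuple[int, int] = (0, 0),
) -> dict:
    """Maximum-likelihood fit of one spot ROI.

    ``roi`` is a square photon image with odd side; ``init`` gives the
    starting pixel (a :class:`DetectionCandidate` or a (row, col) pair in
    ROI coordinates).  ``calib_roi``, if given, is the per-pixel
    ``variance/gain^2`` map for the ROI (sCMOS correction); pass ``None``
    or zeros for a pure-Poisson camera.

    Returns a dict with x_nm, y_nm (frame coordinates via ``roi_origin``),
    sigma_nm, photons, background_photons, converged, loglik, n_iter.
    """
    roi = np.asarray(roi, dtype=float)
    if roi.ndim != 2 or roi.shape[0] != roi.shape[1]:
        raise ValueError("ROI must be square")
    n_side = roi.shape[0]
    if n_side % 2 != 1 or n_side < 3:
        raise ValueError("ROI side must be odd and >=3")
    if not np.all(np.isfinite(roi)):
        raise ValueError("ROI contains non-finite values")

    z = roi.copy()
    if calib_roi is not None:
        corr = np.asarray(calib_roi, dtype=float)
        if corr.shape != roi.shape:
            raise ValueError("calibration ROI shape mismatch")
        z = z + corr
    else:
        corr = None

    if isinstance(init, DetectionCandidate):
        r0, c0 = init.row - roi_origin[0], init.col - roi_origin[1]
    else:
        r0, c0 = init
    x_init = float(c0) + 0.5
    y_init = float(r0) + 0.5

    border = np.concatenate([roi[0], roi[-1], roi[1:-1, 0], roi[1:-1, -1]])
    b0 = max(float(np.median(border)), 1e-2)
    n0 = max(float(roi.sum() - b0 * roi.size), 20.0)
    theta = np.array([x_init, y_init, n0, b0, fit_params.initial_sigma_px])

    lam = 1e-3
    mu, jac = _model_and_jac(theta, n_side)
    if corr is not None:
        mu = mu + corr
    nll = _nll(mu, z)
    converged = False
    it = 0
    for it in range(1, fit_params.max_iterations + 1):
        mu_safe = np.maximum(mu, 1e-12)
        resid = 1.0 - z / mu_safe
        j2 = jac.reshape(5, -1)
        g = j2 @ resid.ravel()
        fisher = (j2 / mu_safe.ravel()) @ j2.T
        step_ok = False
        for _ in range(12):
            h = fisher + lam * np.diag(np.maximum(np.diag(fisher), 1e-12))
            try:
                delta = np.linalg.solve(h, -g)
            except np.linalg.LinAlgError:
                lam *= 10.0
                continue
            eta_new = np.array(
                [
                    theta[0] + delta[0],
                    theta[1] + delta[1],
                    math.log(theta[2]) + delta[2],
                    math.log(theta[3]) + delta[3],
                    math.log(theta[4]) + delta[4],
                ]
            )
            # keep exp() sane
            eta_new[2:] = np.clip(eta_new[2:], -20.0, 20.0)
            theta_new = np.array(
                [eta_new[0], eta_new[1], math.exp(eta_new[2]), math.exp(eta_new[3]), math.exp(eta_new[4])]
            )
            mu_new, jac_new = _model_and_jac(theta_new, n_side)
            if corr is not None:
                mu_new = mu_new + corr
            nll_new = _nll(mu_new, z)
            if nll_new <= nll + 1e-12:
                step_ok = True
                lam = max(lam * 0.3, 1e-9)
                break
            lam *= 10.0
        if not step_ok:
            break
        rel = float(np.max(np.abs(delta)))
        theta, mu, jac, nll = theta_new, mu_new, jac_new, nll_new
        if rel < fit_params.tol:
            converged = True
            break

    x0, y0, n_phot, bkg, sig = theta
    inside = -1.0 <= x0 <= n_side + 1.0 and -1.0 <= y0 <= n_side + 1.0
    if not (n_phot > 0 and sig > 0 and inside and np.isfinite(nll)):
        converged = False
    loglik = float(np.sum(z * np.log(np.maximum(mu, 1e-12)) - mu))
    return {
        "x_nm": (roi_origin[1] + x0) * pixel_size_nm,
        "y_nm": (roi_origin[0] + y0) * pixel_size_nm,
        "x_px_roi": x0,
        "y_px_roi": y0,
        "sigma_nm": sig * pixel_size_nm,
        "photons": n_phot,
        "background_photons": bkg,
        "converged": bool(converged),
        "loglik": loglik,
        "n_iter": it,
    }


def estimate_precision(
    sigma_nm: float, photons: float, background_photons: float, pixel_size_nm: float
) -> float:
    """Closed-form MLE localization precision (standard error, nm).

    sigma_loc^2 = (sigma_a^2/N) * (16/9 + 8*pi*sigma_a^2*b / (N*a^2)),
    with sigma_a^2 = sigma^2 + a^2/12, a the pixel size, N the fitted
    photons and b the background per pixel.
    """
    if photons <= 0:
        raise ValueError("photons must be positive")
    a2 = pixel_size_nm**2
    sa2 = sigma_nm**2 + a2 / 12.0
    var = (sa2 / photons) * (16.0 / 9.0 + 8.0 * math.pi * sa2 * background_photons / (photons * a2))
    return math.sqrt(var)


# ---------------------------------------------------------------------------
# Whole-stack driver


def localize_stack(
    movie: MovieStack,
    calib: CameraCalibration,
    params: ParameterSet,
) -> LocalizationSet:
    """Photon conversion -> detection -> MLE fit -> precision, per frame.

    Non-converged fits are retained (flagged) until filtering.  Fits whose
    centre lands more than 1 px from the candidate pixel centre are
    discarded: with the single-emitter model they indicate the fit locked
    onto a neighbouring spot.
    """
    h = params.detection.roi_halfsize_px
    side = 2 * h + 1
    px = movie.pixel_size_nm
    offset_map, var_map = calib.maps_for(movie.shape)
    gain2 = calib.e_per_adu**2
    scmos_full = (var_map / gain2) if params.fit.use_scmos else None

    rows: list[dict] = []
    for f_idx in range(movie.n_frames):
        photon_frame = (movie.frames[f_idx].astype(float) - offset_map) * calib.e_per_adu / calib.qe
        cands = detect_candidates(photon_frame, f_idx + 1, params.detection)
        for cand in cands:
            r0, c0 = cand.row - h, cand.col - h
            roi = photon_frame[r0 : r0 + side, c0 : c0 + side]
            calib_roi = scmos_full[r0 : r0 + side, c0 : c0 + side] if scmos_full is not None else None
            fit = fit_spot_mle(
                roi,
                (h, h),
                params.fit,
                calib_roi=calib_roi,
                pixel_size_nm=px,
                roi_origin=(r0, c0),
            )
            if max(abs(fit["x_px_roi"] - (h + 0.5)), abs(fit["y_px_roi"] - (h + 0.5))) > 1.0:
                continue
            try:
                prec = estimate_precision(fit["sigma_nm"], fit["photons"], fit["background_photons"], px)
            except ValueError:
                prec = float("nan")
            rows.append(
                {
                    "frame": cand.frame,
                    "x_nm": fit["x_nm"],
                    "y_nm": fit["y_nm"],
                    "sigma_nm": fit["sigma_nm"],
                    "photons": fit["photons"],
                    "background_photons": fit["background_photons"],
                    "precision_nm": prec,
                    "converged": fit["converged"],
                    "loglik": fit["loglik"],
                }
            )
    if not rows:
        return LocalizationSet.empty(source=movie.source_path, params_digest=params.digest())
    df = pd.DataFrame(rows)
    df["frame"] = df["frame"].astype(int)
    return LocalizationSet(df=df, source=movie.source_path, params_digest=params.digest())


def filter_localizations(
    locs: LocalizationSet, f: FilterParams
) -> tuple[LocalizationSet, dict[str, int]]:
    """Keep converged localizations inside the quality windows.

    Returns the filtered set (order preserved) and per-criterion removal
    counts (a localization failing several criteria is counted in each).
    """
    df = locs.df
    if len(df) == 0:
        return locs, {"not_converged": 0, "sigma": 0, "photons": 0, "precision": 0}
    conv = df["converged"].to_numpy(dtype=bool)
    sig = df["sigma_nm"].to_numpy(dtype=float)
    pho = df["photons"].to_numpy(dtype=float)
    pre = df["precision_nm"].to_numpy(dtype=float)
    ok_sigma = sig >= f.sigma_min_nm
    if f.sigma_max_nm is not None:
        ok_sigma &= sig <= f.sigma_max_nm
    ok_phot = pho >= f.photons_min
    if f.photons_max is not None:
        ok_phot &= pho <= f.photons_max
    ok_prec = np.isfinite(pre)
    if f.precision_max_nm is not None:
        ok_prec &= pre <= f.precision_max_nm
    keep = conv & ok_sigma & ok_phot & ok_prec
    counts = {
        "not_converged": int(np.sum(~conv)),
        "sigma": int(np.sum(conv & ~ok_sigma)),
        "photons": int(np.sum(conv & ~ok_phot)),
        "precision": int(np.sum(conv & ~ok_prec)),
    }
    return (
        LocalizationSet(df=df[keep].reset_index(drop=True), source=locs.source, params_digest=locs.params_digest),
        counts,
    )


def localization_histograms(locs: LocalizationSet) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Freedman–Diaconis histograms of sigma, photons and precision."""
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for key, col in [("sigma_nm", "sigma_nm"), ("photons", "photons"), ("precision_nm", "precision_nm")]:
        vals = locs.df[col].to_numpy(dtype=float) if len(locs.df) else np.array([])
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            out[key] = (np.array([], dtype=int), np.array([]))
            continue
        counts, edges = np.histogram(vals, bins="fd")
        out[key] = (counts, edges)
    return out
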