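"""MSD-based mobility analysis.

Per-track mean-square displacement curves, diffusion coefficients from
ordinary least-squares fits over the first few lags (D = slope/4 for 2-D
diffusion in the membrane plane, free intercept absorbing the
localization-error offset ~4*sigma_loc^2), the log10(D) distribution,
Gaussian-mixture population decomposition and a mobile/immobile split at
a configurable log10(D) threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import MobilityParams
from .track import Track

__all__ = [
    "MSDCurve",
    "TrackMobility",
    "PopulationFit",
    "MobilitySummary",
    "compute_msd",
    "fit_msd_linear",
    "mean_msd",
    "per_track_mobility",
    "population_analysis",
    "analyze_mobility",
    "write_mobility_table",
]

NM2_TO_UM2 = 1e-6


@dataclass
class MSDCurve:
    lags_s: np.ndarray
    values_um2: np.ndarray
    n_pairs: np.ndarray


@dataclass
class TrackMobility:
    track_id: int
    D_um2_per_s: float
    intercept_um2: float
    adj_r2: float
    accepted: bool


@dataclass
class PopulationFit:
    components: list[tuple[float, float, float]]  # (weight, mean, sd) in log10(D)
    peak_logD: float
    mobile_fraction: float
    bic: dict[int, float]


@dataclass
class MobilitySummary:
    mean_curve: MSDCurve
    D_mean_um2_per_s: float
    intercept_um2: float
    adj_r2: float
    logD_values: np.ndarray
    n_tracks: int
    n_rejected_r2: int
    n_nonpositive: int
    population: PopulationFit | None = None


def compute_msd(track: Track, frame_interval_s: float, max_lag: int) -> MSDCurve:
    """Time-averaged MSD with frame (not index) arithmetic.

    For lag n, all ordered pairs of members whose frame numbers differ by
    exactly n contribute, so pairs spanning a bridged gap at matching lag
    are used and non-matching lags are simply skipped.  Lags with no
    contributing pair are dropped.
    """
    n = len(track)
    if n < 2:
        raise ValueError("MSD needs a track with >=2 members")
    frames = np.asarray(track.frames, dtype=int)
    xy = track.positions_nm()
    lags, vals, counts = [], [], []
    for lag in range(1, min(max_lag, n - 1) + 1):
        # match frames f and f+lag
        target = frames + lag
        ia = np.nonzero(np.isin(target, frames))[0]
        if ia.size == 0:
            continue
        pos = {f: k for k, f in enumerate(frames)}
        ib = np.array([pos[frames[a] + lag] for a in ia])
        sq = ((xy[ib] - xy[ia]) ** 2).sum(axis=1)
        lags.append(lag * frame_interval_s)
        vals.append(float(np.mean(sq)) * NM2_TO_UM2)
        counts.append(int(ia.size))
    return MSDCurve(np.array(lags), np.array(vals), np.array(counts, dtype=int))


def fit_msd_linear(curve: MSDCurve, n_fit_points: int) -> tuple[float, float, float]:
    """OLS fit of the first ``n_fit_points`` MSD lags; D = slope/4.

    Returns (D_um2_per_s, intercept_um2, adjusted R^2).  The adjusted R^2
    is 1 - (1-R^2)(m-1)/(m-2) with m fit points; for m=2 (exact line) it
    is defined as R^2 itself.
    """
    if n_fit_points < 2:
        raise ValueError("n_fit_points must be >=2")
    if len(curve.lags_s) < n_fit_points:
        raise ValueError("MSD curve has fewer lags than n_fit_points")
    t = curve.lags_s[:n_fit_points]
    y = curve.values_um2[:n_fit_points]
    m = n_fit_points
    tm, ym = t.mean(), y.mean()
    sxx = float(np.sum((t - tm) ** 2))
    slope = float(np.sum((t - tm) * (y - ym)) / sxx)
    intercept = ym - slope * tm
    ss_res = float(np.sum((y - (slope * t + intercept)) ** 2))
    ss_tot = float(np.sum((y - ym) ** 2))
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    adj = r2 if m == 2 else 1.0 - (1.0 - r2) * (m - 1) / (m - 2)
    return slope / 4.0, intercept, adj


def mean_msd(
    tracks: list[Track], frame_interval_s: float, n_fit_points: int, max_lag: int = 10
) -> tuple[MSDCurve, float, float, float]:
    """Unweighted mean of per-track MSD values and a fit of the mean curve.

    A lag is retained only while at least 50% of the tracks contribute to
    it, trimming noisy tail lags.  Returns (curve, D_mean, intercept,
    adj_r2).
    """
    if not tracks:
        raise ValueError("mean MSD needs at least one track")
    per_lag: dict[float, list[float]] = {}
    for t in tracks:
        c = compute_msd(t, frame_interval_s, max_lag)
        for lag, v in zip(c.lags_s, c.values_um2):
            per_lag.setdefault(round(float(lag), 12), []).append(float(v))
    n_tracks = len(tracks)
    lags, vals, counts = [], [], []
    for lag in sorted(per_lag):
        contrib = per_lag[lag]
        if len(contrib) < 0.5 * n_tracks:
            break
        lags.append(lag)
        vals.append(float(np.mean(contrib)))
        counts.append(len(contrib))
    curve = MSDCurve(np.array(lags), np.array(vals), np.array(counts, dtype=int))
    d_mean, intercept, adj = fit_msd_linear(curve, n_fit_points)
    return curve, d_mean, intercept, adj


def per_track_mobility(
    tracks: list[Track],
    frame_interval_s: float,
    n_fit_points: int,
    adj_r2_min: float,
    max_lag: int = 10,
) -> tuple[list[TrackMobility], np.ndarray, int, int]:
    """Per-track D estimates and the accepted log10(D) sample.

    A track is accepted iff its linear MSD fit has adjusted R^2 >= the
    threshold AND positive slope.  Returns (per-track list, logD values
    of accepted tracks, n rejected for low adjusted R^2, n rejected for
    non-positive slope).  Tracks too short to fit count as low-R^2
    rejections with NaN D.
    """
    results: list[TrackMobility] = []
    logd: list[float] = []
    n_low_r2 = 0
    n_nonpos = 0
    for t in tracks:
        try:
            curve = compute_msd(t, frame_interval_s, max_lag)
            d, intercept, adj = fit_msd_linear(curve, n_fit_points)
        except ValueError:
            results.append(TrackMobility(t.track_id, float("nan"), float("nan"), float("nan"), False))
            n_low_r2 += 1
            continue
        accepted = bool(adj >= adj_r2_min and d > 0)
        if not accepted:
            if d <= 0:
                n_nonpos += 1
            else:
                n_low_r2 += 1
        else:
            logd.append(math.log10(d))
        results.append(TrackMobility(t.track_id, d, intercept, adj, accepted))
    return results, np.array(logd), n_low_r2, n_nonpos


# ---------------------------------------------------------------------------
# 1-D Gaussian mixture by EM (deterministic quantile inits)

_SD_FLOOR = 0.05
_QUANTILE_PAIRS = [(0.25, 0.75), (0.10, 0.90), (0.33, 0.67), (0.20, 0.80), (0.40, 0.60)]


def _gmm_em(x: np.ndarray, means0: np.ndarray, max_iter: int = 300, tol: float = 1e-9):
    k = len(means0)
    n = len(x)
    w = np.full(k, 1.0 / k)
    mu = means0.astype(float).copy()
    sd = np.full(k, max(float(np.std(x)), _SD_FLOOR))
    ll_prev = -np.inf
    for _ in range(max_iter):
        # E step in log space
        log_pdf = (
            -0.5 * ((x[None, :] - mu[:, None]) / sd[:, None]) ** 2
            - np.log(sd[:, None] * math.sqrt(2 * math.pi))
            + np.log(w[:, None])
        )
        mx = log_pdf.max(axis=0)
        lse = mx + np.log(np.exp(log_pdf - mx).sum(axis=0))
        resp = np.exp(log_pdf - lse)
        ll = float(lse.sum())
        # M step
        nk = resp.sum(axis=1) + 1e-300
        w = nk / n
        mu = (resp @ x) / nk
        var = (resp @ (x**2)) / nk - mu**2
        sd = np.sqrt(np.maximum(var, _SD_FLOOR**2))
        if abs(ll - ll_prev) < tol * (1 + abs(ll)):
            break
        ll_prev = ll
    return ll, w, mu, sd


def population_analysis(
    logD_values: np.ndarray,
    max_components: int = 2,
    threshold_logD: float = -2.0,
    n_immobile_extra: int = 0,
) -> PopulationFit:
    """Gaussian-mixture decomposition of the log10(D) distribution.

    Fits 1..``max_components`` components by maximum likelihood (EM with
    5 deterministic quantile-based starts, sd floored at 0.05 dex) and
    selects the component count by BIC.  ``peak_logD`` is the mean of the
    highest-weight component.  ``mobile_fraction`` is the fraction of
    values above ``threshold_logD``; ``n_immobile_extra`` adds tracks
    with non-positive fitted slope (log D undefined) to the immobile
    denominator.
    """
    x = np.asarray(logD_values, dtype=float)
    if x.size < 10:
        raise ValueError(
            "population analysis needs >=10 accepted tracks; aggregate more files"
        )
    bic: dict[int, float] = {}
    fits: dict[int, tuple[float, np.ndarray, np.ndarray, np.ndarray]] = {}
    n = x.size
    for k in range(1, max_components + 1):
        if k == 1:
            mu = np.array([float(np.mean(x))])
            sd = np.array([max(float(np.std(x)), _SD_FLOOR)])
            ll = float(
                np.sum(-0.5 * ((x - mu[0]) / sd[0]) ** 2 - math.log(sd[0] * math.sqrt(2 * math.pi)))
            )
            best = (ll, np.array([1.0]), mu, sd)
        else:
            best = None
            for qlo, qhi in _QUANTILE_PAIRS:
                means0 = np.quantile(x, [qlo, qhi])
                cand = _gmm_em(x, means0)
                if best is None or cand[0] > best[0]:
                    best = cand
        fits[k] = best
        n_params = 3 * k - 1
        bic[k] = -2.0 * best[0] + n_params * math.log(n)
    k_best = min(bic, key=lambda k: (bic[k], k))
    ll, w, mu, sd = fits[k_best]
    order = np.argsort(mu)
    comps = [(float(w[i]), float(mu[i]), float(sd[i])) for i in order]
    peak = comps[int(np.argmax([c[0] for c in comps]))][1]
    n_mobile = int(np.sum(x > threshold_logD))
    mobile_fraction = n_mobile / (n + n_immobile_extra)
    return PopulationFit(components=comps, peak_logD=peak, mobile_fraction=mobile_fraction, bic=bic)


def analyze_mobility(
    tracks: list[Track], frame_interval_s: float, p: MobilityParams
) -> MobilitySummary:
    """Full mobility stage: mean MSD, per-track D, populations."""
    curve, d_mean, intercept, adj = mean_msd(tracks, frame_interval_s, p.n_fit_points, p.max_lag)
    per_track, logd, n_low, n_nonpos = per_track_mobility(
        tracks, frame_interval_s, p.n_fit_points, p.adj_r2_min, p.max_lag
    )
    population = None
    if logd.size >= 10:
        population = population_analysis(
            logd, p.max_components, p.threshold_logD, n_immobile_extra=n_nonpos
        )
    return MobilitySummary(
        mean_curve=curve,
        D_mean_um2_per_s=d_mean,
        intercept_um2=intercept,
        adj_r2=adj,
        logD_values=logd,
        n_tracks=len(tracks),
        n_rejected_r2=n_low,
        n_nonpositive=n_nonpos,
        population=population,
    )


def write_mobility_table(per_track: list[TrackMobility], path) -> None:
    pd.DataFrame(
        {
            "track_id": [t.track_id for t in per_track],
            "D_um2_per_s": [t.D_um2_per_s for t in per_track],
            "intercept_um2": [t.intercept_um2 for t in per_track],
            "adj_r2": [t.adj_r2 for t in per_track],
            "accepted": [t.accepted for t in per_track],
        }
    ).to_csv(path, index=False, float_format="%.10g")
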