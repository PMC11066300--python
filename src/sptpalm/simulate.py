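"""Synthetic sptPALM data with known ground truth.

Generates movies (and matching dark-noise stacks) that emulate sparse
photoactivation experiments: molecules diffuse in 2-D (Brownian, one or
two mobility populations, reflecting field boundaries), switch through an
activation/blinking/bleaching schedule with geometric waiting times, and
are rendered as integrated-Gaussian PSF spots with Poisson shot noise on
an affine camera (offset, gain, Gaussian read noise, 16-bit clipping).

Also provides lighter-weight generators used by the downstream stages'
tests: bare Brownian track sets with localization noise, clustered
(Thomas) and completely random (CSR) point patterns, and hotspot-confined
track sets.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy.special import erf

from .camera import MovieStack, write_movie_stack
from .localize import LocalizationSet
from .track import Track

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_trajectories",
    "simulate_photophysics",
    "render_movie",
    "simulate",
    "write_ground_truth",
    "read_ground_truth",
    "render_spot",
    "simulate_track_set",
    "ground_truth_tracks_to_locs",
    "csr_points",
    "thomas_points",
    "simulate_hotspot_tracks",
    "FLUOROPHORE_PRESETS",
]

logger = logging.getLogger(__name__)

_SQRT2 = math.sqrt(2.0)

# Convenience presets differing only in brightness and on-time defaults;
# loosely styled after common photoconvertible/-activatable FPs, values
# are this package's choices, not measured properties.
FLUOROPHORE_PRESETS: dict[str, dict[str, float]] = {
    "mEos3.2-like": {"photons_per_frame": 800.0, "mean_on_frames": 20.0},
    "PA-GFP-like": {"photons_per_frame": 500.0, "mean_on_frames": 12.0},
    "PATagRFP-like": {"photons_per_frame": 600.0, "mean_on_frames": 15.0},
}


class CameraModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    offset_adu: float = 100.0
    e_per_adu: float = Field(0.5, gt=0)
    read_noise_adu: float = Field(2.0, ge=0)
    qe: float = Field(1.0, gt=0, le=1.0)


class ThomasLayout(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_parents: int = Field(20, ge=1)
    sigma_nm: float = Field(40.0, gt=0)
    background_fraction: float = Field(0.1, ge=0, le=1)


class SimulationConfig(BaseModel):
    """Study conditions for a synthetic acquisition.

    Defaults emulate a typical sparse sptPALM movie: 128x128 px at
    100 nm/px, 3000 frames at 20 Hz, ~800 detected photons per emitter
    per frame on a 10 photon/px background, PSF sigma 130 nm, and an
    equal mix of a near-immobile (0.001 um^2/s) and a mobile
    (0.05 um^2/s) population.
    """

    model_config = ConfigDict(extra="forbid")
    field_px: tuple[int, int] = (128, 128)  # (height, width)
    n_frames: int = Field(3000, ge=1)
    n_dark_frames: int = Field(500, ge=2)
    frame_interval_s: float = Field(0.05, gt=0)
    pixel_size_nm: float = Field(100.0, gt=0)
    populations: list[tuple[float, float]] = Field(
        default_factory=lambda: [(0.5, 0.001), (0.5, 0.05)]
    )  # (fraction, D um^2/s)
    n_molecules: int = Field(1500, ge=0)
    activation_rate_per_frame: float = Field(0.001, ge=0, le=1)
    mean_on_frames: float = Field(20.0, ge=1)
    p_blink_off: float = Field(0.1, ge=0, le=1)
    mean_dark_frames: float = Field(1.5, ge=1)
    p_bleach_per_frame: float = Field(0.02, ge=0, le=1)
    photons_per_frame: float = Field(800.0, gt=0)
    background_photons_per_px: float = Field(10.0, ge=0)
    psf_sigma_nm: float = Field(130.0, gt=0)
    camera: CameraModel = Field(default_factory=CameraModel)
    spatial_layout: Literal["uniform", "thomas"] = "uniform"
    thomas: ThomasLayout = Field(default_factory=ThomasLayout)
    confined_layout: bool = False
    confinement_radius_nm: float = Field(150.0, gt=0)
    rng_seed: int = 0

    @model_validator(mode="after")
    def _fractions(self) -> "SimulationConfig":
        total = sum(f for f, _ in self.populations)
        if abs(total - 1.0) > 1e-9:
            raise ValueError("population fractions must sum to 1")
        if any(f < 0 or d < 0 for f, d in self.populations):
            raise ValueError("population fractions and D must be non-negative")
        return self


@dataclass
class GroundTruth:
    """True molecule states and per-frame emissions of one simulation."""

    molecules: pd.DataFrame  # molecule_id, population, D_um2_per_s, x0_nm, y0_nm, parent_id, activation_frame
    emissions: pd.DataFrame  # molecule_id, frame (1-based), x_nm, y_nm, photons
    positions_nm: Optional[np.ndarray] = None  # (n_molecules, n_frames, 2), not serialized

    def tracks(self, min_length: int = 1) -> list[Track]:
        """Ground-truth trajectories restricted to emission frames."""
        out: list[Track] = []
        for mid, grp in self.emissions.groupby("molecule_id", sort=True):
            if len(grp) < min_length:
                continue
            grp = grp.sort_values("frame")
            out.append(
                Track(
                    track_id=int(mid),
                    frames=grp["frame"].to_numpy(dtype=int),
                    x_nm=grp["x_nm"].to_numpy(dtype=float),
                    y_nm=grp["y_nm"].to_numpy(dtype=float),
                    loc_indices=grp.index.to_numpy(),
                )
            )
        return out


def _reflect(p: np.ndarray, length: float) -> np.ndarray:
    q = np.mod(p, 2.0 * length)
    return np.where(q > length, 2.0 * length - q, q)


def simulate_trajectories(cfg: SimulationConfig, rng: np.random.Generator | None = None) -> GroundTruth:
    """Brownian trajectories for all molecules over all frames.

    Initial positions follow the spatial layout (uniform, or Thomas:
    Gaussian offspring around uniformly placed parents); each molecule
    takes per-axis steps of variance 2*D*dt with reflecting boundaries.
    With ``confined_layout`` molecules with a parent are clamped to a
    disc of ``confinement_radius_nm`` around it.
    """
    rng = np.random.default_rng(cfg.rng_seed) if rng is None else rng
    h_nm = cfg.field_px[0] * cfg.pixel_size_nm
    w_nm = cfg.field_px[1] * cfg.pixel_size_nm
    n = cfg.n_molecules

    fractions = np.array([f for f, _ in cfg.populations])
    d_values = np.array([d for _, d in cfg.populations])
    pop = rng.choice(len(fractions), size=n, p=fractions)
    d_nm2_per_s = d_values[pop] * 1e6  # um^2/s -> nm^2/s

    parent_id = np.full(n, -1, dtype=int)
    if cfg.spatial_layout == "thomas":
        parents = np.column_stack(
            [rng.uniform(0, w_nm, cfg.thomas.n_parents), rng.uniform(0, h_nm, cfg.thomas.n_parents)]
        )
        is_bg = rng.random(n) < cfg.thomas.background_fraction
        parent_id = np.where(is_bg, -1, rng.integers(0, cfg.thomas.n_parents, n))
        start = np.empty((n, 2))
        start[is_bg, 0] = rng.uniform(0, w_nm, int(is_bg.sum()))
        start[is_bg, 1] = rng.uniform(0, h_nm, int(is_bg.sum()))
        clustered = ~is_bg
        start[clustered] = parents[parent_id[clustered]] + rng.normal(
            0, cfg.thomas.sigma_nm, (int(clustered.sum()), 2)
        )
        start[:, 0] = _reflect(start[:, 0], w_nm)
        start[:, 1] = _reflect(start[:, 1], h_nm)
    else:
        parents = np.empty((0, 2))
        start = np.column_stack([rng.uniform(0, w_nm, n), rng.uniform(0, h_nm, n)])

    step_sd = np.sqrt(2.0 * d_nm2_per_s * cfg.frame_interval_s)  # per axis, nm
    steps = rng.normal(size=(n, cfg.n_frames - 1, 2)) * step_sd[:, None, None]
    pos = np.empty((n, cfg.n_frames, 2))
    pos[:, 0, :] = start
    if cfg.confined_layout and cfg.spatial_layout == "thomas":
        centers = np.where(parent_id[:, None] >= 0, parents[np.clip(parent_id, 0, None)], start)
        r = cfg.confinement_radius_nm
        for f in range(1, cfg.n_frames):
            p = pos[:, f - 1, :] + steps[:, f - 1, :]
            off = p - centers
            dist = np.linalg.norm(off, axis=1)
            out = dist > r
            if np.any(out):
                p[out] = centers[out] + off[out] * (r / dist[out])[:, None]
            pos[:, f, :] = p
        pos[..., 0] = _reflect(pos[..., 0], w_nm)
        pos[..., 1] = _reflect(pos[..., 1], h_nm)
    else:
        pos[:, 1:, :] = start[:, None, :] + np.cumsum(steps, axis=1)
        pos[..., 0] = _reflect(pos[..., 0], w_nm)
        pos[..., 1] = _reflect(pos[..., 1], h_nm)

    molecules = pd.DataFrame(
        {
            "molecule_id": np.arange(n, dtype=int),
            "population": pop.astype(int),
            "D_um2_per_s": d_values[pop],
            "x0_nm": pos[:, 0, 0] if n else np.array([]),
            "y0_nm": pos[:, 0, 1] if n else np.array([]),
            "parent_id": parent_id,
            "activation_frame": np.full(n, -1, dtype=int),
        }
    )
    emissions = pd.DataFrame(
        columns=["molecule_id", "frame", "x_nm", "y_nm", "photons"]
    ).astype({"molecule_id": int, "frame": int, "x_nm": float, "y_nm": float, "photons": float})
    return GroundTruth(molecules=molecules, emissions=emissions, positions_nm=pos)


def simulate_photophysics(
    cfg: SimulationConfig, gt: GroundTruth, rng: np.random.Generator | None = None
) -> GroundTruth:
    """Activation/blinking/bleaching schedule on top of the trajectories.

    Each molecule activates once (geometric waiting time), stays on for a
    geometric number of frames, may blink into geometric dark periods,
    and bleaches permanently; photons per on-frame are Poisson.
    """
    rng = np.random.default_rng(cfg.rng_seed + 1) if rng is None else rng
    if gt.positions_nm is None:
        raise ValueError("run simulate_trajectories first")
    n, n_frames = gt.positions_nm.shape[:2]
    rows_mid: list[int] = []
    rows_frame: list[int] = []
    act_frames = np.full(n, -1, dtype=int)
    p_act = cfg.activation_rate_per_frame
    for mol in range(n):
        if p_act <= 0:
            break
        f = int(rng.geometric(p_act)) - 1  # 0-based first on-frame
        if f >= n_frames:
            continue
        act_frames[mol] = f
        alive = True
        while alive and f < n_frames:
            rem_on = int(rng.geometric(1.0 / cfg.mean_on_frames))
            blinked = False
            for _ in range(rem_on):
                if f >= n_frames:
                    alive = False
                    break
                rows_mid.append(mol)
                rows_frame.append(f)
                f += 1
                if cfg.p_bleach_per_frame > 0 and rng.random() < cfg.p_bleach_per_frame:
                    alive = False
                    break
                if cfg.p_blink_off > 0 and rng.random() < cfg.p_blink_off:
                    f += int(rng.geometric(1.0 / cfg.mean_dark_frames))
                    blinked = True
                    break
            if not blinked and alive:
                alive = False  # on-time expired: end of this molecule's emission
    mid = np.array(rows_mid, dtype=int)
    frm = np.array(rows_frame, dtype=int)
    photons = rng.poisson(cfg.photons_per_frame, size=len(mid)).astype(float)
    xy = gt.positions_nm[mid, frm] if len(mid) else np.empty((0, 2))
    emissions = pd.DataFrame(
        {
            "molecule_id": mid,
            "frame": frm + 1,  # tables are 1-based
            "x_nm": xy[:, 0],
            "y_nm": xy[:, 1],
            "photons": photons,
        }
    )
    emissions = emissions.sort_values(["frame", "molecule_id"]).reset_index(drop=True)
    molecules = gt.molecules.copy()
    molecules["activation_frame"] = act_frames + 1  # 1-based, 0 = never activated
    return GroundTruth(molecules=molecules, emissions=emissions, positions_nm=gt.positions_nm)


def _render_emitters(
    expected: np.ndarray,
    x_px: np.ndarray,
    y_px: np.ndarray,
    photons: np.ndarray,
    sigma_px: float,
) -> None:
    """Add integrated-Gaussian spots to an expected-photon image in place."""
    h, w = expected.shape
    half = int(math.ceil(4.0 * sigma_px)) + 1
    for x, y, n_ph in zip(x_px, y_px, photons):
        c0 = max(int(math.floor(x)) - half, 0)
        c1 = min(int(math.floor(x)) + half + 1, w)
        r0 = max(int(math.floor(y)) - half, 0)
        r1 = min(int(math.floor(y)) + half + 1, h)
        if c1 <= c0 or r1 <= r0:
            continue
        ex = 0.5 * np.diff(erf((np.arange(c0, c1 + 1) - x) / (sigma_px * _SQRT2)))
        ey = 0.5 * np.diff(erf((np.arange(r0, r1 + 1) - y) / (sigma_px * _SQRT2)))
        expected[r0:r1, c0:c1] += n_ph * np.outer(ey, ex)


def render_movie(
    cfg: SimulationConfig, gt: GroundTruth, rng: np.random.Generator | None = None
) -> tuple[MovieStack, MovieStack]:
    """Render the emission schedule into a 16-bit movie plus dark stack.

    Expected photons per frame = sum of emitter PSFs + uniform
    background; detected ~ Poisson(expected * qe); counts =
    detected/e_per_adu + offset + Gaussian read noise, rounded and
    clipped to [0, 65535].
    """
    rng = np.random.default_rng(cfg.rng_seed + 2) if rng is None else rng
    h, w = cfg.field_px
    cam = cfg.camera
    sigma_px = cfg.psf_sigma_nm / cfg.pixel_size_nm
    frames = np.empty((cfg.n_frames, h, w), dtype=np.uint16)
    by_frame = dict(tuple(gt.emissions.groupby("frame"))) if len(gt.emissions) else {}
    n_clipped = 0
    for f in range(cfg.n_frames):
        expected = np.full((h, w), float(cfg.background_photons_per_px))
        grp = by_frame.get(f + 1)
        if grp is not None:
            _render_emitters(
                expected,
                grp["x_nm"].to_numpy() / cfg.pixel_size_nm,
                grp["y_nm"].to_numpy() / cfg.pixel_size_nm,
                grp["photons"].to_numpy(),
                sigma_px,
            )
        detected = rng.poisson(expected * cam.qe)
        adu = detected / cam.e_per_adu + cam.offset_adu + rng.normal(0.0, cam.read_noise_adu, (h, w))
        adu = np.rint(adu)
        n_clipped += int(np.sum((adu < 0) | (adu > 65535)))
        frames[f] = np.clip(adu, 0, 65535).astype(np.uint16)
    if n_clipped:
        logger.warning("render_movie: %d pixel values clipped to the 16-bit range", n_clipped)
    dark = np.rint(
        cam.offset_adu + rng.normal(0.0, cam.read_noise_adu, (cfg.n_dark_frames, h, w))
    )
    dark = np.clip(dark, 0, 65535).astype(np.uint16)
    movie = MovieStack(frames, cfg.pixel_size_nm, cfg.frame_interval_s, source_path="<simulated>")
    dark_stack = MovieStack(dark, cfg.pixel_size_nm, cfg.frame_interval_s, source_path="<simulated dark>")
    return movie, dark_stack


def simulate(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[MovieStack, MovieStack, GroundTruth]:
    """Trajectories -> photophysics -> rendering with one RNG stream."""
    rng = np.random.default_rng(cfg.rng_seed) if rng is None else rng
    gt = simulate_trajectories(cfg, rng)
    gt = simulate_photophysics(cfg, gt, rng)
    movie, dark = render_movie(cfg, gt, rng)
    return movie, dark, gt


def write_ground_truth(gt: GroundTruth, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gt.emissions.to_csv(out / "gt_emissions.csv", index=False, float_format="%.10g")
    gt.molecules.to_csv(out / "gt_molecules.csv", index=False, float_format="%.10g")


def read_ground_truth(out_dir: str | Path) -> GroundTruth:
    out = Path(out_dir)
    return GroundTruth(
        molecules=pd.read_csv(out / "gt_molecules.csv"),
        emissions=pd.read_csv(out / "gt_emissions.csv"),
    )


# ---------------------------------------------------------------------------
# Small generators for stage-level tests


def render_spot(
    photons: float,
    background: float,
    sigma_px: float,
    center_px: tuple[float, float],
    size: int,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One integrated-Gaussian spot on constant background, photon units.

    ``center_px`` is (x, y) in pixel coordinates (pixel j spans [j, j+1)).
    With an RNG the image is Poisson-sampled, otherwise noise-free.
    """
    expected = np.full((size, size), float(background))
    _render_emitters(
        expected,
        np.array([center_px[0]]),
        np.array([center_px[1]]),
        np.array([float(photons)]),
        sigma_px,
    )
    if rng is None:
        return expected
    return rng.poisson(expected).astype(float)


def simulate_track_set(
    n_tracks: int,
    n_steps: int,
    d_um2_per_s: float | Sequence[tuple[float, float]],
    frame_interval_s: float,
    loc_noise_nm: float = 0.0,
    rng: np.random.Generator | None = None,
    start_spacing_nm: float = 5000.0,
    start_jitter_nm: float = 0.0,
) -> tuple[list[Track], np.ndarray]:
    """Bare Brownian tracks with optional Gaussian localization noise.

    ``d_um2_per_s`` is a scalar or a list of (fraction, D) populations.
    Tracks start on a grid with ``start_spacing_nm`` spacing (keeps them
    well separated for tracking benchmarks).  Returns the tracks and the
    true per-track D values.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    if np.isscalar(d_um2_per_s):
        d_true = np.full(n_tracks, float(d_um2_per_s))
    else:
        fractions = np.array([f for f, _ in d_um2_per_s])
        ds = np.array([d for _, d in d_um2_per_s])
        counts = np.round(fractions * n_tracks).astype(int)
        counts[-1] = n_tracks - counts[:-1].sum()
        d_true = np.repeat(ds, counts)
    side = int(math.ceil(math.sqrt(n_tracks)))
    tracks: list[Track] = []
    n_pts = n_steps + 1
    for k in range(n_tracks):
        gx, gy = k % side, k // side
        start = np.array([(gx + 1) * start_spacing_nm, (gy + 1) * start_spacing_nm])
        if start_jitter_nm > 0:
            start = start + rng.uniform(-start_jitter_nm, start_jitter_nm, 2)
        sd = math.sqrt(2.0 * d_true[k] * 1e6 * frame_interval_s)
        steps = rng.normal(0.0, sd, (n_pts - 1, 2))
        pos = start + np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
        if loc_noise_nm > 0:
            pos = pos + rng.normal(0.0, loc_noise_nm, pos.shape)
        tracks.append(
            Track(
                track_id=k + 1,
                frames=np.arange(1, n_pts + 1),
                x_nm=pos[:, 0],
                y_nm=pos[:, 1],
                loc_indices=np.arange(n_pts),
            )
        )
    return tracks, d_true


def ground_truth_tracks_to_locs(
    tracks: list[Track],
    drop_fraction: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[LocalizationSet, np.ndarray]:
    """Flatten tracks into a LocalizationSet, optionally dropping detections.

    Emulates single-frame blinking dropouts: each interior localization is
    removed with probability ``drop_fraction`` except directly after
    another dropout, so every gap is exactly one frame long (the regime
    that single-gap closing is built for); endpoints are kept so the
    ground-truth track count is unchanged.  Returns the set and the true
    molecule id per remaining row.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    rows = []
    owner = []
    for t in tracks:
        keep = np.ones(len(t), dtype=bool)
        if drop_fraction > 0:
            for i in range(1, len(t) - 1):
                if keep[i - 1] and rng.random() < drop_fraction:
                    keep[i] = False
        for f, x, y in zip(t.frames[keep], t.x_nm[keep], t.y_nm[keep]):
            rows.append((int(f), float(x), float(y)))
            owner.append(t.track_id)
    df = pd.DataFrame(rows, columns=["frame", "x_nm", "y_nm"])
    order = np.lexsort((np.arange(len(df)), df["frame"].to_numpy()))
    df = df.iloc[order].reset_index(drop=True)
    owner_arr = np.asarray(owner)[order]
    df["sigma_nm"] = 130.0
    df["photons"] = 1000.0
    df["background_photons"] = 10.0
    df["precision_nm"] = 10.0
    df["converged"] = True
    return LocalizationSet(df=df, source="<synthetic tracks>"), owner_arr


def csr_points(n: int, field_nm: tuple[float, float], rng: np.random.Generator) -> np.ndarray:
    """Complete spatial randomness: n uniform points on the field."""
    return np.column_stack([rng.uniform(0, field_nm[0], n), rng.uniform(0, field_nm[1], n)])


def thomas_points(
    n_parents: int,
    pts_per_parent: int,
    sigma_nm: float,
    field_nm: tuple[float, float],
    background_fraction: float,
    rng: np.random.Generator,
    min_parent_sep_nm: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Thomas process: Gaussian offspring around uniform parent centres.

    Returns (points, parent index per point; -1 for background points).
    """
    parents = np.column_stack(
        [rng.uniform(0, field_nm[0], n_parents), rng.uniform(0, field_nm[1], n_parents)]
    )
    if min_parent_sep_nm > 0:
        for _ in range(200):
            d = np.linalg.norm(parents[:, None] - parents[None, :], axis=2)
            np.fill_diagonal(d, np.inf)
            bad = np.nonzero(d.min(axis=1) < min_parent_sep_nm)[0]
            if bad.size == 0:
                break
            parents[bad] = np.column_stack(
                [rng.uniform(0, field_nm[0], bad.size), rng.uniform(0, field_nm[1], bad.size)]
            )
    pts = []
    parent_ids = []
    for k in range(n_parents):
        offspring = parents[k] + rng.normal(0, sigma_nm, (pts_per_parent, 2))
        pts.append(offspring)
        parent_ids.extend([k] * pts_per_parent)
    n_bg = int(round(background_fraction * n_parents * pts_per_parent))
    if n_bg:
        pts.append(csr_points(n_bg, field_nm, rng))
        parent_ids.extend([-1] * n_bg)
    return np.vstack(pts), np.asarray(parent_ids, dtype=int)


def simulate_hotspot_tracks(
    n_hotspots: int,
    tracks_per_hotspot: int,
    n_free: int,
    field_nm: tuple[float, float],
    hotspot_radius_nm: float,
    n_steps: int,
    d_um2_per_s: float,
    frame_interval_s: float,
    rng: np.random.Generator,
    min_hotspot_sep_nm: float | None = None,
) -> tuple[list[Track], np.ndarray]:
    """Confined tracks in well-separated hotspots plus free tracks.

    Returns (tracks, hotspot id per track; -1 for free tracks).  Used by
    the NASTIC benchmarks: all tracks of one hotspot stay within its
    disc, so their bounding boxes overlap.
    """
    if min_hotspot_sep_nm is None:
        min_hotspot_sep_nm = 8.0 * hotspot_radius_nm
    centers = np.empty((n_hotspots, 2))
    placed = 0
    for _ in range(10000):
        if placed == n_hotspots:
            break
        cand = np.array(
            [
                rng.uniform(2 * hotspot_radius_nm, field_nm[0] - 2 * hotspot_radius_nm),
                rng.uniform(2 * hotspot_radius_nm, field_nm[1] - 2 * hotspot_radius_nm),
            ]
        )
        if placed == 0 or np.all(np.linalg.norm(centers[:placed] - cand, axis=1) >= min_hotspot_sep_nm):
            centers[placed] = cand
            placed += 1
    if placed < n_hotspots:
        raise ValueError("could not place hotspots with the requested separation")
    sd = math.sqrt(2.0 * d_um2_per_s * 1e6 * frame_interval_s)
    tracks: list[Track] = []
    hotspot_of: list[int] = []
    tid = 0
    n_pts = n_steps + 1
    for k in range(n_hotspots):
        for _ in range(tracks_per_hotspot):
            tid += 1
            pos = np.empty((n_pts, 2))
            pos[0] = centers[k] + rng.normal(0, hotspot_radius_nm / 3.0, 2)
            for s in range(1, n_pts):
                step = pos[s - 1] + rng.normal(0, sd, 2)
                off = step - centers[k]
                dist = float(np.linalg.norm(off))
                if dist > hotspot_radius_nm:
                    step = centers[k] + off * hotspot_radius_nm / dist
                pos[s] = step
            tracks.append(
                Track(tid, np.arange(1, n_pts + 1), pos[:, 0], pos[:, 1], np.arange(n_pts))
            )
            hotspot_of.append(k)
    for _ in range(n_free):
        tid += 1
        start = np.array([rng.uniform(0, field_nm[0]), rng.uniform(0, field_nm[1])])
        steps = rng.normal(0, sd, (n_pts - 1, 2))
        pos = start + np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
        tracks.append(Track(tid, np.arange(1, n_pts + 1), pos[:, 0], pos[:, 1], np.arange(n_pts)))
        hotspot_of.append(-1)
    return tracks, np.asarray(hotspot_of, dtype=int)
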