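"""Trajectory building: LAP frame-to-frame linking plus gap closing.

Localizations in successive frames are connected by solving a linear
assignment problem per frame pair: linking costs are squared distances
for pairs within the maximum linking distance, and every localization has
a non-link (birth/death) alternative with fixed cost
``(1.05 * max_link_distance)^2``.  A second global assignment between
segment ends and later segment starts bridges short detection gaps
(fluorophore blinking); bridged frames are recorded, never interpolated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .camera import FormatError, RegionMask
from .localize import LocalizationSet
from .params import TrackingParams

__all__ = [
    "Track",
    "link_frames",
    "close_gaps",
    "apply_mask",
    "filter_tracks",
    "write_tracks",
    "read_tracks",
]

_BIG = 1e15
_ALT_FACTOR = 1.05  # non-link alternative cost = (1.05 * max distance)^2


@dataclass
class Track:
    """One molecule's ordered localizations; frames strictly increasing."""

    track_id: int
    frames: np.ndarray  # 1-based frame numbers
    x_nm: np.ndarray
    y_nm: np.ndarray
    loc_indices: np.ndarray  # row indices into the source LocalizationSet
    gaps: list[int] = field(default_factory=list)  # bridged frame numbers

    def __len__(self) -> int:
        return len(self.frames)

    def positions_nm(self) -> np.ndarray:
        return np.column_stack([self.x_nm, self.y_nm])

    def centroid_nm(self) -> tuple[float, float]:
        return float(np.mean(self.x_nm)), float(np.mean(self.y_nm))


def _solve_lap(points_a: np.ndarray, points_b: np.ndarray, max_dist: float) -> list[tuple[int, int]]:
    """Globally optimal links between two point sets.

    Square Jaqaman-style cost matrix: top-left link costs (squared
    distance, gated at ``max_dist``), diagonal birth/death alternatives at
    ``(1.05*max_dist)^2``, and a lower-right mirror block so a perfect
    matching always exists.  Ties are broken deterministically by
    ``linear_sum_assignment`` on the row-ordered matrix.
    """
    n, m = len(points_a), len(points_b)
    if n == 0 or m == 0:
        return []
    d2 = ((points_a[:, None, :] - points_b[None, :, :]) ** 2).sum(axis=2)
    link = np.where(d2 <= max_dist**2, d2, _BIG)
    alt = (_ALT_FACTOR * max_dist) ** 2
    cost = np.full((n + m, n + m), _BIG)
    cost[:n, :m] = link
    cost[np.arange(n), m + np.arange(n)] = alt
    cost[n + np.arange(m), np.arange(m)] = alt
    cost[n:, m:] = np.where(link.T < _BIG, 0.0, _BIG)
    rows, cols = linear_sum_assignment(cost)
    return [(int(r), int(c)) for r, c in zip(rows, cols) if r < n and c < m and link[r, c] < _BIG]


def link_frames(locs: LocalizationSet, p: TrackingParams) -> list[Track]:
    """Frame-to-frame linking into gap-free segments.

    Only localizations in frames t and t+1 are candidates for a direct
    link; every localization ends up in exactly one segment (possibly a
    singleton).  Deterministic given input order.
    """
    df = locs.df
    n_locs = len(df)
    if n_locs == 0:
        return []
    frames = df["frame"].to_numpy(dtype=int)
    xy = df[["x_nm", "y_nm"]].to_numpy(dtype=float)
    order = np.argsort(frames, kind="stable")
    by_frame: dict[int, np.ndarray] = {}
    for f in np.unique(frames):
        by_frame[int(f)] = order[frames[order] == f]

    next_link = np.full(n_locs, -1, dtype=int)
    has_prev = np.zeros(n_locs, dtype=bool)
    frame_values = sorted(by_frame)
    for f in frame_values:
        if f + 1 not in by_frame:
            continue
        ia, ib = by_frame[f], by_frame[f + 1]
        for a, b in _solve_lap(xy[ia], xy[ib], p.max_link_distance_nm):
            next_link[ia[a]] = ib[b]
            has_prev[ib[b]] = True

    segments: list[Track] = []
    for i in range(n_locs):
        if has_prev[i]:
            continue
        chain = [i]
        while next_link[chain[-1]] >= 0:
            chain.append(next_link[chain[-1]])
        idx = np.array(chain, dtype=int)
        segments.append(
            Track(
                track_id=len(segments) + 1,
                frames=frames[idx].copy(),
                x_nm=xy[idx, 0].copy(),
                y_nm=xy[idx, 1].copy(),
                loc_indices=idx,
            )
        )
    return segments


def close_gaps(segments: list[Track], p: TrackingParams) -> list[Track]:
    """Bridge blinking gaps by a global end-to-start assignment.

    A segment end may connect to a later segment start when the frame gap
    is in ``[2, max_gap_frames+1]`` and the distance is at most
    ``max_gap_distance_nm`` (cost = squared distance, alternative cost
    ``(1.05*max_gap_distance)^2``).  Accepted pairs are concatenated; the
    bridged frame numbers are recorded in ``gaps``.
    """
    if p.max_gap_frames == 0 or len(segments) < 2:
        return [_reid(s, i + 1) for i, s in enumerate(segments)]
    n = len(segments)
    ends = np.array([[s.x_nm[-1], s.y_nm[-1]] for s in segments])
    starts = np.array([[s.x_nm[0], s.y_nm[0]] for s in segments])
    end_f = np.array([s.frames[-1] for s in segments])
    start_f = np.array([s.frames[0] for s in segments])

    d2 = ((ends[:, None, :] - starts[None, :, :]) ** 2).sum(axis=2)
    gap = start_f[None, :] - end_f[:, None]
    feasible = (gap >= 2) & (gap <= p.max_gap_frames + 1) & (d2 <= p.max_gap_distance_nm**2)
    link = np.where(feasible, d2, _BIG)
    alt = (_ALT_FACTOR * p.max_gap_distance_nm) ** 2
    cost = np.full((2 * n, 2 * n), _BIG)
    cost[:n, :n] = link
    cost[np.arange(n), n + np.arange(n)] = alt
    cost[n + np.arange(n), np.arange(n)] = alt
    cost[n:, n:] = np.where(link.T < _BIG, 0.0, _BIG)
    rows, cols = linear_sum_assignment(cost)
    successor = {r: c for r, c in zip(rows, cols) if r < n and c < n and link[r, c] < _BIG}

    merged: list[Track] = []
    has_pred = set(successor.values())
    for i in range(n):
        if i in has_pred:
            continue
        chain = [i]
        while chain[-1] in successor:
            chain.append(successor[chain[-1]])
        parts = [segments[j] for j in chain]
        gaps: list[int] = []
        for a, b in zip(parts[:-1], parts[1:]):
            gaps.extend(range(int(a.frames[-1]) + 1, int(b.frames[0])))
        merged.append(
            Track(
                track_id=len(merged) + 1,
                frames=np.concatenate([t.frames for t in parts]),
                x_nm=np.concatenate([t.x_nm for t in parts]),
                y_nm=np.concatenate([t.y_nm for t in parts]),
                loc_indices=np.concatenate([t.loc_indices for t in parts]),
                gaps=gaps,
            )
        )
    return merged


def _reid(t: Track, new_id: int) -> Track:
    return Track(
        track_id=new_id, frames=t.frames, x_nm=t.x_nm, y_nm=t.y_nm,
        loc_indices=t.loc_indices, gaps=list(t.gaps),
    )


def apply_mask(
    tracks: list[Track], mask: RegionMask, pixel_size_nm: float
) -> tuple[list[Track], int]:
    """Drop any track with at least one member in an excluded pixel.

    Positions outside the mask grid count as excluded.  Returns the kept
    tracks (re-numbered) and the number removed.
    """
    inc = mask.include
    h, w = inc.shape
    kept: list[Track] = []
    removed = 0
    for t in tracks:
        cols = np.floor(t.x_nm / pixel_size_nm).astype(int)
        rows = np.floor(t.y_nm / pixel_size_nm).astype(int)
        inside = (rows >= 0) & (rows < h) & (cols >= 0) & (cols < w)
        ok = inside & inc[np.clip(rows, 0, h - 1), np.clip(cols, 0, w - 1)]
        if np.all(ok):
            kept.append(_reid(t, len(kept) + 1))
        else:
            removed += 1
    return kept, removed


def filter_tracks(tracks: list[Track], p: TrackingParams) -> list[Track]:
    """Keep tracks with at least ``min_track_length`` localizations."""
    kept = [t for t in tracks if len(t) >= p.min_track_length]
    return [_reid(t, i + 1) for i, t in enumerate(kept)]


def write_tracks(tracks: list[Track], path: str | Path) -> None:
    rows = {
        "track_id": np.concatenate([np.full(len(t), t.track_id, dtype=int) for t in tracks]) if tracks else [],
        "frame": np.concatenate([t.frames for t in tracks]) if tracks else [],
        "x_nm": np.concatenate([t.x_nm for t in tracks]) if tracks else [],
        "y_nm": np.concatenate([t.y_nm for t in tracks]) if tracks else [],
    }
    pd.DataFrame(rows).to_csv(Path(path), index=False, float_format="%.10g")


def read_tracks(path: str | Path) -> list[Track]:
    df = pd.read_csv(Path(path))
    required = ["track_id", "frame", "x_nm", "y_nm"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"track table missing columns: {missing}")
    tracks: list[Track] = []
    for tid, grp in df.groupby("track_id", sort=True):
        grp = grp.sort_values("frame")
        frames = grp["frame"].to_numpy(dtype=int)
        if len(frames) > 1 and np.any(np.diff(frames) <= 0):
            raise FormatError(f"track {tid}: frames not strictly increasing")
        tracks.append(
            Track(
                track_id=int(tid),
                frames=frames,
                x_nm=grp["x_nm"].to_numpy(dtype=float),
                y_nm=grp["y_nm"].to_numpy(dtype=float),
                loc_indices=grp.index.to_numpy(),
                gaps=[int(f) for f in range(frames[0], frames[-1] + 1) if f not in set(frames)],
            )
        )
    return tracks
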