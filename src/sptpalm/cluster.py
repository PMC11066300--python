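"""Nanoscale cluster analysis: Voronoi tessellation, DBSCAN and NASTIC.

Point-based methods (Voronoi, DBSCAN) run on either all filtered
localizations or one centroid per track; NASTIC runs on the tracks
themselves, grouping trajectories whose expanded bounding boxes overlap
(found with an STR-tree spatial index, equal by construction to the
all-pairs intersection graph).  All geometry is in nm internally; areas
are reported in um^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, Voronoi, cKDTree
from scipy.spatial import QhullError
from shapely import STRtree, box

from .localize import LocalizationSet
from .params import DBSCANParams, NASTICParams, VoronoiParams
from .track import Track

__all__ = [
    "ClusterInput",
    "Cluster",
    "ClusterResult",
    "make_cluster_input",
    "cluster_dbscan",
    "cluster_voronoi",
    "cluster_nastic",
    "cluster_metrics",
]

NM2_TO_UM2 = 1e-6


@dataclass
class ClusterInput:
    mode: Literal["all_localizations", "track_centroids", "tracks"]
    points: Optional[np.ndarray] = None  # (n, 2) nm, point modes
    tracks: Optional[list[Track]] = None  # NASTIC mode

    @property
    def n(self) -> int:
        return len(self.tracks) if self.mode == "tracks" else len(self.points)


@dataclass
class Cluster:
    cluster_id: int
    member_ids: np.ndarray
    centroid_nm: tuple[float, float]
    area_um2: float
    diameter_nm: float
    n_members: int


@dataclass
class ClusterResult:
    algorithm: str
    parameters: dict
    clusters: list[Cluster]
    noise_ids: np.ndarray
    n_input: int

    @property
    def clustered_fraction(self) -> float:
        if self.n_input == 0:
            return 0.0
        return sum(c.n_members for c in self.clusters) / self.n_input


def make_cluster_input(
    locs: LocalizationSet | None,
    tracks: list[Track] | None,
    mode: str,
) -> ClusterInput:
    """Assemble the working set for a clustering run.

    ``all_localizations`` uses every filtered localization;
    ``track_centroids`` one unweighted mean position per track (one
    cluster point per detected molecule); ``tracks`` passes trajectories
    through for NASTIC.
    """
    if mode == "all_localizations":
        if locs is None:
            raise ValueError("all_localizations mode needs a LocalizationSet")
        return ClusterInput(mode=mode, points=locs.positions_nm())
    if mode == "track_centroids":
        if tracks is None:
            raise ValueError("track_centroids mode needs tracks")
        pts = np.array([t.centroid_nm() for t in tracks]).reshape(-1, 2)
        return ClusterInput(mode=mode, points=pts)
    if mode == "tracks":
        if tracks is None:
            raise ValueError("tracks mode needs tracks")
        return ClusterInput(mode=mode, tracks=tracks)
    raise ValueError(f"unknown cluster input mode: {mode}")


def _hull_metrics(points: np.ndarray) -> tuple[tuple[float, float], float, float]:
    """Centroid, convex-hull area (um^2) and equivalent diameter (nm)."""
    centroid = (float(points[:, 0].mean()), float(points[:, 1].mean()))
    if len(points) < 3:
        return centroid, 0.0, 0.0
    try:
        hull = ConvexHull(points)
        area_nm2 = float(hull.volume)  # in 2-D, .volume is the area
    except QhullError:  # collinear members: degenerate, zero area
        area_nm2 = 0.0
    area_um2 = area_nm2 * NM2_TO_UM2
    diameter_nm = 2.0 * math.sqrt(area_nm2 / math.pi)
    return centroid, area_um2, diameter_nm


def _build_point_result(
    algorithm: str, parameters: dict, points: np.ndarray, labels: np.ndarray
) -> ClusterResult:
    clusters = []
    for cid in sorted(set(labels[labels >= 0])):
        members = np.nonzero(labels == cid)[0]
        centroid, area, diam = _hull_metrics(points[members])
        clusters.append(
            Cluster(
                cluster_id=int(cid),
                member_ids=members,
                centroid_nm=centroid,
                area_um2=area,
                diameter_nm=diam,
                n_members=len(members),
            )
        )
    return ClusterResult(
        algorithm=algorithm,
        parameters=parameters,
        clusters=clusters,
        noise_ids=np.nonzero(labels < 0)[0],
        n_input=len(points),
    )


# ---------------------------------------------------------------------------
# DBSCAN


def dbscan_labels(points: np.ndarray, eps_nm: float, min_pts: int) -> np.ndarray:
    """Canonical DBSCAN labels (-1 = noise), deterministic.

    A core point has >= ``min_pts`` neighbours within eps (itself
    included).  Clusters are the density-connected components of core
    points, numbered 1.. in order of their lowest core-point index;
    border points reachable from several clusters join the one with the
    lowest cluster id.
    """
    n = len(points)
    labels = np.full(n, -1, dtype=int)
    if n == 0:
        return labels
    tree = cKDTree(points)
    neighbors = tree.query_ball_point(points, r=eps_nm)
    core = np.array([len(nb) >= min_pts for nb in neighbors])
    cid = 0
    for i in range(n):
        if not core[i] or labels[i] >= 0:
            continue
        cid += 1
        labels[i] = cid
        stack = [i]
        while stack:
            j = stack.pop()
            for k in neighbors[j]:
                if core[k] and labels[k] < 0:
                    labels[k] = cid
                    stack.append(k)
    # border points: lowest neighbouring core cluster id wins
    for i in range(n):
        if labels[i] >= 0 or core[i]:
            continue
        core_labels = [labels[k] for k in neighbors[i] if core[k]]
        if core_labels:
            labels[i] = min(core_labels)
    return labels


def cluster_dbscan(input: ClusterInput, p: DBSCANParams) -> ClusterResult:
    if input.points is None:
        raise ValueError("DBSCAN needs a point-mode ClusterInput")
    labels = dbscan_labels(np.asarray(input.points, dtype=float), p.eps_nm, p.min_pts)
    return _build_point_result(
        "dbscan", {"eps_nm": p.eps_nm, "min_pts": p.min_pts}, input.points, labels
    )


# ---------------------------------------------------------------------------
# Voronoi


def _polygon_area(vertices: np.ndarray) -> float:
    x, y = vertices[:, 0], vertices[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def cluster_voronoi(input: ClusterInput, p: VoronoiParams) -> ClusterResult:
    """Voronoi-tessellation clustering with first-rank local densities.

    Each point's local density is the neighbour-averaged first-rank
    density ``(1 + #valid neighbours) / (own cell area + neighbour cell
    areas)``; cells unbounded or extending past the analysis rectangle
    (tight bounding box of the points, grown by 2%) cannot seed clusters.
    Seeds are points whose density exceeds ``density_factor`` times the
    mean density n/rectangle-area; clusters are connected components of
    seeds whose cells share an edge, and components below ``min_pts``
    members drop to noise.  The neighbour averaging suppresses the large
    single-cell area fluctuations of a homogeneous Poisson pattern, which
    would otherwise seed spurious clusters.
    """
    if input.points is None:
        raise ValueError("Voronoi clustering needs a point-mode ClusterInput")
    points = np.asarray(input.points, dtype=float)
    n = len(points)
    if n < 4:
        raise ValueError("Voronoi clustering needs >=4 points")
    try:
        vor = Voronoi(points)
    except QhullError as exc:
        raise ValueError(f"degenerate point geometry for Voronoi tessellation: {exc}") from exc

    lo = points.min(axis=0)
    hi = points.max(axis=0)
    span = np.maximum(hi - lo, 1e-9)
    lo_r = lo - 0.01 * span
    hi_r = hi + 0.01 * span
    rect_area = float(np.prod(hi_r - lo_r))
    mean_density = n / rect_area

    cell_area = np.full(n, np.nan)
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or len(region) < 3:
            continue
        verts = vor.vertices[region]
        if np.any(verts[:, 0] < lo_r[0]) or np.any(verts[:, 0] > hi_r[0]) or np.any(
            verts[:, 1] < lo_r[1]
        ) or np.any(verts[:, 1] > hi_r[1]):
            continue
        area = _polygon_area(verts)
        if area > 0:
            cell_area[i] = area

    neighbours: list[list[int]] = [[] for _ in range(n)]
    for (i, j) in vor.ridge_points:
        neighbours[i].append(int(j))
        neighbours[j].append(int(i))

    density = np.zeros(n)
    eligible = np.isfinite(cell_area)
    for i in range(n):
        if not eligible[i]:
            continue
        areas = [cell_area[i]] + [cell_area[j] for j in neighbours[i] if np.isfinite(cell_area[j])]
        density[i] = len(areas) / float(np.sum(areas))

    seed = eligible & (density >= p.density_factor * mean_density)

    parent = np.arange(n)

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for (i, j) in vor.ridge_points:
        if seed[i] and seed[j]:
            ri, rj = find(int(i)), find(int(j))
            if ri != rj:
                parent[max(ri, rj)] = min(ri, rj)

    labels = np.full(n, -1, dtype=int)
    comp_members: dict[int, list[int]] = {}
    for i in range(n):
        if seed[i]:
            comp_members.setdefault(find(i), []).append(i)
    cid = 0
    for root in sorted(comp_members):
        members = comp_members[root]
        if len(members) < p.min_pts:
            continue
        cid += 1
        labels[np.array(members)] = cid
    return _build_point_result(
        "voronoi",
        {"density_factor": p.density_factor, "min_pts": p.min_pts},
        points,
        labels,
    )


# ---------------------------------------------------------------------------
# NASTIC


def track_bounding_boxes(tracks: list[Track], radius_factor: float) -> np.ndarray:
    """Axis-aligned track bounding boxes expanded about their centres.

    Returns (n, 4) array of (xmin, ymin, xmax, ymax) in nm; each box's
    half-width/height is multiplied by ``radius_factor``.
    """
    out = np.empty((len(tracks), 4))
    for k, t in enumerate(tracks):
        xmin, xmax = float(t.x_nm.min()), float(t.x_nm.max())
        ymin, ymax = float(t.y_nm.min()), float(t.y_nm.max())
        cx, cy = 0.5 * (xmin + xmax), 0.5 * (ymin + ymax)
        hx, hy = radius_factor * 0.5 * (xmax - xmin), radius_factor * 0.5 * (ymax - ymin)
        out[k] = (cx - hx, cy - hy, cx + hx, cy + hy)
    return out


def cluster_nastic(
    input: ClusterInput, p: NASTICParams, frame_interval_s: float = 1.0
) -> ClusterResult:
    """Spatio(-temporal) indexing clustering of whole trajectories.

    Tracks are connected when their expanded bounding boxes intersect
    (touching counts) and, if ``temporal_window_s`` is set, their time
    intervals come within that window.  Connected components with at
    least ``min_tracks`` tracks are clusters; members are tracks, and the
    geometry metrics are computed on the union of member localizations.
    Candidate pairs come from an STR-tree spatial index; the resulting
    graph equals the all-pairs box-intersection graph.
    """
    if input.tracks is None:
        raise ValueError("NASTIC needs a tracks-mode ClusterInput")
    tracks = input.tracks
    n = len(tracks)
    boxes = track_bounding_boxes(tracks, p.radius_factor)
    geoms = [box(*b) for b in boxes]
    tree = STRtree(geoms)

    parent = np.arange(n)

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    times = None
    if p.temporal_window_s is not None:
        times = np.array([[t.frames[0], t.frames[-1]] for t in tracks], dtype=float)

    for i in range(n):
        for j in tree.query(geoms[i], predicate="intersects"):
            j = int(j)
            if j <= i:
                continue
            if times is not None:
                gap_frames = max(times[j, 0] - times[i, 1], times[i, 0] - times[j, 1], 0.0)
                if gap_frames * frame_interval_s > p.temporal_window_s:
                    continue
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[max(ri, rj)] = min(ri, rj)

    comp: dict[int, list[int]] = {}
    for i in range(n):
        comp.setdefault(find(i), []).append(i)
    clusters: list[Cluster] = []
    noise: list[int] = []
    cid = 0
    for root in sorted(comp):
        members = comp[root]
        if len(members) < p.min_tracks:
            noise.extend(members)
            continue
        cid += 1
        pts = np.vstack([tracks[m].positions_nm() for m in members])
        centroid, area, diam = _hull_metrics(pts)
        clusters.append(
            Cluster(
                cluster_id=cid,
                member_ids=np.array(sorted(members)),
                centroid_nm=centroid,
                area_um2=area,
                diameter_nm=diam,
                n_members=len(members),
            )
        )
    return ClusterResult(
        algorithm="nastic",
        parameters={
            "radius_factor": p.radius_factor,
            "min_tracks": p.min_tracks,
            "temporal_window_s": p.temporal_window_s,
        },
        clusters=clusters,
        noise_ids=np.array(sorted(noise), dtype=int),
        n_input=n,
    )


def cluster_metrics(result: ClusterResult) -> tuple[pd.DataFrame, dict]:
    """Per-cluster metric rows plus a global summary."""
    rows = [
        {
            "cluster_id": c.cluster_id,
            "n_members": c.n_members,
            "centroid_x_nm": c.centroid_nm[0],
            "centroid_y_nm": c.centroid_nm[1],
            "area_um2": c.area_um2,
            "diameter_nm": c.diameter_nm,
            "degenerate": c.area_um2 == 0.0,
        }
        for c in result.clusters
    ]
    df = pd.DataFrame(
        rows,
        columns=[
            "cluster_id", "n_members", "centroid_x_nm", "centroid_y_nm",
            "area_um2", "diameter_nm", "degenerate",
        ],
    )
    summary = {
        "n_clusters": len(result.clusters),
        "median_diameter_nm": float(np.median(df["diameter_nm"])) if len(df) else float("nan"),
        "clustered_fraction": result.clustered_fraction,
    }
    return df, summary
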