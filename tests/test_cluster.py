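"""Cluster analysis: DBSCAN, Voronoi tessellation and NASTIC."""

import numpy as np
import pytest

from sptpalm.cluster import (
    ClusterInput,
    cluster_dbscan,
    cluster_metrics,
    cluster_nastic,
    cluster_voronoi,
    dbscan_labels,
    make_cluster_input,
    track_bounding_boxes,
)
from sptpalm.localize import LocalizationSet
from sptpalm.params import DBSCANParams, NASTICParams, VoronoiParams
from sptpalm.simulate import csr_points, simulate_hotspot_tracks, simulate_track_set, thomas_points
from sptpalm.track import Track


def _points_input(points):
    return ClusterInput(mode="all_localizations", points=np.asarray(points, dtype=float))


def _brute_force_dbscan(points, eps, min_pts):
    """Independent O(n^2) reference: explicit neighbourhood expansion with
    the same border tie-break (lowest cluster id)."""
    n = len(points)
    d = np.linalg.norm(points[:, None] - points[None, :], axis=2)
    nbrs = [np.nonzero(d[i] <= eps)[0].tolist() for i in range(n)]
    core = [len(nb) >= min_pts for nb in nbrs]
    labels = [-1] * n
    cid = 0
    for i in range(n):
        if not core[i] or labels[i] >= 0:
            continue
        cid += 1
        frontier = [i]
        labels[i] = cid
        while frontier:
            j = frontier.pop()
            for k in nbrs[j]:
                if core[k] and labels[k] < 0:
                    labels[k] = cid
                    frontier.append(k)
    for i in range(n):
        if labels[i] < 0 and not core[i]:
            owners = [labels[k] for k in nbrs[i] if core[k]]
            if owners:
                labels[i] = min(owners)
    return np.array(labels)


class TestClusterInput:
    def test_track_centroid(self):
        t = Track(1, np.array([1, 2]), np.array([0.0, 100.0]), np.array([0.0, 0.0]), np.arange(2))
        ci = make_cluster_input(None, [t], "track_centroids")
        np.testing.assert_allclose(ci.points, [[50.0, 0.0]])

    def test_counts_per_mode(self, rng):
        tracks, _ = simulate_track_set(4, 5, 0.01, 0.05, 0, rng)
        import pandas as pd

        df = pd.DataFrame(
            {
                "frame": [1, 1, 2],
                "x_nm": [0.0, 10.0, 20.0],
                "y_nm": [0.0, 10.0, 20.0],
                "sigma_nm": 130.0,
                "photons": 500.0,
                "background_photons": 5.0,
                "precision_nm": 10.0,
                "converged": True,
            }
        )
        locs = LocalizationSet(df=df)
        assert make_cluster_input(locs, tracks, "all_localizations").n == 3
        assert make_cluster_input(locs, tracks, "track_centroids").n == 4
        assert make_cluster_input(locs, tracks, "tracks").n == 4

    def test_mode_source_mismatch(self):
        with pytest.raises(ValueError):
            make_cluster_input(None, None, "all_localizations")


class TestDBSCAN:
    def test_fewer_points_than_min_pts_all_noise(self, rng):
        pts = rng.uniform(0, 1000, (3, 2))
        res = cluster_dbscan(_points_input(pts), DBSCANParams(eps_nm=50, min_pts=5))
        assert res.clusters == [] and len(res.noise_ids) == 3

    def test_coincident_points_one_cluster(self):
        pts = np.zeros((8, 2))
        res = cluster_dbscan(_points_input(pts), DBSCANParams(eps_nm=50, min_pts=5))
        assert len(res.clusters) == 1 and res.clusters[0].n_members == 8

    @pytest.mark.parametrize("eps,min_pts", [(40.0, 3), (60.0, 5), (100.0, 8)])
    def test_matches_brute_force_oracle(self, eps, min_pts, rng):
        for _ in range(10):
            pts = csr_points(200, (1500.0, 1500.0), rng)
            got = dbscan_labels(pts, eps, min_pts)
            want = _brute_force_dbscan(pts, eps, min_pts)
            np.testing.assert_array_equal(got, want)

    def test_core_partition_matches_sklearn(self, rng):
        """Independent library cross-check on core-point memberships
        (border assignment conventions may differ)."""
        sklearn_cluster = pytest.importorskip("sklearn.cluster")
        pts = csr_points(300, (2000.0, 2000.0), rng)
        eps, min_pts = 80.0, 5
        ours = dbscan_labels(pts, eps, min_pts)
        sk = sklearn_cluster.DBSCAN(eps=eps, min_samples=min_pts).fit(pts)
        core = np.zeros(len(pts), dtype=bool)
        core[sk.core_sample_indices_] = True
        # same core points, and the same partition of them
        from scipy.spatial import cKDTree

        nb = cKDTree(pts).query_ball_point(pts, r=eps)
        assert np.array_equal(core, np.array([len(x) >= min_pts for x in nb]))
        for arr in (ours, sk.labels_):
            pass
        mapping = {}
        for o, s in zip(ours[core], sk.labels_[core]):
            assert mapping.setdefault(o, s) == s

    def test_partition_property(self, rng):
        pts = csr_points(150, (1000.0, 1000.0), rng)
        res = cluster_dbscan(_points_input(pts), DBSCANParams(eps_nm=60, min_pts=4))
        ids = np.concatenate([c.member_ids for c in res.clusters] + [res.noise_ids])
        assert sorted(ids) == list(range(150))


class TestVoronoi:
    def test_uniform_grid_yields_no_clusters(self):
        g = np.stack(np.meshgrid(np.arange(12) * 100.0, np.arange(12) * 100.0), -1).reshape(-1, 2)
        res = cluster_voronoi(_points_input(g), VoronoiParams(density_factor=2.0, min_pts=5))
        assert res.clusters == []

    def test_collinear_points_rejected(self):
        pts = np.column_stack([np.arange(10.0), np.arange(10.0)])
        with pytest.raises(ValueError):
            cluster_voronoi(_points_input(pts), VoronoiParams())

    def test_planted_thomas_cluster_count(self, rng):
        pts, _ = thomas_points(20, 30, 40.0, (4000.0, 4000.0), 0.10, rng, min_parent_sep_nm=400.0)
        res = cluster_voronoi(_points_input(pts), VoronoiParams(density_factor=2.0, min_pts=5))
        assert abs(len(res.clusters) - 20) <= 2  # within 10%

    def test_csr_false_positive_control(self, rng):
        counts = []
        for _ in range(10):
            pts = csr_points(660, (4000.0, 4000.0), rng)
            res = cluster_voronoi(_points_input(pts), VoronoiParams(density_factor=2.0, min_pts=5))
            counts.append(len(res.clusters))
        assert np.median(counts) <= 1

    def test_partition_property(self, rng):
        pts = csr_points(200, (2000.0, 2000.0), rng)
        res = cluster_voronoi(_points_input(pts), VoronoiParams())
        ids = np.concatenate([c.member_ids for c in res.clusters] + [res.noise_ids])
        assert sorted(ids) == list(range(200))


def _all_pairs_components(tracks, radius_factor, min_tracks):
    """Independent O(n^2) box-overlap oracle for NASTIC."""
    boxes = track_bounding_boxes(tracks, radius_factor)
    n = len(tracks)
    adj = [[] for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            a, b = boxes[i], boxes[j]
            if max(a[0], b[0]) <= min(a[2], b[2]) and max(a[1], b[1]) <= min(a[3], b[3]):
                adj[i].append(j)
                adj[j].append(i)
    seen = [False] * n
    comps = []
    for i in range(n):
        if seen[i]:
            continue
        stack, comp = [i], []
        seen[i] = True
        while stack:
            j = stack.pop()
            comp.append(j)
            for k in adj[j]:
                if not seen[k]:
                    seen[k] = True
                    stack.append(k)
        comps.append(frozenset(comp))
    return {c for c in comps if len(c) >= min_tracks}


class TestNASTIC:
    def test_identical_boxes_cluster(self, rng):
        tracks, _ = simulate_track_set(1, 10, 0.05, 0.05, 0, rng)
        t = tracks[0]
        t2 = Track(2, t.frames, t.x_nm.copy(), t.y_nm.copy(), t.loc_indices)
        res = cluster_nastic(
            ClusterInput(mode="tracks", tracks=[t, t2]), NASTICParams(min_tracks=2)
        )
        assert len(res.clusters) == 1 and res.clusters[0].n_members == 2

    def test_distant_tracks_are_noise(self, rng):
        tracks, _ = simulate_track_set(2, 10, 0.05, 0.05, 0, rng, start_spacing_nm=50000.0)
        res = cluster_nastic(ClusterInput(mode="tracks", tracks=tracks), NASTICParams(min_tracks=2))
        assert res.clusters == [] and len(res.noise_ids) == 2

    def test_matches_all_pairs_oracle(self, rng):
        for _ in range(10):
            tracks, _ = simulate_track_set(
                40, 10, 0.05, 0.05, 0, rng, start_spacing_nm=1200.0, start_jitter_nm=900.0
            )
            res = cluster_nastic(ClusterInput(mode="tracks", tracks=tracks), NASTICParams())
            got = {frozenset(int(m) for m in c.member_ids) for c in res.clusters}
            want = _all_pairs_components(tracks, 1.2, 3)
            assert got == want

    def test_hotspot_scenario(self, rng):
        tracks, hid = simulate_hotspot_tracks(
            5, 10, 20, (12800.0, 12800.0), 200.0, 20, 0.05, 0.05, rng
        )
        res = cluster_nastic(ClusterInput(mode="tracks", tracks=tracks), NASTICParams())
        assert len(res.clusters) == 5
        # >=95% of hotspot tracks grouped with their own hotspot
        grouped = 0
        for c in res.clusters:
            owners = hid[[m for m in c.member_ids]]
            vals, counts = np.unique(owners[owners >= 0], return_counts=True)
            grouped += counts.max()
        assert grouped / (hid >= 0).sum() >= 0.95

    def test_temporal_window_blocks_disjoint_times(self, rng):
        tracks, _ = simulate_track_set(1, 10, 0.05, 0.05, 0, rng)
        t = tracks[0]
        late = Track(2, t.frames + 1000, t.x_nm.copy(), t.y_nm.copy(), t.loc_indices)
        p = NASTICParams(min_tracks=2, temporal_window_s=1.0)
        res = cluster_nastic(ClusterInput(mode="tracks", tracks=[t, late]), p, frame_interval_s=0.05)
        assert res.clusters == []


class TestMetricsAndInvariants:
    def test_right_triangle_area(self):
        pts = np.array([[0.0, 0.0], [100.0, 0.0], [0.0, 100.0]])
        labels_input = _points_input(pts)
        res = cluster_dbscan(labels_input, DBSCANParams(eps_nm=300, min_pts=3))
        assert len(res.clusters) == 1
        c = res.clusters[0]
        assert c.area_um2 == pytest.approx(5000.0 * 1e-6, rel=1e-12)
        df, summary = cluster_metrics(res)
        assert summary["n_clusters"] == 1
        assert df.loc[0, "area_um2"] == pytest.approx(5e-3, rel=1e-9)

    def test_two_point_cluster_degenerate(self):
        pts = np.zeros((2, 2))
        res = cluster_dbscan(_points_input(pts), DBSCANParams(eps_nm=50, min_pts=2))
        c = res.clusters[0]
        assert c.area_um2 == 0.0 and c.diameter_nm == 0.0
        df, _ = cluster_metrics(res)
        assert bool(df.loc[0, "degenerate"])

    def test_metrics_deterministic(self, rng):
        pts = csr_points(100, (500.0, 500.0), rng)
        a = cluster_dbscan(_points_input(pts), DBSCANParams(eps_nm=80, min_pts=3))
        b = cluster_dbscan(_points_input(pts), DBSCANParams(eps_nm=80, min_pts=3))
        df_a, sum_a = cluster_metrics(a)
        df_b, sum_b = cluster_metrics(b)
        assert df_a.equals(df_b) and sum_a == sum_b

    def test_scale_equivariance(self, rng):
        """Scaling coordinates and eps scales areas by the square and
        leaves memberships unchanged."""
        pts = csr_points(120, (1000.0, 1000.0), rng)
        s = 3.7
        res1 = cluster_dbscan(_points_input(pts), DBSCANParams(eps_nm=70, min_pts=4))
        res2 = cluster_dbscan(_points_input(pts * s), DBSCANParams(eps_nm=70 * s, min_pts=4))
        assert len(res1.clusters) == len(res2.clusters)
        for c1, c2 in zip(res1.clusters, res2.clusters):
            np.testing.assert_array_equal(c1.member_ids, c2.member_ids)
            assert c2.area_um2 == pytest.approx(c1.area_um2 * s**2, rel=1e-9)
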