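"""Compare the three clustering algorithms on planted hotspot data.

NASTIC works on whole trajectories (bounding-box overlap), DBSCAN and
Voronoi on the track centroids.  With five planted hotspots of ten
confined tracks each plus twenty free tracks, NASTIC and DBSCAN report
the five hotspots with the free tracks left as noise; Voronoi, which
thresholds neighbour-averaged cell densities, needs denser point sets
than ten centroids per hotspot and typically finds fewer.
"""

import numpy as np

from sptpalm import cluster_dbscan, cluster_metrics, cluster_nastic, cluster_voronoi, make_cluster_input
from sptpalm.params import DBSCANParams, NASTICParams, VoronoiParams
from sptpalm.simulate import simulate_hotspot_tracks

rng = np.random.default_rng(9)
tracks, hotspot_of = simulate_hotspot_tracks(
    n_hotspots=5, tracks_per_hotspot=10, n_free=20,
    field_nm=(12800.0, 12800.0), hotspot_radius_nm=200.0,
    n_steps=20, d_um2_per_s=0.05, frame_interval_s=0.05, rng=rng,
)
print(f"{len(tracks)} tracks: 5 hotspots x 10 confined + 20 free")

nastic = cluster_nastic(make_cluster_input(None, tracks, "tracks"), NASTICParams())
_, summ = cluster_metrics(nastic)
print(f"NASTIC: {summ['n_clusters']} clusters, median diameter "
      f"{summ['median_diameter_nm']:.0f} nm, clustered fraction {summ['clustered_fraction']:.2f}")

centroids = make_cluster_input(None, tracks, "track_centroids")
dbscan = cluster_dbscan(centroids, DBSCANParams(eps_nm=150.0, min_pts=4))
print(f"DBSCAN on centroids: {len(dbscan.clusters)} clusters, "
      f"{len(dbscan.noise_ids)} noise points")

voronoi = cluster_voronoi(centroids, VoronoiParams(density_factor=2.0, min_pts=4))
print(f"Voronoi on centroids: {len(voronoi.clusters)} clusters")
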