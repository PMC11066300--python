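# sptpalm

Analysis pipeline for single-particle-tracking PALM (sptPALM) experiments,
built for sparse photoactivation movies of membrane proteins (the regime
typical of plant plasma-membrane imaging under VAEM/HiLo illumination:
100–400 px fields at 100 nm/px, thousands of frames at 20–50 Hz). The
package takes a raw TIFF movie all the way to diffusion coefficients and
nanoscale cluster statistics, and ships a full simulator so every stage
can be validated against known ground truth.

## What it computes

1. **Localization** — candidate spots are detected per frame as local
   maxima of a difference-of-Gaussians filter, then each ROI is fitted
   with a 2-D *integrated* Gaussian PSF model by maximum likelihood under
   Poisson noise:

   μ<sub>k</sub> = N·ΔE<sup>x</sup><sub>k</sub>·ΔE<sup>y</sup><sub>k</sub> + b,

   where the ΔE are erf-integrals of the Gaussian over pixel k. sCMOS
   read noise enters the likelihood through the standard var/gain²
   offset addition. The per-spot precision uses the closed-form MLE
   approximation σ<sub>loc</sub>² = (σ<sub>a</sub>²/N)(16/9 +
   8πσ<sub>a</sub>²b/(Na²)) with σ<sub>a</sub>² = σ² + a²/12.
2. **Tracking** — frame-to-frame linking as a linear assignment problem
   (squared-distance costs, non-link alternative (1.05·d<sub>max</sub>)²),
   plus a second global assignment that bridges short blinking gaps.
3. **Mobility** — time-averaged MSD per track; D = slope/4 from an OLS
   fit of the first few lags (free intercept absorbs the ≈4σ<sub>loc</sub>²
   localization-error offset); log₁₀(D) distributions, Gaussian-mixture
   population decomposition (BIC-selected, deterministic EM), and a
   mobile/immobile split at a configurable log₁₀(D) threshold.
4. **Clustering** — Voronoi tessellation (neighbour-averaged first-rank
   densities), DBSCAN, and NASTIC (trajectory bounding-box overlap via an
   STR-tree index) with uniform per-cluster metrics.
5. **Batch** — the whole pipeline over file lists with one frozen
   parameter set; results workbook embeds the complete parameter JSON for
   FAIR traceability.

## Worked example

```python
from sptpalm import (ParameterSet, analyze_mobility, calibrate_camera, close_gaps,
                     filter_localizations, filter_tracks, link_frames, localize_stack)
from sptpalm.simulate import SimulationConfig, simulate

cfg = SimulationConfig(n_frames=1000, n_molecules=600, rng_seed=3)
movie, dark, gt = simulate(cfg)          # 50/50 mix of D = 0.001 and 0.05 um^2/s
params = ParameterSet()
calib = calibrate_camera(dark, params.camera.e_per_adu, params.camera.qe)
locs, _ = filter_localizations(localize_stack(movie, calib, params), params.filter)
tracks = filter_tracks(close_gaps(link_frames(locs, params.tracking), params.tracking),
                       params.tracking)
summary = analyze_mobility(tracks, cfg.frame_interval_s, params.mobility)
```

Running this (it is `examples/02_track_and_mobility.py`) prints:

```
5170 localizations -> 251 tracks of >= 8 points
mean-MSD D = 0.0239 um^2/s (planted population mean 0.0255)
  population: weight 0.48, log10 D = -2.94 (D = 0.0012 um^2/s)
  population: weight 0.52, log10 D = -1.35 (D = 0.0448 um^2/s)
mobile fraction (log10 D > -2.0): 0.51
```

The mean-MSD coefficient lands on the planted population mean, and the
mixture decomposition recovers both planted populations (log₁₀ D = −3 and
−1.3) with near-equal weights — the same quantities one reports for a
real movie. The other `examples/` scripts demonstrate localization
quality control, the three clustering algorithms, and batch processing.

A thin CLI wraps the same functions:

```bash
sptpalm simulate --out sim/
sptpalm localize --movie sim/movie.tif --noise sim/dark.tif --out locs.csv
sptpalm track --locs locs.csv --out tracks.csv
sptpalm mobility --tracks tracks.csv --out mob/
sptpalm cluster --tracks tracks.csv --algorithm nastic --input-mode tracks --out clus/
sptpalm batch --items items.json --params params.json --out results/
```

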