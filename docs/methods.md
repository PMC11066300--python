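# Methods

## Scope and data model

The package analyzes sparse single-molecule movies: at any time only a
handful of photoactivated emitters are visible, each for a short burst of
frames. All tables use 1-based frame numbers and nanometre coordinates;
the continuous position of pixel (row i, col j) centre is
x = (j+0.5)·a, y = (i+0.5)·a with pixel size a, origin at the top-left
corner of the top-left pixel. TIFF metadata is never trusted — pixel
size and frame interval come from the parameter set, because they are
fixed at the microscope, not in the file.

## Camera model and calibration

Counts are modelled as ADU = photons·qe/g + offset + read noise, with
g the e⁻/ADU gain. Calibration from a dark series uses per-pixel
temporal mean (offset) and unbiased variance. Photon conversion is the
affine inverse (ADU − offset)·g/qe; values may be negative after offset
subtraction and are passed unclipped to the fitter (clipping is display
only). Quantum efficiency defaults to 1.0 — whether reported photon
counts should be QE-corrected is a lab convention, so it is exposed as a
parameter rather than fixed.

## Localization

Detection: difference of Gaussians (σ = 1.0 / 2.5 px), 8-neighbourhood
local maxima above `threshold_factor` (default 4.0) times a robust noise
scale (1.4826·MAD of the filtered frame) plus a numerically negligible
absolute floor that suppresses float-rounding maxima on constant frames.
Candidates whose 7×7 ROI (half-size 3) would cross the frame border are
dropped.

Fitting maximizes the Poisson log-likelihood of the integrated-Gaussian
model μ_k = N·ΔEx_k·ΔEy_k + b over (x₀, y₀, N, b, σ), ΔE being erf
differences over each pixel's extent. The optimizer is
Levenberg–Marquardt on the Poisson deviance using the expected
(Fisher-information) Hessian and analytic first derivatives; N, b, σ are
log-transformed to enforce positivity; convergence when the largest step
component (px for positions, log-units otherwise) falls below `tol`
(1e-6) within `max_iterations` (30). The free σ supports the PSF-size
quality histograms; astigmatic/3-D models are out of scope. With sCMOS
correction, var/g² is added to both data and model before evaluating the
likelihood — the standard Poisson-approximation treatment of Gaussian
read noise. A zero variance map reproduces the pure-Poisson path
exactly. Fits whose centre lands more than 1 px from the candidate
pixel centre are discarded: under a single-emitter model they indicate
the fit locked onto a neighbouring spot (multi-emitter fitting is out of
scope).

Precision uses the closed-form MLE approximation
σ_loc² = (σ_a²/N)(16/9 + 8πσ_a²b/(Na²)), σ_a² = σ² + a²/12. On
simulated spots the fitter is unbiased to well under 1 nm and its RMSE
matches the numerically computed Cramér–Rao bound within a few percent
(tests cover 300–3000 photons/frame); the median closed-form precision
tracks the empirical RMSE within ~20%.

Default quality filter: σ ∈ [80, 250] nm, photons ≥ 100, precision
≤ 50 nm — wide enough for visible fluorescent proteins at 100 nm/px,
and all user-adjustable.

## Tracking

Frame-to-frame linking solves a linear assignment problem per
consecutive frame pair: link cost = squared distance for pairs within
`max_link_distance_nm` (default 500), with a birth/death alternative at
(1.05·max_link)² — the convention popularized by the simple LAP
trackers. Squared costs penalize long links superlinearly. Gap closing
is a second global assignment between segment ends and later segment
starts (frame gap ∈ [2, max_gap+1], distance ≤ `max_gap_distance_nm`,
same cost convention); accepted bridges are concatenated with the
bridged frames recorded, never interpolated. Defaults: one-frame gaps,
minimum track length 8 localizations. Merge/split handling and motion
models are omitted: photoactivation density is deliberately low, so
trajectory crossings are rare. On small instances the solver is verified
against exhaustive enumeration of all feasible assignments.

## Mobility

Per track, MSD(nΔt) averages squared displacements over all ordered
member pairs whose frame numbers differ by exactly n (frame arithmetic,
so bridged gaps contribute at matching lags and are skipped otherwise;
lags with no pair are dropped). D = slope/4 from OLS over the first
`n_fit_points` lags (default 4 — MSD curves bend at long lags, where
time-averaged estimates decorrelate), intercept free: localization error
adds ≈4σ_loc² to every lag, so forcing the line through the origin would
bias D. The adjusted R² gate (default 0.7) rejects tracks whose 4-point
fit is uninformative; with exactly 2 fit points the adjustment is
undefined and R² itself is used. Tracks with non-positive slope have no
log D; they are excluded from the distribution but counted as immobile.

The mean MSD averages per-track MSD values unweighted per lag, keeping
lags only while ≥50% of tracks contribute (tail lags of the longest few
tracks are noisy and would dominate the fit). The log₁₀(D) distribution
is decomposed into 1–2 Gaussian components by EM with five deterministic
quantile-based starts (no RNG), a 0.05-dex standard-deviation floor
against degenerate components, and BIC model selection. The "peak
log D" summary is defined as the mean of the highest-weight component;
the mobile fraction is the fraction of log D values above
`threshold_logD` (default −2, i.e. D = 0.01 µm²/s), with
non-positive-slope tracks in the immobile denominator.

## Cluster analysis

All three algorithms partition their input into clusters plus noise and
report convex-hull area (µm²), equivalent diameter 2√(area/π), centroid
and membership. Point inputs are either all filtered localizations or
one centroid per track; NASTIC consumes trajectories directly.

*DBSCAN* follows the canonical semantics (core iff ≥min_pts neighbours
within eps, counting itself); border points reachable from several
clusters deterministically join the lowest cluster id. The
implementation is an indexed (k-d tree) expansion verified against a
brute-force O(n²) reference over parameter grids.

*Voronoi* thresholding uses neighbour-averaged first-rank densities:
δ_i = (1 + #valid neighbours)/(Σ cell areas), against
`density_factor` (default 2) times the mean density n/A of the analysis
rectangle (tight bounding box grown 2%). Cells unbounded or leaving the
rectangle cannot seed. Own-cell (rank-0) densities were evaluated and
rejected: ~30% of cells in a homogeneous Poisson pattern fall below half
the mean area, so rank-0 thresholding at 2× seeds many spurious ≥5-point
components (measured median 4 per CSR field), while the neighbour
average keeps the false-positive control at ≤1 cluster and still
resolves planted Thomas-process clusters to within ±10%.

*NASTIC* expands each track's axis-aligned bounding box about its centre
by `radius_factor` (default 1.2) and clusters connected components of
the box-overlap graph (≥`min_tracks`, default 3). Candidate pairs come
from an STR-tree (O(n log n) expected); results are checked equal to the
all-pairs intersection graph. An optional temporal window additionally
requires track time intervals to approach within the window; it is off
by default because spatial overlap is the primary criterion in sparse
data. Cluster metrics are computed on the union of member localizations.

Cluster-analysis outputs are sensitive to their parameters; like-for-like
comparisons require a frozen parameter set, which is what the batch
workbook records.

## Simulator

The simulator emulates the full acquisition: molecules diffuse by 2-D
Brownian steps (per-axis variance 2DΔt) with reflecting field
boundaries, drawn from one or two mobility populations; initial
positions are uniform or Thomas-process clustered, optionally confined
to discs for hotspot scenarios. Photophysics uses geometric (discrete)
waiting times — frames are the natural clock: single activation,
geometric on-times, per-frame blink-off into geometric dark periods,
per-frame bleaching; photons per on-frame are Poisson. Rendering sums
integrated-Gaussian PSFs plus uniform background, applies Poisson shot
noise times QE, then gain, offset, Gaussian read noise, rounding and
16-bit clipping (logged if it occurs). Dark stacks share the camera
model with zero expected photons.

Defaults are the study conditions used throughout the tests: 128×128 px
at 100 nm/px, 3000 frames at 20 Hz, 800 photons/frame, background
10 photons/px, PSF σ 130 nm, camera offset 100 ADU, gain 0.5 e⁻/ADU,
read noise 2 ADU; populations 50/50 at D = 0.001 and 0.05 µm²/s (a
planted mobile fraction of 0.5 at the default threshold); 1500 molecules
with activation 0.001/frame, mean on-time 20 frames, 10% blink
probability (mean dark 1.5 frames), 2% bleach/frame — yielding ≈20 000
localizations per movie at sparse density, the scale of a typical
experimental file. Emitters render at their frame-start position (no
motion blur), there is no drift, no cell-shaped background, no EMCCD
excess noise, and blinking is memoryless — so passing tests demonstrate
correctness of the estimators under the model's assumptions, not
robustness to every real-world artifact.

Benchmark generators used in tests state their own conditions: the
blinking-recovery benchmark drops 10% of interior detections as
single-frame dropouts (never two in a row), the regime one-frame gap
closing is built for; the two-population decomposition benchmark uses
noiseless tracks so the slow population's MSD is not dominated by the
localization-error offset.

## Numerical choices and degenerate inputs

- LAP matrices use a large finite sentinel (1e15) for forbidden
  assignments; chosen links are validated against the gate afterwards.
- Convex hulls of <3 or collinear points have zero area and are flagged
  degenerate rather than erroring.
- Histograms use Freedman–Diaconis bins clipped to the data range;
  constant data collapses to a single bin.
- All tie-breaks (candidate ordering, border-point assignment, cluster
  numbering) are by ascending index, making every stage deterministic
  given its input; the only RNG in the package is the simulator's, fully
  determined by its seed.
- Empty inputs return empty results (header-only tables, empty
  histograms); undersized inputs that make a quantity undefined (1-frame
  dark stack, <2-member tracks, <10 log D values, <4 Voronoi points)
  raise ValueError with the reason.

## Problem sizes in the validation suite

The test-suite and acceptance-script simulations use 1000 spots for the
CRLB comparison, 50 tracks for each tracking benchmark, 300/400 tracks
for the diffusion and mixture recoveries, 50 random instances for each
clustering oracle, 20 CSR and 5 Thomas replicates for the Voronoi
controls, and one full-size default movie (3000 frames, ≈900 analyzed
tracks) for the end-to-end identifiability check — sizes at which the
statistical tolerances stated in the tests are comfortably resolvable.

## Known limitations

- Single-emitter fitting only; overlapping spots are detected but the
  later-fitted one is discarded by the 1-px wander rule, so recall drops
  at high activation density.
- 2-D only: D = slope/4 assumes in-plane diffusion; out-of-plane motion
  and 3-D PSF shapes are not modelled.
- No drift correction; long acquisitions with stage drift will broaden
  both σ and the apparent mobility.
- The closed-form precision is an approximation that degrades at very
  low photon counts (<100) and high background.
- NASTIC cluster metrics depend on track length through bounding-box
  size; comparisons across conditions should hold tracking parameters
  fixed.
- Any allowed link (distance below the gate) is preferred over the
  birth/death alternative, so when one molecule bleaches and another
  activates nearby within a frame the tracker joins them. These rare
  mislinks add large squared jumps to a few tracks and, because the mean
  MSD weights tracks equally, bias the ensemble D upward by up to
  ~10–15% at the default simulation density; the per-track log D
  distribution is far less sensitive.
- The adjusted-R² gate rejects near-immobile tracks more often than
  mobile ones (their 4-point MSD fits are flatter relative to noise), so
  the mobile fraction computed over accepted-plus-negative-slope tracks
  runs a few points above the planted value.
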