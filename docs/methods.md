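# Methods

This note documents the models, defaults and numerical choices behind the
`crrc` package, and what the synthetic benchmark does and does not show
about real microscope data.

## The measurement model

Each cell carries a unimolecular rate constant k (min⁻¹) for the reaction
under study (the motivating case is fluorescein efflux across the plasma
membrane). Its background-subtracted fluorescence intensity, integrated
within the cell contour, follows

    y(t) = A · exp(−k t) + y0

with t measured from efflux initiation (medium exchange, by default the
first fluorescence timestamp; configurable offset). A population is
summarized by the histogram of accepted per-cell k̂, its median and its
adjusted Fisher–Pearson skewness (G1).

Acquisition alternates channels: the transmitted-light image of pair j is
taken at j·t2 and its fluorescence partner t1 seconds later. Defaults
t2 = 60 s and t1 = 3 s satisfy the two design constraints
v_max·t1 ≪ d (contours transferable within a pair: 0.33 μm ≈ 2.5% of d)
and v_max·t2 < d (nearest-within-a-diameter linking valid: 6.7 μm < 13 μm).
`crrc.track.linking_gate` and `crrc.track.displacement_error` expose both
bounds.

## Synthetic time-lapse generator (`crrc.simulate`)

The generator emulates the situation the two workflows are meant to
distinguish: a sub-confluent monolayer of motile cells with heterogeneous
kinetics. Defaults (one draw per cell unless noted):

| parameter | default | unit | rationale |
|---|---|---|---|
| n_cells | 200 | — | a few hundred cells per field, typical of 10× imaging |
| field | 512 × 512 at 0.65 | px, μm/px | sCMOS pixel pitch at 10× |
| n_frames / t2 / t1 | 61 / 60 / 3 | —, s, s | 1 h at one pair per minute |
| radius | Normal(6.5, 1.5), clipped to [3, 12] | μm | d = 13 ± 3 μm; clip matches the single-cell filter |
| speed | log-normal, mode 150, IQR 40, max 400 | μm/h | reported motility statistics; right-skewed, positive |
| persistence | 0.9 | — | minutes-scale directional persistence of mesenchymal migration |
| k | log-normal, median 0.05, σ_log 0.4 | min⁻¹ | ~3 decay constants within the 1 h window; right-skewed population |
| A / y0 / background | 600 / 20 / 100 | a.u./px | decaying signal stays well above offset and background |
| transmitted foreground | 300 over background | a.u. | bright-on-dark, SNR ≈ 10 at the default noise |
| read noise σ | 30 (Gaussian, additive) | a.u. | segmentation of defaults succeeds; optional Poisson term off |

**Speed distribution.** Only the mode, IQR and maximum of the speed
distribution are specified by the study conditions; the log-normal is the
simplest strictly-positive right-skewed family with two free parameters.
Given mode m and IQR q, σ solves m·exp(σ²)·2 sinh(σ z₀.₇₅) = q (monotone,
bisection) and μ = ln m + σ². Draws are rejection-truncated at the
configured maximum (negligible mass at the defaults). IQR = 0 degenerates
to a point mass, and mode 0 with IQR 0 expresses an immobile population.

**Motion model.** Persistent random walk: each frame interval the heading
turns by (1 − p)·Uniform(−π, π) and the cell advances v·Δt; p = 1 is
ballistic and p = 0 reproduces the uncorrelated 2-D walk
(MSD(n) = n·(vΔt)², verified against the closed form). Walls reflect both
position and heading (specular). A step that would bring two centers
closer than r_i + r_j + margin is rejected and redrawn with a fresh
uniform heading (8 attempts, then the cell stays); redrawing rather than
freezing preserves realized speeds at the default packing density. The
margin (default 2 μm) also keeps rendered anti-aliased disks from fusing
into single 8-connected blobs, so "non-overlapping" holds at the pixel
level, not just between ideal circles. Within a frame pair the
fluorescence-time positions are the transmitted positions advanced by
v·t1 along the current heading.

**Rendering.** Cells are disks (shape change is out of scope). Per-pixel
coverage uses the linear ramp clip(r + ½ − ρ, 0, 1); its continuum total is
πr² + π/12, i.e. < 1% area error for r ≥ 3 px, which is the tolerance the
closed-form conservation tests use. The fluorescence per-pixel value adds
A·exp(−k·t) + y0 times coverage to the background; Gaussian read noise
(optionally Poisson shot noise) is added and frames clip at zero. In-memory
stacks are float; writing produces 16-bit TIFF (quantization perturbs
refitted k by ≲ 2% on short traces, ≲ 0.1% at 61 frames).

**What the generator does not emulate** — and therefore what passing tests
do not certify on real data: optical blur and defocus (the transmitted
channel directly renders the bright-on-dark regime that live thresholding
produces), illumination non-uniformity, photobleaching, cell shape change,
division, death, adhesion and crawling mechanics beyond the persistent
walk, and overlapping/clustered cells. The pipeline's behaviour under
those effects must be validated on real stacks.

## Segmentation (`crrc.segment`)

Global threshold (Otsu by default; fixed and percentile thresholds for
parity with manual live thresholding) → 8-connected component labeling →
equivalent-radius filter, closed interval [3, 12] μm, which keeps single
cells and drops debris and fused clusters. A deep-learning detector would
also work here, but contours of bright-on-dark blobs do not need one; the
classical chain is dependency-free and deterministic. Constant images
cannot be auto-thresholded and return an empty foreground with a warning.
Detection accuracy against reference centroids is scored by greedy
nearest-first one-to-one matching within 6.5 μm (half a typical diameter) —
stricter than count comparison, since positions must agree.

## Tracking (`crrc.track`)

Per-frame-pair minimum-total-distance one-to-one assignment (Hungarian
algorithm) restricted to pairs within one cell diameter (13 μm);
infeasible pairs carry a cost exceeding any feasible total, so the solver
maximizes the number of gated links, then minimizes distance. No gap
closing and no split/merge handling: tracks that do not span every frame
are excluded anyway, so gap closing could only promote ambiguous
identities. Equal-cost ties resolve deterministically (lowest combined
index order). Mean track speed is polyline path length over elapsed time.

## Trace extraction (`crrc.traces`)

Per-frame rolling-ball background subtraction (radius 50 px) precedes
integration. For radius ≥ 16 px the ball is rolled on a 4× block-minimum
shrunk image and the background re-enlarged bilinearly — the standard
ImageJ speed-up, exact for backgrounds smooth on the ball scale. The
intensity statistic is the **sum** within the contour, not the mean: for a
fixed mask k̂ is invariant to this choice, but the sum is sensitive to
mask drift, which is precisely the motility effect the workflows differ
on. The new workflow integrates each fluorescence frame inside that
frame's own tracked contour; the original workflow freezes the contours
segmented from the first fluorescence frame.

## Fitting and QC (`crrc.kinetics`)

Unbounded Levenberg–Marquardt least squares of (A, k, y0), at least five
points per trace. The problem is internally normalized (time to [0, 1],
intensities by their maximum) so results are invariant to intensity
scaling and to the time unit up to the optimizer tolerance (1e-8, max
1000 evaluations). Initialization: y0₀ = min(y), A₀ = y(0) − y0₀, k₀ from
a log-linear regression over the first half of the trace (sign free, so
rising traces start at negative k); fallback τ₀ = duration/3. k is
deliberately unbounded: rising traces must fit with k < 0 so the sign
filter can see them, rather than being clamped to zero. SE(k) comes from
the residual-scaled covariance; RSE = 100·SE(k)/|k|. The acceptance rule
is: converged, k > 0, RSE ≤ 100% (exactly 100% is kept; the cut is
strictly ">"). Non-convergence and singular covariances are reported as
rejected fits, never raised.

## Population statistics (`crrc.popstats`)

Histogram bins default to Freedman–Diaconis with explicit custom edges
supported. Skewness is the adjusted Fisher–Pearson G1 (the spreadsheet /
descriptive-statistics convention). The two-sample KS statistic
D = sup|ECDF₁ − ECDF₂| is computed exactly over the pooled breakpoints;
the p-value uses the asymptotic Kolmogorov distribution at √(n_eff)·D with
n_eff = n₁n₂/(n₁+n₂) (an exact small-sample p is available for
n₁·n₂ ≤ 10⁴), and the critical value is D_α = c(α)·√((n₁+n₂)/(n₁n₂)) with
c(α) = √(−ln(α/2)/2). Significance is defined as D > D_α; this agrees
with p < α except within the higher-order series terms exactly at the
boundary (relative effect < 1e-6 at α = 0.001), where the critical-value
criterion wins by definition.

## Pipeline, formats, determinism (`crrc.io`, `crrc.pipeline`, `crrc.cli`)

`run_pipeline` chains simulate/read → segment → track → traces (both
workflows) → fit → compare, persists every intermediate (versioned-CSV
tables, 16-bit multi-page TIFFs, `comparison.json`) and writes a run log
with versions, seed and parameters. Any stage failure aborts with a
stage-labeled error. Everything is deterministic given (config, seed).
Coordinates are 0-based (row, col) with pixel centers at integers; files
store times in seconds and rate constants in min⁻¹.

## Problem sizes used in validation

The bundled checks run the full default population (200 cells, 61 frames,
512 × 512 px) once for the motile comparison and once immobile; the
multi-seed directional-bias check uses ten scaled-down populations
(60 cells, 31 frames, 256 × 256 px), which preserves the motility/contour
geometry (same pixel size, speeds and radii) at a tenth of the rendering
cost. Monte-Carlo fitter calibration uses 500 replicate traces; oracle
equivalence suites use 100–200 random instances each. The immobile
recovery check uses read noise 1 a.u. so that the per-cell 1% bound
probes systematic bias (measured ≈ 1e-5 noiseless) rather than the tail
of the noise distribution.

## Known limitations

* Segmentation assumes well-separated bright-on-dark cells; touching or
  overlapping cells merge and are discarded by the radius filter rather
  than split (marker-based splitting is not enabled by default).
* The exponential model is single-phase; bi-exponential or
  Michaelis–Menten kinetics, bleaching correction and ratiometric
  normalization are out of scope.
* The KS p-value is asymptotic in the default path; for very small
  samples use the exact option.
* Tracking assumes the gate condition v_max·t2 < d holds; at slower
  cadences identity errors rise and the validity flag should be checked.
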