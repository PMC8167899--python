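# Methods

`metquant` implements two quantitative pipelines for live and fixed imaging
of epithelial transitions in embryonic tissue, together with the synthetic
ground-truthed data used to validate them.

## 1. Nucleus tracking pipeline

### Motion model of the synthetic movies

Nuclei of two diameter classes — small epithelial-precursor (PMEC-like,
~3 µm) and large interstitial-precursor (ICP-like, ~6 µm) nuclei — undergo
directed, partially coordinated 3D migration.  Per frame, cell *i* of a
population takes the step

    step_i = ρ · s_pop + (1 − ρ) · s_i,
    s_pop, s_i ~ N(v·Δt·û, σ_step² I)

where `v` is the programmed speed (default 1.2 µm/min, the canonical
wild-type midgut migration speed at 25 °C), `Δt` the frame interval
(2 min), `û` the shared direction, and `σ_step` = 0.2 µm a mild per-frame
wiggle.  The shared term `s_pop` is drawn once per frame per population, so
the convex weight ρ ∈ [0, 1] directly tunes how correlated neighbouring
trajectories are; this is the simplest model in which the coordination
statistic has a monotone programmable expectation (verified at
ρ ∈ {0, 0.5, 1} in the test suite).  A constant global drift (default
0.25 µm/frame in y and x) translates every nucleus identically, emulating
residual embryo movement.  Note that the *acquisition-frame* motion is the
directed step plus the drift; where the pipeline's velocity is compared
with a "programmed speed", that reference is `‖v·Δt·û + d‖/Δt`, the speed
of the total programmed motion.

Each nucleus is rendered as an isotropic 3D Gaussian whose FWHM equals its
diameter (σ = d / (2√(2 ln 2))), sampled through anisotropic voxels
(default 1.5 × 0.5 × 0.5 µm in z, y, x).  Gaussian read noise is added
last (default σ = 15 on a peak amplitude of 120, i.e. peak SNR 8; Poisson
noise is available but off by default so detection tests control SNR
exactly); intensities are clipped to [0, 255].  Ground truth records the
exact pre-noise positions (acquisition frame) and the cumulative drift.

Default movie geometry: 31 frames × 14 z × 256 × 256 px.  The xy pixel
size is 0.5 µm, giving a 128 µm field: at 1.2 µm/min a nucleus travels
~72 µm in the 60-min window, plus drift, so a smaller field could not hold
full-length trajectories.  The z geometry (14 × 1.5 µm ≈ 21 µm) matches
the acquisition design the generator emulates.

What the generator does *not* model: photobleaching, division, apoptosis,
membrane signal, non-rigid tissue deformation, anisotropic PSFs, and
intensity variation between nuclei.  Passing tests therefore demonstrate
correctness of the measurement chain under its stated assumptions, not
robustness to every property of real embryo movies.

### Drift compensation

Overall movement is estimated per consecutive frame pair by unnormalized
cross-correlation of maximum-intensity projections (z-projection for the
xy shift, y-projection for the z shift), after light Gaussian smoothing
(σ = 1 px) of the projections; plain correlation with smoothing proved
markedly more accurate than phase normalization for subvoxel steps at
realistic noise.  Per-pair estimates are accumulated and rounded to
integer voxels.  Compensation shifts each frame uniformly by minus its
cumulative shift — integer shifts, no interpolation, vacated voxels filled
with the movie's modal background value — and the stored table is later
inverted on detected coordinates (`restore_coordinates`), so tracks are
reported in the original acquisition frame.  With coherently migrating
cells the estimator deliberately absorbs the collective motion as well as
true drift; this is the point of the scheme (near-stationary nuclei are far
easier to link), and restoration puts the motion back before statistics.

### Detection

An adjusted 3D Laplacian-of-Gaussian detector.  For an expected nucleus
radius r, the physical scale is σ = r/√3 (the LoG optimum for a 3D blob);
each axis uses σ divided by its voxel size, and the per-axis second
derivatives are rescaled by 1/voxel² so the operator is the true µm-space
Laplacian on anisotropic grids.  Second-derivative kernels are forced to
zero DC gain, making the response of a constant image exactly zero.  The
response is scale-normalized (×σ²) so qualities are comparable across
scales; bright blobs give negative minima and quality = −response.

Candidates are strict 26-neighbour local minima with per-axis quadratic
subvoxel refinement.  The default quality floor is 8× the robust noise
sigma of the response (1.4826 × median |response|, excluding exactly-zero
voxels such as shift fill); minima of a smooth noise field rarely exceed a
few sigma, so this rejects noise and shift-boundary artifacts while
keeping an ample margin to genuine nuclei (measured ≥ 4× at peak SNR 5).

Both diameter classes are detected in one pass: the detector runs one
scale per class (radii 1.5 and 3 µm), pools candidates, and prunes them
jointly — sort by quality descending, accept a candidate only if no
accepted candidate lies within the suppression radius (the larger of the
two candidates' radii; ties broken by scan order).  Scale normalization
makes the matched scale respond most strongly, so the surviving detection
carries the correct class and its diameter estimate (2 × detection radius)
feeds classification.  No boundary segmentation is attempted.

### Linking, curation, classification

Frame-to-frame constrained linear assignment on squared distances: links
longer than `max_link_dist` (default 4 µm ≈ 1.7× the fastest programmed
per-frame displacement) are forbidden, and every detection can instead
terminate (death) or start (birth) a track at cost `max_link_dist²` — the
standard augmented-matrix LAP.  The solver's total cost is provably the
optimum; the test suite checks it against exhaustive enumeration on
thousands of random instances.  No gap closing and no merge/split events:
curation keeps only tracks that span the whole video (and start inside an
optional ROI box), so a single missed detection removes the track rather
than corrupting it.  Cell types are assigned from the per-track *median*
diameter (robust to occasional cross-scale mismatches): < 3.5 µm → PMEC,
> 5.5 µm → ICP, between → unclassified and excluded from statistics.

### Track statistics

* instantaneous speed: ‖Δx‖/Δt per frame pair (3D, µm/min);
* velocity: arithmetic mean of instantaneous speeds (the mean-speed
  reading of "average velocity"; net-displacement-over-time is not used);
* directional persistence: net displacement / total path length (the
  standard definition; 1 = straight, 0 = closed loop);
* coordination: Pearson correlation between a track's instantaneous
  velocity series and that of its nearest neighbour (nearest by
  first-frame position, self excluded, ties to the lower track id), with
  the z, y, x components concatenated into one series so both direction
  and magnitude matter.  A mean-cosine (direction-only) variant is
  available via `coordination_mode="cosine"`.  Note the stacked-component
  correlation of two *directed* tracks is dominated by the shared mean
  velocity vector, so coherently migrating populations score near 1 by
  construction; the statistic separates conditions through speed and
  coordination deficits jointly.

Undefined per-track values (zero path, zero-variance velocity) propagate
as missing, never as zero.  Aggregation is two-stage: tracks → embryo mean
(per cell type; a warning below 15 tracks), embryos → condition.
Conditions are compared on embryo means with unpaired two-tailed t tests
(classic equal-variance by default, Welch by flag) and one-way ANOVA when
three or more conditions are present; stars at p ≤ 0.05/0.01/0.001.

## 2. Apicobasal profile pipeline

### Synthetic epithelium

A band of columnar "cells" (default 10, length 15 ± 1 µm) rendered in 2D
at 0.1 µm/px, rows running along the apical→basal axis.  Profile distance
0 sits 1 µm above the apical membrane and the line ends 1 µm below the
basal mesoderm surface, so the apical membrane is at 1 µm in line
coordinates.  Marker intensity along the axis is a sum of Gaussians with
programmable position, amplitude (0–255) and FWHM, laterally uniform
within each cell strip; per-cell length jitter rescales intra-cell peak
positions and rigidly shifts mesoderm peaks.  A configurable block of
background-only rows below the band emulates the large empty field of a
real micrograph — important because the 3% pooled-histogram threshold is a
percentile of *all* pixels, and an image that is mostly tissue would push
the threshold into the peaks.  The generator emits images in the
bright-signal (post-inversion) convention; when the pipeline simulates its
own input the 8-bit/invert step is therefore skipped
(`apply_8bit_inversion: false`), while file-based raw micrographs go
through the full chain.

### Preprocessing

8-bit conversion (linear min–max rescale) and inversion (v → 255 − v),
then sliding-paraboloid background subtraction, then stack-histogram
thresholding, in that order.  The paraboloid background is the grayscale
opening of the image by the structuring surface h(d) = d²/(2·radius),
computed exactly via separable 1D quadratic structuring functions
(truncation beyond the image's value range is lossless).  The default
radius is 150 px (15 µm at default sampling): the background probe must be
several-fold wider than the broadest genuine feature or its opening rises
into wide peaks and clips their amplitude — at radius 50 px a 2.4 µm-FWHM
peak loses ~6% of its height, at 150 px under 2%.  Thresholding keeps the
brightest `signal_fraction` (default 3%) of pixels of the pooled histogram
and zeroes the rest; the percentile reading of the "stacked histogram at
3%" convention is implemented (the fraction is configurable; an
of-the-maximum reading would be a different, not-implemented convention).

### Profiles and peaks

Wide-line profiles sample every pixel step along a manually supplied (or
generator-supplied) line, averaging bilinearly across a perpendicular band
of 60 px so most of a cell's width contributes while lateral membranes are
excluded.  Cell profiles (≥ 10 per embryo; lengths within ±1 µm of the
median, violators dropped with a warning) are linearly rescaled onto the
median-length grid and averaged pointwise into an embryo profile; embryo
profiles (design: 6 per condition) average into the condition profile.

Peak metrics are windowed: amplitude is the profile maximum inside the
window (defaults 0–10 µm apical, 10–20 µm basal, configurable per marker;
position refined by a parabolic fit), and FWHM is the width at half the
amplitude, with half-level crossings found by walking outward from the
peak and linear interpolation on each flank.  Because profiles are
background-subtracted and thresholded upstream, the half-maximum baseline
is zero; a local-minimum baseline is deliberately not used.  Peaks whose
flanks never descend to half level are flagged unbounded and excluded.
Per-embryo metrics are compared mutant-vs-control with unpaired two-tailed
t tests, plotted as embryo dots with mean and SD bars.  Nuclear levels
(e.g. a transcription factor's decline) are measured as the mean gray value
inside 30 elliptical nucleus ROIs, averaged per embryo.

## 3. Validation studies and problem sizes

All validation data are generated programmatically at run time; nothing is
bundled.  The test suite and `scripts/acceptance.py` run:

* tracking recovery on one default movie (30 nuclei, 31 frames, drift on);
* assignment optimality on 1,000 random frame pairs (≤ 6 detections);
* drift round trips on a pure-drift movie (0.5 px/frame, 12 frames);
* analytic statistic cases (persistence 1 / 0 / √2⁄2, coordination ±1,
  30-track random-walk null);
* FWHM/amplitude recovery over programmed FWHM {0.8, 1.0, 1.3, 1.8, 2.0,
  2.4} µm, 3 conditions × 6 embryos × 10 cells;
* a statistical oracle check against values frozen from R 4.3
  (`t.test(var.equal=TRUE)`, `anova(lm(...))`) at 1e-10;
* a ten-seed two-arm contrast study (wild-type-like vs mutant-like with
  programmed deficits in speed, coordination, and basal-peak FWHM), run
  end to end through both pipelines at 6 embryos per arm.  The contrast
  movies use a compact geometry (12 frames, 80 µm field, 6+6 nuclei) and
  the contrast epithelia a narrower strip (40 px cells, 30 px lines) so
  the 120-movie study completes in minutes; the programmed effects are the
  package's chosen study conditions, not fitted values.

## 4. Numerical choices and degenerate inputs

* Tie-breaks: pruning ties by scan order; nearest-partner ties by lower
  track id; all pipelines are bit-deterministic given the config seed
  (children seeds derive from `numpy.random.SeedSequence` spawn keys).
* Constant image → 8-bit conversion maps to 0, inversion to 255
  (documented degenerate case); constant stack → threshold retains all.
* Blank frames during drift estimation contribute zero shift with a
  warning; shifts that would exceed the image extent raise.
* All-zero profile windows report amplitude 0 with flagged position;
  FWHM of unbounded peaks is missing, not extrapolated.
* Quality floors, link gates, and classification bands are configurable;
  defaults are dumped with provenance by `metquant explain-defaults`.

## 5. Known limitations

* Diameter estimates come from the detection scale (two discrete values by
  default), not from segmentation; intermediate-size nuclei are resolved
  only by the median over a track.
* The coordination statistic's null distribution under directed motion is
  strongly positive (see above); comparisons are meaningful between
  conditions, not as absolute coordination levels.
* The drift estimator assumes a dominant rigid translation; rotation and
  non-rigid deformation are out of scope.
* FWHM is undefined for peaks truncated by the profile domain; broad
  mutant-like plateaus that cross a window boundary are measured at the
  window's global maximum, which may straddle two biological structures.
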