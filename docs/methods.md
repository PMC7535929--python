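# Methods

This note documents the models, parameters, and numerical choices behind
`bitetrack`, what the synthetic generators do and do not emulate, and the
design decisions taken where the problem is genuinely open.

## Imaging model and units

Recordings are top-down views of a flat, bright, back-lit substrate with
mosquitoes appearing as dark silhouettes. All geometry is expressed in
image pixels (origin top-left, x right, y down, 0-based frames) and
converted to physical units through a single `Calibration`
(`um_per_px`, default 25 µm — a ~4.3 × 4.3 cm field of view on a 2 k
sensor — and `fps`, typically 25 or 40). Areas scale with the square of
the pixel pitch; the scale-covariance of all measurements is tested.

## Detection and tracking

**Background.** Per-pixel temporal median over frames sampled every
`stride` (default 5). The median is only valid when each pixel is
background more than half of the sampled time; scenes dominated by
stationary animals (long feeding bouts) violate this, so the pipeline
also accepts an explicitly measured empty-substrate image, which is the
recommended practice when one is available.

**Segmentation.** |frame − background| is thresholded with Otsu's method
(a fixed level is configurable for IR recordings with stable contrast),
then opened and closed with a 2 px disk to drop noise and fill body
holes. Connected components with area inside
[`min_blob_area`, `max_blob_area`] (defaults 0.5–20 mm²) become
detections; centroids are intensity-weighted by the difference image.

**Linking.** Crocker–Grier linking realized as per-frame globally optimal
assignment: candidate (track, detection) pairs within `search_range`
(default 2 mm/frame) enter an augmented cost matrix (squared displacement
for links, `search_range²` for leaving either side unmatched) solved by
the Hungarian algorithm. A property test checks the result equals
exhaustive enumeration over permutations for up to five particles per
frame. Tracks missing a detection persist for `memory` frames (default
3) at their last position before being closed. Identity swaps (crossing
animals) are not resolved automatically; `relabel_tracks` applies a
manual correction table, mirroring how validation overlays are used in
practice.

**Trajectories.** A track is split into landing-to-departure episodes at
detection gaps longer than `gap_s` (default 1 s). Landing is the first
detection of an episode and take-off the last, since the camera images
only the substrate.

**Validation.** `evaluate_tracking` matches each track sample to the
nearest ground-truth agent within 10 px; a track whose matched identity
is not unique along its length (swap or merge) counts as one error, and
the error rate is errors over tracks checked.

## Body shape and engorgement

Appendages are removed by a morphological opening with a disk of radius
0.15 mm — wider than a leg (~0.05 mm), much narrower than the abdomen.
Because the opening also clips the high-curvature abdominal tip, the
opened mask is dilated back inside the original body mask; this restores
the tip while re-adding only negligible appendage stubs. The boundary of
the largest remaining component is resampled to 120 points and refined
with an active contour (α = 0.01, β = 0.5, 100 iterations) attracted to
the gradient of the smoothed mask, whose peak sits at the sub-pixel
boundary independently of illumination. A diverged snake (area off by
more than 2× from the mask) falls back to the mask boundary. Area is the
shoelace area of the contour; width is the extent along the minor
principal axis. On synthetic ellipses and circles both measurements land
within ~2% of the analytic values.

Engorgement uses two empirical criteria on the abdominal-area series:

1. fold expansion = P90(area, full trajectory) / P10(area, first 10 s)
   must reach **1.3** (inclusive: the area "needs to expand 1.3 fold");
2. P90(area) must strictly exceed a genus threshold: **2.4 mm²**
   (*An. stephensi*, *An. coluzzii*) or **3.0 mm²** (*Ae. aegypti*,
   *Ae. albopictus*) — "needs to exceed" read as a strict inequality.

Percentiles use the linear-interpolation convention (configurable).
Series shorter than the 10 s baseline window use the whole series as the
baseline. No closed-form definition of the engorgement time exists for
the running measurement, so it is defined as the first time the running
area satisfies both criteria (≥ the genus cut and ≥ 1.3 × the baseline
P10); on synthetic logistic feeding ramps this lands between the ramp
midpoint and the plateau.

## Locomotion and ethograms

Speed is computed from centroid positions by central differences
(one-sided at the ends) and smoothed with a running median over 3 frames,
which suppresses single-frame segmentation jitter without lagging
transitions. Classes: stationary < 2 mm/s, walking 2–12 mm/s, flight
> 12 mm/s. The boundary convention is unstated in the underlying
decision rule, so walking is taken as the closed interval [2, 12] and
both thresholds are configurable. Ethograms are run-length encodings of
the per-frame labels stored as half-open frame intervals, so
encode → decode is exactly lossless; the engorgement time is attached as
a point mark. Trajectory statistics: duration (landing to take-off),
distance (sum of per-step displacements whose arrival frame is not
flight-labeled — flight displacements are not surface locomotion), and
mean velocity = distance / surface time, which therefore includes
stationary periods in the denominator; this choice is documented rather
than inferred.

## Pose kinematics

Pose tables use the common three-header-row CSV dialect (scorer /
bodyparts / coords with x, y, likelihood). Frames whose abdominal tip or
center falls below `min_likelihood` (default 0.9) are invalid for
alignment; gaps of at most 5 frames are filled linearly, longer gaps
become NaN and are excluded from feature assembly. The egocentric frame
puts the abdominal tip at the origin with +x toward the abdomen center
(posterior → anterior; the axis direction is a convention choice), and is
a proper rigid map plus px→mm scaling, so inter-part distances are
preserved and any rigid motion of the raw pose leaves the output
unchanged (tested to 1e-6 mm).

Spectrograms use the complex Morlet wavelet `cmor1.0-1.0` (bandwidth and
center frequency 1), 25 log-spaced channels between 0.5 Hz and Nyquist,
mean removed first. Peak localization is cross-checked against a direct
convolution oracle written independently of the wavelet library.
Features (egocentric coordinates concatenated with wavelet amplitudes)
are standardized to zero mean and unit variance; columns that are
constant up to float rounding are dropped (standardizing them would only
amplify numerical noise) with a log record. The 2-D embedder is
pluggable — t-SNE by default, PCA as a deterministic alternative — since
the contract is the feature assembly and scaling, not a specific
embedder.

## Region-of-interest analytics

Polygons are simple (validated on load) and membership is
boundary-inclusive: contacts at the coated edge are the scientifically
interesting case, so a point exactly on an edge counts as inside.
Landing rate counts trajectories whose first sample lies inside, divided
by the polygon area in mm² (the supplied polygon's area, not any larger
coated region it may represent). Dwell time credits each trajectory to
each region with the time its centroid spends inside, so an episode
spanning two surfaces is split proportionally; the per-region mean is
over contributing trajectories. Touch-and-go requires landing inside and
total residence strictly below 0.5 s. Appendage contacts are maximal
runs of inside-frames per body part, with single-frame dropouts bridged
(tracking jitter; configurable) and sub-threshold-likelihood frames
ignored.

## Synthetic generators

The scene generator emulates the study conditions: dark agents
(background 200, agent 60 on an 8-bit scale, matching transmitted-light
contrast) composed of an ellipse body (semi-axes 1.5 × 0.5 mm), six 1 px
legs, and a 0.5 mm proboscis; Gaussian pixel noise; 25 µm/px and 25 fps
defaults. Behavior programs run per agent: stationary agents do not
move, walking speeds are drawn uniformly from 2.2–10.8 mm/s (a 10%
margin inside the 2–12 mm/s class so ground-truth labels are
unambiguous), flight is rendered as absence from the substrate, and
feeding dilates the minor axis along a smooth logistic ramp (default
1.5-fold over 5 s — the published expansion curves are smooth but give
no functional form). Ground truth records, per rendered agent and frame,
the silhouette's intensity-weighted centroid (what an ideal detector
measures), the behavior label, and the analytic body area; the
engorgement time is the end of the dilation ramp. Agents reflect off the
walls before any appendage reaches the frame edge, so silhouettes are
never clipped.

What the generator does **not** emulate: photometric texture, wing and
flight kinematics, soft-body deformation, occlusion shading when animals
overlap, excretion droplets (a known *Anopheles* confounder), and the
stylet. Passing tests therefore demonstrate the correctness of the
measurement chain, not robustness to every nuisance of real video.

The pose generator reproduces qualitative signatures only — circular
foreleg motion with static middle legs (grooming), tripod-phased leg
oscillation along the body axis (walking), and sharp-attack pulls of the
fore/middle legs toward the body (probing) — embedded in image
coordinates at a random position and heading. No quantitative gait model
is implied.

## Problem sizes and numerical choices

Test scenes use 640 × 640 px frames with 2 agents and 5–20 s programs,
large enough for unambiguous tracking geometry while keeping the full
suite around two minutes. The two-agent feeding scene measures body
shape on every second trajectory frame; the area series is then sampled
at 12.5 Hz, which leaves the percentile-based engorgement criteria
unchanged. Bisections for decision boundaries run to 1e-5 and are
reported at the printed precision of each threshold. Boundary sweeps on
frame-quantized quantities (touch-and-go residence at 40 fps) report the
supremum of the accepted set, i.e. the smallest rejected residence,
since the accepted interval is open at the cutoff.

Degenerate inputs are rejected rather than guessed at: blank crops,
empty tracks, zero-area polygons, tip-equals-center poses,
above-Nyquist frequencies, and negative velocities all raise.

## Known limitations

- Crossing animals can swap identities; the linker does not model
  occlusion, matching the manual-correction workflow.
- The temporal-median background absorbs animals that remain stationary
  for most of a recording; supply a measured background in that case.
- Engorgement relies on a clean body segmentation; touching animals or
  strong excretion droplets bias the area series.
- Width measurements include residual appendage stubs of up to the
  opening radius when legs attach laterally (~0.1 mm bias on synthetic
  agents).
- The t-SNE embedding is seeded but, like all such embeddings, not
  metrically meaningful across runs with different data.
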