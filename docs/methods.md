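# Methods

This note records the models implemented in `arpquant`, the defaults and
why they were chosen, what the synthetic data does and does not emulate,
and the numerical decisions made where the procedure was genuinely open.

## Coordinate and unit conventions

Frames are 0-based; a spot at pixel (row, col) has position
x = col·pixel_size, y = row·pixel_size in micrometres, with the origin at
the centre of pixel (0, 0). Positions are micrometres everywhere outside
detection internals; times are seconds; molecule counts are dimensionless;
binding concentrations are micromolar and titration concentrations
nanomolar, matching the conventions of each assay. Default pixel sizes are
0.065 μm (patch movies, 100× objective) and 0.325 μm (bead movies, 20×);
default frame intervals are 1 s (patch) and 70 s (bead). The inter-frame
interval of patch acquisitions is an open experimental parameter and is
therefore configuration, not a constant.

## Image corrections

Corrections run in the order illumination → photobleaching → cytosol.

*Illumination.* The profile is estimated as a wide Gaussian blur
(default scale 2 μm) of the temporal median frame per channel, normalised
to mean one, and divided out. The estimate needs a diffuse background to
read from: when the median frame carries no diffuse level (its median
pixel below 10× the high-frequency residual noise — the situation after
background subtraction), the field is taken as flat and the correction is
the identity. This guard is what makes the correction pipeline idempotent.

*Photobleaching.* Whole-frame mean intensity versus time is fitted per
channel to offset + amplitude·e^(−rate·t); the above-offset signal is
divided by the decay. A mono-exponential whole-frame fit was chosen
because it is the simplest model that is testable by round trip against
the generator. Fits that pin at the rate bound, explain less than half the
variance, or have amplitude below 1% of the mean are reported as the null
model and the channel is left uncorrected: frame-mean fluctuations driven
by patch activity must not be mistaken for bleaching.

*Cytosol subtraction.* The local diffuse background is a large-radius
(default 2.5 μm, ten spot radii) rank filter computed on a strided
subsample, resampled, and subtracted with negatives clipped to zero. Two
details matter for stability under re-application. First, the rank is a
guard-banded median (40th percentile): after one subtraction about half
the remaining pixels are exactly zero, so an exact median would sit on a
knife edge. Second, the subtraction is gated on significance — background
below 5 standard errors of the rank estimator (errors propagated from the
image's robust noise sd) is treated as absent. The residual bias of the
guard band is ≈0.25 noise sd, a constant pedestal that cancels in the
annulus-corrected spot intensities used downstream.

## Patch detection and quality calibration

Spots are detected per frame with a scale-normalised Laplacian of
Gaussian at σ = diameter/(2√2) for the 0.5 μm default blob diameter, an
optional 3×3 median prefilter (on for the dimmer Las17 channel, off for
Abp1), and sub-pixel refinement by intensity-weighted centroid within the
spot radius. `corrected_intensity` is the pixel sum within the spot radius
minus the annulus-median local background.

The quality threshold of 5 is a detector-scaled calibration, not a
portable constant, so the quality score is defined to make it meaningful:
quality = LoG response / (robust image noise sd × L2 norm of the LoG
kernel), i.e. the response in units of its expected noise standard
deviation. The noise sd uses a half-normal median estimator on
zero-inflated (background-subtracted) images and a plain MAD otherwise.
Normalising by the response image's own MAD instead is unstable on
clipped backgrounds, whose response distribution is heavy-tailed relative
to its MAD. Maxima within one spot radius of the image border are
discarded as filter boundary artifacts. Raising the threshold can only
remove detections (monotonicity holds by construction).

## Linking, curation, pairing, alignment

Linking is greedy nearest-neighbour within 0.5 μm frame to frame, with
track ends joined across at most 2 missing frames within a 0.5 μm
gap-closing distance — the standard single-particle settings for these
movies. Curation drops tracks touching the first or last frame (lifetime
not fully recorded), drops both members of any concurrent pair closer
than 0.5 μm ("well separated" has no canonical distance; the linking
distance is reused), and optionally keeps only tracks starting inside a
cortex ROI mask, since cell-boundary selection is a manual step.

Las17/Abp1 tracks pair one-to-one, greedily by increasing distance
between time-averaged positions (≤0.5 μm) with lifetimes overlapping or
abutting within 10 s. The pairing rule is a package choice; unpaired
tracks are returned so its effect is auditable. Events align at t = 0 =
the Abp1 corrected-intensity maximum, ties resolving to the earliest
frame; averaging across events uses this axis.

## Molecule counts and per-event metrics

molecules(t) = corrected intensity(t) × reference count / control-strain
average maximum corrected intensity, per channel. Reference counts are
literature calibration values and deliberately have no defaults: they are
required configuration. Because the control average is measured by the
same pipeline (same spot radius, same background rules), systematic
intensity factors — PSF truncation at the measurement radius, gain —
cancel in the conversion.

Accumulation and deaccumulation rates are least-squares slopes over all
points from first appearance through the maximum, and from the maximum
through the last measurable frame; a phase with fewer than 3 points
leaves the rate undefined and flagged. Assembly time is t(Abp1 max) −
t(first Abp1). Displacement is measured on the Abp1 track from its first
detected position; internalization requires strictly more than 0.25 μm.
"Las17-early" is operationalised as: the Las17 molecule-count argmax
precedes the first frame with detectable Abp1 signal (the detector
threshold defines "detectable"); neither side of that comparison has a
canonical formal definition, so both choices are documented here.

## Bead motility

Beads are segmented by thresholding at 50% of the above-background range.
The actin shell renders a bead as a bright ring whose rear is contaminated
by the comet tail, so the bead centre is the centroid of the ring's dark
interior (hole), which the tail cannot bias; the ring-pixel median
distance estimates the radius. Exclusions: crossing tracks (inter-track
distance below the sum of radii at any common frame, both excluded),
diameter > 3.8 μm, or a trajectory whose bead edge leaves the field.

Velocity is the central-difference speed in μm/min with an optional
3-frame boxcar (whether the original measurement was instantaneous or
window-averaged is unstated, so the window is configuration). The motion
direction per frame comes from the 3-frame displacement, falling back to
the net track displacement below 0.05 μm/min. Line profiles are sampled
along the motion axis through the bead centre; the leading and trailing
local maxima bracketing the central minimum give edge intensities and
peak separations, and the relative polymerization rate is velocity ×
trailing-peak intensity — the actin maximum sits at the rear bead
surface. The metric is linear in image gain and therefore reported in
arbitrary-unit·μm/min.

Angular profiles aggregate pixels with centre distance within [4, 15]
pixels of the bead position (radii are specified in pixels by convention;
μm equivalents are carried alongside), binned every 30° relative to the
motion direction with bins centred on 0°, 30°, … so the 180° bin
straddles the tail symmetrically. Bundle peaks use prominence (default
3× the profile MAD), minimum separation (default 1 μm) and optional
width/window criteria; hand-annotated profiles are accepted as CSV so the
operator applies to real annotations.

## Biochemical fits

The tight-binding quadratic is fitted for K_D only, with the receptor
total fixed at the 50 nM assay design value — it is known exactly, and
floating it would degrade identifiability on 8-point titrations. Bounds
are [1e-6, 1e3] μM with multi-starts at {0.01, 0.1, 1} μM; a fit pinned
at a bound is flagged. The MPR is the maximum sliding-window
least-squares slope (default 5 points — a compromise between noise
rejection and peak-slope bias, configurable because the underlying
"slope at each time point" admits no unique discretisation). RFU→nM
conversion anchors the trace between a baseline and a plateau (supplied,
or taken as the first sample and the final-5% mean) and scales by the
polymerizable actin pool; the actual fluorimeter calibration constants
are not recoverable, so anchoring is the package's convention.
Equilibration time is the earliest time after which the signal stays
within 5% of its final value.

## Statistics

Group comparisons are an ordinary one-way ANOVA with Dunnett's
many-to-one test against the designated control, computed from the
multivariate-t distribution with a fixed integration seed so reports are
reproducible. Adjusted p values are never smaller than the unadjusted
pairwise p.

## Synthetic data: what it emulates, and what it does not

Patch movies place 20 non-overlapping patches in a 10.4 μm field over
75 frames at 1 s. Intensity kinetics are piecewise linear
(accumulate → peak → deaccumulate) *by design*: the analysis defines
rates as straight-line slopes, so generator and analyzer share an exact
expectation and every downstream stage becomes a recovery test.
Per-patch parameters are drawn uniformly: 8–12 s phases, 600–1000 peak
Abp1 molecules (matching control-strain scale), 100–200 peak Las17
molecules, Las17 leading by 8–15 s, 97% of events internalizing by
0.3–0.5 μm. Internalized patches translate inward during the first half
of deaccumulation — scission and vesicle departure precede full
disassembly — so the displacement is attained while the patch is still
detectable. Rendering uses a Gaussian PSF (σ = 0.1 μm), camera offset
100, gain 4 a.u./molecule (putting the dim Las17 channel at peak-pixel
SNR ≈ 5, the regime in which both channels are trackable), read noise
sd 8, mild bleaching (0.002/s) and a 10% linear illumination gradient.
Realistic molecule-count noise at endocytic sites is not characterised,
so these noise settings are stated assumptions, not measurements.

Bead movies render a 3 μm bead as a surface ring with an exponential
comet tail (5 μm decay length) translating at 1 μm/min over 70 s frames,
plus optional bundle streaks parallel to the trajectory at fixed
transverse offsets. The pyrene generator is a logistic stand-in — chosen
for its analytic maximum slope r·P_total/4, the oracle for MPR
extraction — not a mechanistic nucleation model. Depletion titrations
come from the tight-binding quadratic itself with multiplicative Gaussian
noise.

Consequently, passing recovery tests demonstrates correctness of the
measurement pipeline under known ground truth; it does not validate the
piecewise-linear or logistic models as descriptions of real kinetics,
nor the noise model as a description of real cameras. Brownian patch
jitter, cell-to-cell variability, comet-tail shape fluctuations and
filament-level network structure are all outside the generators' scope.

## Problem sizes

Default test and verification runs use one 75-frame two-channel
160×160 px patch movie (20 patches), one 20-frame 128×128 px bead movie,
100 replicate K_D fits at 1% noise, and 10⁴-point grid searches as fit
oracles; these sizes make every recovery property measurable while the
whole suite completes in well under a minute.

## Known limitations

Tracking is 2-D and greedy (no global assignment as in LAP trackers);
pairing is heuristic; cell segmentation and scission detection are out of
scope; detection quality calibration is an in-package convention and not
numerically interchangeable with other software's thresholds; the bleach
model is global mono-exponential per channel; and equilibration analysis
assumes an approach to a plateau rather than fitting exchange kinetics.
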