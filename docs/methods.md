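# Methods

## The reference displacement field

The synthetic generator prescribes, for a point at distance `r` and angle
`θ` from the branch tip and axis, the matrix displacement accumulated since
t = 0:

```
u(x, t) = A · cos^k(θ)          (0 for θ > 90°)
          · exp(−r / λ)
          · g(t)
          · ê(x → tip)

g(t) = ρ · t/P + (1 − ρ) · (1 − cos(2π t / P)) / 2
```

This functional form is the package's own construction.  It is the
simplest field that reproduces, with independently tunable parameters, the
three qualitative features of matrix deformation around an invading
branch: the decrease with angle to the branch axis (`cos^k`, exponent
`k ≥ 0`; `k = 0` gives an isotropic front field), the decay with distance
(`exp(−r/λ)`), and periodic contraction–relaxation cycles that leave a net
plastic gain (`g`: a raised-cosine elastic cycle of period `P` carrying a
linear ramp that accumulates `ρ·A` per period, `ρ ∈ [0, 1]` the plastic
fraction).  It is kinematic only: no fiber mechanics, no force balance, no
constitutive model.

Beads are advected frame-to-frame by field increments evaluated at the
current position, `x(t+Δ) = x(t) + u(x(t), t+Δ) − u(x(t), t)`, so tracers
accumulate history the way physical beads do, rather than being re-placed
by a total-field evaluation.  Ground-truth positions are recorded before
rendering; rendering draws Gaussian spots of width `psf_sigma` voxels plus
i.i.d. additive Gaussian noise.  Poisson shot noise is deliberately
omitted so the signal-to-noise ratio stays a single knob.

Defaults the acquisition does not constrain (documented as assumptions):
frame interval 10 min (matching the acquisition protocol), bead peak
intensity 100 with noise σ as the SNR knob, `psf_sigma` 1.5 voxels, voxel
size 2 µm, bead placement uniform with an optional minimum-spacing
rejection sampler.

## Drift correction

Stage drift is estimated per consecutive frame pair as the integer shift
in `[−max_shift, +max_shift]³` maximizing the normalized cross-correlation
of the overlapping region, computed by sliding the interior crop of the
earlier frame over the later one (FFT-accelerated template matching; an
axis too small for the full window gets the largest feasible range).
Normalized correlation was chosen for robustness to intensity scaling.
Ties break toward the smaller-magnitude shift.  Pairwise chaining (rather
than all-to-reference registration) accumulates a random-walk error over
very long movies — accepted because consecutive frames are the natural
comparison for slowly drifting stages.  Optional subvoxel refinement
interpolates a quadratic through the correlation peak; it is off by
default (integer, stepwise shifts).  Flat frames raise an
"uninformative frame" error; a peak on the window edge warns that
`max_shift` may be too small.

## Bead detection and linking

Detection order matters and is fixed: (1) Gaussian smoothing with
`smooth_sigma` = 1 voxel — a matched filter for spot-like signals; without
it, single-voxel noise excursions pass any threshold low enough to keep
real beads at SNR ≈ 5; (2) intensity threshold (default: Otsu on the
smoothed frame); (3) removal of connected components smaller than
`min_size` = 5 voxels (smoothed noise excursions are tiny next to a real
spot footprint); (4) removal of components touching the boundary margin;
(5) for every surviving pair of centroids closer than `min_distance`
(default 5 µm), removal of BOTH members.  Boundary removal precedes pair
removal, so a bead whose only close neighbour touched the boundary
survives.

Centroids are computed on the component patch linearly interpolated by an
`upsample` factor (default 4), with threshold-subtracted weights
`max(I − threshold, 0)`: subtracting the threshold makes the centroid
continuous as noise moves voxels across the mask edge, removing a
~0.3-voxel jitter observed with raw thresholded weights.  Coordinates are
0-based voxel indices converted to µm at the voxel center.

Linking is mutual-nearest-neighbour matching between consecutive frames
within `link_radius` (default 10 µm per 10-min frame); chains shorter than
three consecutive frames are dropped, and a missed detection terminates a
track (no gap closing).  A brute-force globally-optimal assignment on
small instances serves as the test oracle for the matching rule.

## ECM deformation statistics

Sign convention, fixed everywhere: the signed scalar
`s = −Δu · ê(tip → bead)` is positive when the bead moves toward the tip
(contraction) and negative for relaxation.  The near field is the region
within 300 µm of the tip.  The cumulative series sums `s` per bead over
time and reports the mean across beads; a bead leaving the near field is
frozen at its exit value — it stops accumulating but keeps contributing
its frozen value to the mean, so the series is continuous under population
changes (the alternative, dropping it from the mean, produces jumps that
are artefacts of the bookkeeping, not of the matrix).  Angular profiles
use 15° bins by default; stripe profiles use 100-µm distance bins; empty
bins are reported as missing (NaN with n = 0), never as zero.  Phase
labels threshold the per-frame mean `s̄(t)` against a noise floor
(recommended: twice the median per-frame |s̄| of a zero-field calibration
scene; default 0).  The relaxation delta after a perturbation event is
`value(end) − value(event)`, negative when the matrix recoils.

## Fiber alignment

Per-pixel orientations come from the structure tensor (Gaussian window
`tensor_sigma` = 1.5 px): the fiber direction is the minor eigenvector of
the smoothed gradient outer product.  Pixels are kept when coherence
`(λ₁ − λ₂)/(λ₁ + λ₂)` ≥ 0.2 AND tensor energy > 5% of its image maximum.
Both filters matter, and in opposite directions: without the energy floor
the histogram is flooded by near-zero-gradient background whose
orientation is random (a heavy uniform tail), while *raising* the
coherence threshold much above 0.2 biases the distribution — pixels on
fibers oriented far from the local dominant direction sit in
higher-contrast neighbourhoods, lose coherence, and are preferentially
dropped, narrowing the recovered distribution.

The orientation histogram is axial (angles mod 180°, domain [−90°, 90°),
5° bins by default).  The FWHM fit circularly re-centers the histogram
(mode to 0°) and least-squares fits a Gaussian continued periodically at
±180°; FWHM = 2√(2 ln 2)·σ̂.  No constant background term is fitted: under
periodic continuation a uniform background is numerically degenerate with
a very wide Gaussian (fits with a free offset underestimated broad
distributions by 20–30%), and background suppression is the extraction
filters' job.  A fit wider than the domain is clipped to 180° and flagged
as near-isotropic.  `FWHM_max` is always the maximum over the supplied
set of regions/conditions, never a constant.

The synthetic textures render fibers as analytic Gaussian-profile ridges
(exact distance to the segment) rather than rasterized anti-aliased lines;
rasterization stair-steps otherwise add degrees of per-pixel orientation
noise that dominates narrow distributions.

## Cell dynamics

Dense optical flow runs on 2D frames (single slice or maximum projection)
using the iterative Lucas–Kanade estimator of scikit-image wrapped in a
coarse-to-fine image pyramid (3 levels by default): single-scale ILK only
captures displacements up to roughly its window radius, while cells moving
at 1 µm/min traverse ~10 px between 10-min frames at 1-µm pixels.  Flow
vectors are oriented feature-motion-forward (frame t → t+1) and scaled to
µm/min from the voxel size and frame interval.  The decomposition
`v_par = v · ê_axis` (outward positive), `v_orth = v · ê_axis⊥` is exact
and invertible; image rows increasing downward are accounted for when
mapping to the mathematical y-axis.

Phases: per frame pair, Φ = |mean of sign(v_par)| over valid (optionally
speed-floored) pixels; Φ ≥ 0.5 labels the pair collective with the sign of
the mean, otherwise uncoordinated; equal consecutive labels merge into
intervals.  Both the Φ definition and the 0.5 threshold are package
conventions, exposed in the configuration.  Cell–ECM coupling is the
Pearson (optionally Spearman) correlation between `v_par(t)` and `−s̄(t)`
scanned over integer lags; positive lag means the cells lead the matrix.
The sign pairing encodes the observed phenomenology: outward collective
motion accompanies matrix relaxation in front of the tip, inward motion
accompanies contraction.

## Validation by parameter recovery

Because every generator parameter is known, each stage is validated by
recovery (module `branchmech.validation`, exercised both by the test suite
and by `scripts/acceptance.py`): exact integer drift recovery plus
agreement with an exhaustive brute-force correlation search; localization
RMSE < 0.25 voxel with detection precision/recall ≥ 0.98 at SNR 5 (spot
spacing ≥ 4× the effective spot width, i.e. the rendering PSF convolved
with the matched filter); exact-count agreement of the filter rules with a
brute-force oracle on constructed scenes; ≥ 99% correct links for
constant-velocity beads stepping 0.4× the link radius; cumulative series
equal to n·δ exactly for constant steps and matching the m·ρ·A closed-form
plastic ramp on a ρ = 0.5 three-period field; strictly decreasing binned
s̄(θ) for k ∈ {1, 2, 4} and a flat profile for k = 0, with beads on a thin
radial shell so the radial decay does not confound the angular bins;
stripe means within 5% of the analytic exponential bin averages at 500
beads; FWHM within 5% of 2√(2 ln 2)·σ for σ ∈ {5°, 10°, 20°, 40°}
(averaged over three replicate textures of 800 fibers on 1024² px, 2.5°
bins — the estimand is the generating width, and a single 800-fiber
texture fluctuates by a few percent); uniform-translation flow speed
within 10%; exact phase-schedule recovery on jitter-free scenes; and a
coupling peak > 0.9 at the constructed lag with independent series inside
the permutation null.

Problem sizes were chosen so the whole suite runs in minutes on one CPU
while keeping each statistical check well powered.

## What the synthetic scenes do not capture

The generator validates the measurement chain, not the biology or the
optics: real collagen displacement fields are not separable in (r, θ),
real fiber textures have curvature, variable thickness and depth
structure, bead SNR varies with depth, nuclei deform and overlap, and the
bright organoid body sits inside the frame.  Passing recovery tests
therefore demonstrates that the pipeline measures prescribed kinematics
accurately under controlled degradation (noise, drift, density), not that
it is robust to every artefact of live-cell microscopy.  Tip-cell
exchange counting is intentionally not automated: it requires visual
inspection, and the package only exports trajectories for manual
annotation.
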