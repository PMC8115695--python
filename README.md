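# branchmech

Quantitative analysis of branch mechanics for organoids growing in fibrous
extracellular matrix (ECM), from time-lapse confocal imaging.

Mammary-gland organoids embedded in floating collagen I gels elongate
branches by invading the surrounding matrix.  The mechanics of that process
are visible in three channels of a time-lapse acquisition: tracer beads
embedded in the gel report matrix deformation, the collagen reflection
channel reports fiber alignment, and the nuclei channel reports collective
cell motion inside the branch.  `branchmech` turns those movies into the
standard quantitative read-outs:

- **Drift correction** — per-frame rigid shifts found by exhaustive
  normalized cross-correlation over a voxel window, chained relative to
  frame 0.
- **Bead tracking** — intensity-threshold masking, sub-voxel centroids on
  an upsampled intensity grid, boundary and minimum-distance filters, and
  mutual-nearest-neighbour linking with a three-consecutive-frame rule.
- **ECM deformation statistics** — every bead step is projected into the
  branch frame (tip position + outward axis) giving its distance *r*, angle
  *θ* to the axis, and signed toward-tip component *s* (positive =
  contraction toward the branch).  From these: the near-field (≤ 300 µm)
  cumulative mean displacement curve, the angular anisotropy profile
  *s̄(θ)*, 100-µm distance-stripe profiles, contraction/relaxation phase
  labels, and post-perturbation relaxation deltas.
- **Fiber alignment** — per-pixel orientations from the structure tensor,
  an axial orientation histogram, a Gaussian fit giving the full width at
  half maximum, and the degree of alignment

  *d* = (FWHM<sub>max</sub> − FWHM) / FWHM<sub>max</sub>,

  where FWHM<sub>max</sub> is the maximal FWHM measured across all analysed
  conditions (so *d* = 0 for the least-aligned condition and *d* → 1 for
  perfect alignment).
- **Cell dynamics** — dense optical flow of the nuclei channel in µm/min,
  decomposed into branch-parallel (*v*<sub>∥</sub>, outward positive) and
  orthogonal (*v*<sub>⊥</sub>) components; a direction-consensus order
  parameter Φ = |⟨sign *v*<sub>∥</sub>⟩| segments the movie into collective
  (outward/inward) and uncoordinated migration phases; and a lag-scanned
  Pearson correlation couples *v*<sub>∥</sub>(t) to the concurrent ECM
  signal −*s̄*(t) (outward cell motion pairs with matrix relaxation).
- **Synthetic scenes** — a generator that renders bead stacks advected by a
  tip-centred displacement field with independently tunable amplitude,
  cos<sup>k</sup> angular anisotropy, exponential radial decay, contraction
  period and plastic fraction, plus fiber textures with controlled
  orientational order and nuclei movies with scheduled migration phases.
  Every scene records its full ground truth, so each analysis stage is
  validated by parameter recovery.

## Worked example

Simulate a branch pulling on its matrix (3 µm peak amplitude, 150 µm decay
length, 60-min contraction period, half of each period's displacement
retained plastically), then run the tracking and deformation analysis:

```python
from branchmech import FieldParams, render_bead_stack, BranchGeometry
from branchmech.bead_tracking import detect_beads_stack, link_tracks, track_displacements
from branchmech.ecm_deformation import project_samples, cumulative_displacement

field = FieldParams(amplitude=3.0, decay_length=150.0, anisotropy_exponent=2.0,
                    period=60.0, plastic_fraction=0.5,
                    tip=(320.0, 64.0, 1.0), axis=(-1.0, 0.0, 0.0))
scene = render_bead_stack(field, n_beads=35, seed=21, n_frames=13,
                          shape=(1, 64, 160), voxel_size=(2.0, 2.0, 2.0),
                          noise_sigma=1.0, min_spacing_um=16.0)

detections = detect_beads_stack(scene.stack, min_distance=5.0)
tracks = link_tracks(detections, link_radius=10.0)
geometry = BranchGeometry(tip=field.tip, axis=field.axis)
samples = project_samples(track_displacements(tracks), geometry)
series = cumulative_displacement(samples, geometry)
```

This prints (13 frames at the default 10-min interval cover two
contraction periods):

```
27 bead tracks from 13 frames
cumulative near-field displacement after 120 min: 1.023 um
  value at period start 1 (60 min): 0.508 um
  value at period start 2 (120 min): 1.023 um
```

The cumulative curve returns to a higher baseline after every
contraction–relaxation cycle: each 60-min period adds ≈ 0.51 µm of
permanent (plastic) matrix displacement, the signature of irreversible
collagen remodeling in front of an elongating branch, while the elastic
half of the cycle contracts and recoils within the period.

The same stages are available from the shell:

```
branchmech simulate --config scene.yaml --seed 7 --out scene/
branchmech drift    --in scene/beads.tif --max-shift 10 --out corrected.tif
branchmech track    --in corrected.tif --out tracks.csv
branchmech deform   --tracks tracks.csv --geometry scene/geometry.json --out deform/
branchmech run      --config run.yaml --out out/
```

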