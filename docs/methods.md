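# Methods

`pb2mc` studies a deep-learning dose-conversion scheme for proton therapy:
a convolutional network maps an analytical pencil-beam (PB) dose — fast but
inaccurate in heterogeneous anatomy — to a Monte-Carlo-quality (MC) dose,
one single-field beam at a time. The package implements the whole chain:
synthetic paired-dose data, canonical beam-frame preprocessing, a
hierarchically dense U-Net with its training protocol, and the dosimetric
evaluation battery (3D γ-analysis, beam's-eye-view range maps, MAE, isodose
DSC, DVH metrics). This note records the models, the conventions, and the
choices made where the design was genuinely open.

## Coordinate and geometry conventions

All volumes live on regular axis-aligned grids with voxel-centre
coordinates; array axes are patient (SI, AP, RL) and world coordinates are
ordered the same way in millimetres. The canonical machine position is
gantry 270°, couch 0°, at which the beam travels along +RL. The
canonicalising rotation undoes the couch angle first (about the AP axis
through the isocenter), then the gantry offset from 270° (about the SI
axis). The composition order and signs are conventions, not physics; the
test suite pins them with a behavioural check — a beam simulated at any
(gantry, couch) must, after forward rotation, propagate along +RL to within
1° — so a sign error cannot pass silently.

Rotation + crop are composed into a single affine resample (one trilinear
interpolation per volume). Trilinear is used for CT and dose,
nearest-neighbour for masks. Fill values are physically neutral: −1000 HU
(air) for CT, 0 for dose and masks.

Interpolation accuracy: a double trilinear pass (forward + backward
rotation) on a 2 mm grid round-trips within 2% of maximum only for fields
whose curvature is resolved by roughly ≥ 6 voxels (Gaussian σ ≳ 12 mm at
2 mm spacing). Sharper structure loses more; this is inherent to trilinear
resampling, and it is why the synthetic beams use distal falloff widths the
grid can resolve (below).

## Normalisation

CT is mapped to [0, 1] over a fixed window of [−1000, 2000] HU, clamped; a
fixed window keeps the mapping consistent across phantoms where a
per-volume min/max would not. Both doses are divided by the maximum PB dose
inside the crop (`pb_max`), so `max(pb_norm) == 1` exactly and the MC
target keeps its amplitude difference from PB — the network must learn
absolute dose errors, not merely shapes. Zoom-augmented copies reuse the
parent sample's `pb_max` and are not re-normalised.

## Synthetic phantoms and paired dose engines

No public dataset pairs PB and MC doses, so the study's data are
manufactured with a transparent error model:

* **Phantom**: a soft-tissue (0 HU) ellipsoid body in air, with air
  cavities (−1000 HU ellipsoids) and bone slabs (+700 HU boxes) placed
  inside, plus an ellipsoidal CTV. The first heterogeneity is anchored
  within 20 mm of the CTV surface so every phantom has heterogeneity near
  the target. Cavities are kept pairwise disjoint (so component counts are
  testable); a small Gaussian blur (0.6–1 voxel) softens label edges. HU →
  relative stopping power uses a stand-in piecewise-linear calibration
  through (−1000, 0.001), (0, 1.00), (700, 1.44), clamped.

* **Depth dose**: a spread-out Bragg peak (SOBP) built as a nonnegative
  least-squares stack of K = 25 range-shifted pristine peaks, flat within
  ±2% over the modulation interval. The pristine curve is an entrance
  plateau (0.35 → 0.45) blended (smooth max, p = 8) with a flat-topped
  unit peak between R − σ_peak and R and a Gaussian distal falloff σ_distal.
  Defaults σ_peak = 3 mm, σ_distal = 1.5 mm suit a 2 mm grid; the
  desk-scale study at 4 mm voxels uses σ_peak = 6 mm, σ_distal = 4 mm so
  the falloff stays resolvable (1.5 mm structure on a 4 mm grid would be
  dominated by resampling error rather than by the physics being tested;
  4 mm distal σ is within the range of clinical passive-scattering beams).

* **MC-like engine**: per lateral ray, water-equivalent depth
  WED = ∫ RSP ds (midpoint rule along the canonical beam axis); voxel dose
  = SOBP(WED) × error-function aperture profile with depth-growing penumbra
  σ(d) = entrance_sigma + sigma_growth·d, then per-depth-slice Gaussian
  smearing with the depth-grown part sigma_growth·d (a scatter surrogate),
  and finally multiplication by local RSP (a dose-to-medium surrogate that
  also suppresses dose in air). Each field is scaled so the CTV median
  equals the prescription.

* **PB-like engine**: identical except each ray's WED is replaced by its
  lateral average over a `pb_beamlet_width` window, and no slice smearing
  is applied. This reproduces the clinically relevant PB failure signature
  — range errors at distal edges behind heterogeneities and missing
  scatter — with an oracle simple enough to reason about. When
  `pb_beamlet_width` equals the voxel size and `sigma_growth` = 0 the two
  engines coincide identically, which the tests exploit.

* **Degradation calibration**: the error magnitude is a free parameter of
  the surrogate, not something the clinical literature pins down for this
  geometry. It is set once (sigma_growth = 0.15 mm/mm,
  pb_beamlet_width = 28 mm at desk scale) so that PB-vs-MC γ(3%/3 mm)
  passing lands broadly below 90% — errors large enough to be worth
  correcting, small enough that PB remains a sane starting point. It is
  **not** tuned to reproduce any clinical passing rate.

Datasets group beams into synthetic "plans" of 3 beams sharing one phantom;
gantry is uniform over [0°, 360°) and ~40% of beams get couch angles drawn
from ±[10°, 30°] (non-coplanar, as is common in head-and-neck proton
therapy). Train and test plans use disjoint phantom seeds.

What the simulator does **not** emulate: nuclear interactions and MC noise,
realistic CT texture and anatomy, collimator/compensator scatter, or the
actual error distribution of any clinical PB implementation. Passing tests
therefore show that the pipeline corrects *this* error family end to end —
they are evidence about the method's machinery, not about clinical
accuracy.

## Network and training

The converter is a hierarchically dense U-Net: dense convolution blocks
(two 3×3×3 conv+ReLU layers, each consuming the concatenation of all
previous feature maps in the block), dense down-sampling (stride-2
convolution with ReLU concatenated with 2× max-pooling), and an up path
(2× nearest-neighbour upsampling after a 1×1×1 channel compression, a
conv+ReLU, concatenation with the same-level encoder features, then a dense
block). The head concatenates the raw input channels back in — a global
dense skip — and applies a 1×1×1 convolution with ReLU, so the output is
nonnegative.

Widths and depth are free parameters (defaults: 4 levels, 16 base/growth
features; desk scale: 3 levels, 8/8). The head is initialised as a **PB
passthrough** (weight 1 on the PB input channel, small noise elsewhere):
an untrained network reproduces the PB dose, so optimisation starts from
the PB baseline instead of from noise and the comparison "does the trained
network beat PB" is meaningful even with a short schedule. This is an
identity-style initialisation choice, in the spirit of residual learning,
not an architectural requirement.

Training: Adam, initial learning rate 1e-3, MSE loss on
(ct_norm, pb_norm) → mc_norm, batch size 4, learning rate ×0.1 when
validation loss stalls for `lr_patience` epochs, early stop after
`early_stop_patience` stalled epochs, maximum 500 epochs; the
best-validation-loss weights are restored (the standard pairing with early
stopping). Cross-validation is 3-fold at the *plan* level (all beams of a
plan stay together), validation folds are never augmented (augmented
copies in validation would leak the augmentation policy into the stopping
rule), and inference averages the three fold models. One master seed fans
out via `numpy.SeedSequence` to dataset generation, fold assignment,
weight initialisation and batch shuffling; the whole pipeline is pure
numpy and bit-reproducible given the seed.

The network and its backpropagation are implemented in numpy inside the
package (`pb2mc.nn`): a small reverse-mode tape with convolutions expressed
as single GEMMs over padded volumes. Gradients are exact and are verified
against finite differences in the test suite.

## Ablation arms

* `baseline` — no canonicalisation: beams enter the tensor at their native
  gantry/couch angles (and no back-rotation at inference);
* `rotation` — canonical beam-frame rotation only;
* `rotation_zoom` — rotation plus zoom augmentation with factors 0.8 and
  1.2 applied in the canonical frame (after rotation), tripling the
  training set. Zoom factors outside [0.7, 1.3] are rejected as producing
  unnatural dose patterns.

## Evaluation battery

* **Global 3D γ**: γ(r) = min over candidate points r′ of
  √(ΔD(r,r′)²/δD² + |r−r′|²/δd²), with δD a percentage of the **maximum
  reference dose in the analysis mask** (global normalisation) and the
  low-dose threshold (10%) applied to the **reference** dose. Candidates:
  the evaluated dose trilinearly interpolated on a lattice of step δd/3
  within a sphere of radius 3δd, with an exact early exit (offsets are
  visited by increasing distance; once the distance term alone exceeds
  every running minimum nothing can improve). A brute-force exhaustive
  twin bounds the implementation error at ≤ 0.02 per voxel in tests.
  γ ≤ 1 passes, with a 1e-12 boundary guard so exact-boundary cases do not
  fail by floating-point rounding.
* **Range maps / ARD**: per lateral ray of the canonical-frame dose, the
  range is the distal-most downward crossing of 90% (R90) or 50% (R50) of
  the per-beam prescription, linearly interpolated between bracketing
  voxels; rays never reaching the threshold are NaN. ARD is the mean of
  (R_ref − R_eval)/R_ref over rays finite in both maps (evaluated deeper
  than reference ⇒ negative). "Prescribed dose" for synthetic beams is the
  CTV-median normalisation target.
* **MAE**: mean |D_ref − D_eval| over body voxels with reference dose ≥
  10% of prescription (the threshold side is a convention, recorded in the
  report metadata).
* **Isodose DSC**: Dice overlap of the [low%, high%) prescription bands
  10–30 / 10–50 / 10–70 / 10–90; upper bound exclusive.
* **DVH / RDE**: D_x% is the linearly interpolated inverse of the
  cumulative DVH (equivalently the (100−x)th percentile of the structure's
  voxel doses); RDE = (D − D_ref)/D_ref for D98/D95/D50/D2.

Single-field reports carry γ(3%/3 mm), MAE and ARD(R90/R50) for DL-vs-MC
and PB-vs-MC; plan reports (voxelwise sums of a plan's beams) carry γ at
1/2/3 %/mm, MAE, the four DSC bands and the four DVH RDEs.

## Desk-scale study conditions

The shipped end-to-end study (`pb2mc.pipeline.micro_config`, used by the
tests and by `scripts/acceptance.py`) runs entirely on one CPU: phantoms
and tensors of 16×24×24 voxels at 4 mm, 18 training + 6 test beams (6 + 2
plans of 3), a 3-level 8/8-feature network (~97k parameters), and at most
12 epochs per fold with lr_patience 3 / early-stop patience 5. These sizes
are the package's desk-scale choice; the full-scale configuration
(96×160×160 at 2 mm, 4 levels, 500-epoch ceiling) is reachable through the
same config surface. At desk scale the study reproduces the qualitative
ablation ordering — PB < baseline < rotation ≤ rotation+zoom in mean γ
passing, and the reverse in MAE — not any clinical magnitude.

## Known limitations

* The PB surrogate's degradation is a two-knob caricature (lateral WED
  averaging + missing smear); real PB algorithms err in more ways.
* Trilinear canonicalisation costs the converted dose a few γ-points on a
  coarse grid relative to a dose evaluated on its native lattice; the
  trained network must earn back more than this interpolation handicap
  before it shows a net gain, which it does at desk scale.
* γ values far above 1 are exact only within the search radius (3δd);
  passing rates are unaffected.
* Non-axis-aligned (oblique) acquisition grids and DICOM coordinate
  handling are out of scope; DICOM import is optional plumbing, untested.
* ARD for R90 is sensitive to plateau dose wobble when the plateau barely
  clears 90% of prescription; rays are dropped (NaN) rather than
  extrapolated.
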