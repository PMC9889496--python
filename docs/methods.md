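# Methods

`legquant` quantifies subcutaneous (SCT) and subfascial (SFT) tissue of the
lower extremities from water-only MR volumes: two CNN landmark detectors
define a canonical leg coordinate system, a cross-validated 2.5D U-Net
ensemble segments the two tissue compartments, probability-map entropy
predicts segmentation quality, and per-slice cross-sectional areas are
reported on a normalized leg axis so that volume, distribution and asymmetry
can be compared across scans with different leg lengths, slice spacings and
table positions.  This note records the model, its assumptions and the
numerical choices; every number quoted here is computed by the test suite or
by `scripts/acceptance.py`.

## The canonical leg axis

Each axial slice receives one relative position per leg within a standardized
leg model: ankles at −1, knees at 0, symphysis at 1.045, femoral heads at
1.220, with linear interpolation between landmarks and nearest-segment linear
extrapolation outside them.  These four values are *fixed constants of the
package* (`legquant.leg_model.CANONICAL_POSITIONS`); the cohort mean landmark
distances from which such a model is historically derived are carried as
provenance metadata only and never used in computation, because the printed
means do not exactly reproduce the canonical ratios under either rounding
convention.  Analysis is restricted to positions in [−1, 1.220]; image
content superior to the femoral heads is cropped.

Landmark heights are recovered from a predicted per-slice position curve as
the level crossings of the canonical values: the curve is smoothed with a
5-slice running median, crossings are located by linear interpolation between
bracketing slices, and when noise produces several crossings the one closest
to the crossing of an isotonic (monotone) fit is kept.  A level that is never
bracketed yields a *not detected* flag rather than a fabricated position.

## Synthetic phantoms with closed-form truth

No imaging data ship with the package; every stage is trained and validated
on two-legged phantoms whose geometry is analytic.  Each leg is a bright
subfascial core of radius r(z) inside a dark subcutaneous annulus of
thickness t(z); both profiles are piecewise linear *on the canonical axis*,
so phantoms of different leg lengths share one anatomy.  Above the symphysis
a midline subfascial bridge slab (a minimal pelvis) joins the legs into one
connected body; its height ramps in linearly over 30 mm so no cross-sectional
quantity is discontinuous.  Per-(leg, tissue) reference volumes are exact:
all area profiles are piecewise polynomials of degree ≤ 3 in z and are
integrated segment-by-segment with Simpson's rule, which is exact for cubics.
An asymmetry factor scales one leg's subcutaneous thickness; the annulus
integral stays closed-form.

The simulated water image assigns per-tissue mean intensities (background 0,
SCT 0.2, SFT 1.0 — fat-suppressed contrast), multiplies by a low-order
in-plane polynomial bias field (amplitude ≤ 20%, default 10%), adds Gaussian
noise (default sd 0.05) and clips at zero.  Three label-neutral "joint"
structures modulate intensity inside the subfascial core only: a dark knee
joint, a bright femoral-head ball per side, and a bright symphysis node.
They stand in for the anatomy that makes landmarks visually identifiable in
real scans; labels and closed-form volumes are untouched.  Two corruptions
can be injected into an axial slab for QC experiments: a water–fat swap
(SCT/SFT intensity statistics exchanged; labels untouched — the corruption
degrades the image, not the reference) and a partial-volume Gaussian blur.

What the phantoms do *not* emulate: muscle/bone substructure and texture,
fluid infiltration, non-circular cross-sections, skin, motion artifacts, and
coil-dependent noise statistics.  Passing tests therefore demonstrate that
the pipeline machinery is correct and trainable end to end, not that the
shipped desk-scale weights transfer to clinical images.

## Landmark detection

*Slice-position regression.*  A small convolutional encoder (three
conv–batchnorm–ReLU stages, global average pooling, linear head; ~25k
parameters at the default 8 base channels) maps each 2.5D axial stack —
three slices spaced 5 mm apart, z-normalized by body-mask statistics — to
the (left, right) slice positions, trained with MSE.  Slices without body
foreground are excluded from training and from the inference curve; half the
training slices are drawn within ±40 mm of landmark heights because the
curve is read off at its canonical-level crossings.

*Keypoint detection.*  The volume is resampled to 2.5 mm isotropic, each
axial slice is recentred so the body-mask centroid sits at the
anterior–posterior image centre, and the matrix is cropped to a ±25 mm AP
slab.  Three coronal planes 5 mm apart around the slab centre form the 2.5D
input of a two-scale U-Net that regresses one Gaussian heatmap (σ = 2
voxels) per *anatomical class* — ankle, knee, femoral head, symphysis.
Sides are resolved at decode time from the peak x positions, because
side-specific output channels would require a translation-equivariant CNN to
encode absolute position, which is not learnable from a few dozen images;
for the same reason two normalized coordinate channels are appended to the
input.  Training uses a peak-weighted MSE (weight 1 + 50·target), a
zero-initialized output head, and random 144-row crops (six per image per
epoch, 25% anchored at each image end so border landmarks are seen as often
as mid-leg ones).  Decoding takes the centre of mass of the ≥ 0.5 × max
region connected to the argmax, up to two peaks per class with non-maximum
suppression, inverse-mapped to scanner millimetres.

*Fusion.*  The two estimates are pooled per landmark as an inverse-variance
weighted mean, with per-landmark-class variances measured on
cross-validation folds (a 1 mm² floor keeps weights finite).  On phantoms
the keypoint branch is the precise one (≈ 1–2 mm) while per-slice regression
carries tens of millimetres of ambiguity — the axial cross-sections of a
phantom are far less position-specific than real anatomy — so the weighted
mean effectively follows the keypoint branch while remaining robust to a
missed detection in either method.  Plain averaging is used when no weights
are available.

## Tissue segmentation

A 2.5D U-Net (two pooling stages, base 8 channels, ~21k parameters) maps
each axial stack to {background, SCT, SFT} probabilities.  The loss is
equal-weight cross-entropy plus soft-Dice; the Dice term is computed *per
sample and per class* so thin distal fat rims (1–2 voxels at desk
resolution) are not drowned out by tissue-rich thigh slices.  Training is
subject-level five-fold cross-validation; at test time the fold models'
softmax outputs are averaged voxelwise and the argmax (ties to background)
gives labels.  The foreground is split into legs by assigning each per-slice
connected component to the side of its centroid relative to the body
midline — estimated as the mean midpoint between the two leg centroids on
slices where the legs are separate — and cutting midline-straddling merged
components at that plane.

## Quality control

Voxelwise Shannon entropy of the averaged probability map, H = −Σ p ln p
(nats, bounded by ln 3), is averaged over the eligible region and regressed
against true Dice (ordinary least squares), once per whole volume and once
per slice.  Only slices between the ankles and femoral heads whose segmented
area exceeds 10% of the image section are eligible (an absolute cm²
override exists).  Mean rather than summed entropy makes the volume and
slice scopes comparable and size-invariant; the volume-scope mean equals the
mean of slice means on equal-sized slices.  The regression targets the SCT
class by default; predicted Dice is clamped to [0, 1] and units below a
0.95 threshold are flagged for review.  The slice-wise model exists to
*localize* degradation: on phantoms with injected water–fat-swap and blur
slabs, flagged slices are checked against the known slab extents.

## Quantification

Per-slice areas are voxel counts × in-plane pixel area; volumes integrate
area × *reconstructed slice spacing* (not slice thickness — overlapping
reconstructions double-cover tissue) over slices up to the femoral heads,
reported in litres (0.1 L display precision).  Areas are interpolated onto a
uniform 256-point grid over [−1, 1.220] per leg; edge values are held for up
to 1.5 slice-equivalents beyond the native range and zeroed further out.
Asymmetry decomposes the two legs pointwise into shared = min(L, R) and
excess = |L − R| with side attribution, integrating the excess in litres
with each side's own mm-per-unit factor.  Longitudinal deltas subtract
follow-up from baseline areas on the baseline's normalized grid; decreases
are clipped at zero for the red overlay while signed values stay in the
table.  Figures are drawn from the emitted CSV, so the visualization is a
pure function of tabular output.  Volumes are invariant (≤ 2–3%) under
slice-spacing changes and table shifts; under leg-length scaling the
*normalized profile* is the invariant — longer legs genuinely hold more
tissue.

## Neural-network engine

The CNNs run on a small numpy engine written for this package: im2col
convolutions, batch normalization, 2×2 max-pooling, nearest-neighbour
upsampling, Adam, and manual backpropagation (verified against central
finite differences in the test suite).  Everything is float32 and seeded;
training is bit-reproducible given the configuration seed.  Heatmap heads
are zero-initialized (dense regression starts from the empty map);
segmentation heads use He initialization, since a zero head combined with
Adam's normalized steps stalls the escape from the all-background solution.

## Problem sizes and defaults

The validation suite runs at two scales, chosen once as the package's study
conditions.  Full resolution (1 × 1 × 2.5 mm, 320 × 160 × 384) is used
wherever no learning is involved: analytic volume recovery, landmark
round-trips, normalization invariance (in-plane 2 mm there; the checks are
about the z axis).  Learned components train on a desk-scale cohort:
64 × 64 × 136 voxels at 5 × 5 × 7.5 mm, 30 training / 10 held-out phantoms
with randomized anatomy (leg length ×0.88–1.06, subfascial radii
×0.85–1.15, subcutaneous thickness ×0.8–1.3 capped so legs never merge below
the symphysis, ~30% asymmetric left legs, noise sd 0.05, bias 10%), 5-fold
ensembles, ≤ 10 epochs per model.  The QC corruption suite injects one
water–fat-swap or blur slab (60–120 mm, σ = 6–12 mm) into each of 20
phantoms.

## Known limitations

- The phantom is geometric; Dice and landmark numbers on it say nothing
  quantitative about clinical images.
- At 5 mm desk-scale pixels the distal subcutaneous rim is 1–2 voxels; its
  segmentation is the accuracy bottleneck and dominates the residual SCT
  Dice deficit.
- Per-slice position regression is intrinsically ambiguous on smooth
  phantom cross-sections; the fusion weights exist precisely to absorb
  this.
- The entropy→Dice regression is fitted on whatever cohort it is given; a
  fit on clean validation scans alone has little entropy spread and a weak
  slope.  QC models intended for artifact screening should be fitted on
  data that includes degraded examples.
- Two pooling stages limit the U-Net's receptive field to roughly 40
  voxels; at full 1 mm resolution the same architecture would need more
  scales.
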