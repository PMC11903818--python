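# Methods

## The problem

Amyloid-beta (Aβ) plaques occupy roughly 1–3 % of an affected cortical
section. Quantum-cascade-laser infrared (QCL-IR) microscopy records a
mid-infrared absorbance spectrum per 4.25 µm pixel (427 samples on the
inclusive 1800→948 cm⁻¹ grid at 2 cm⁻¹), label-free. The spectral
difference between plaque and surrounding tissue is subtle and pixel-exact
manual annotation is infeasible, so supervision is *weak*: each 64 × 64
region of interest (ROI) carries only a binary label derived from anti-Aβ
immunohistochemistry (IHC) on the same, co-registered section. The package
trains a segmenter from those labels, applies it to whole slides, scores
the result against IHC, and converts segmented plaques into cuttable
shapes for laser microdissection (LMD).

## Phantom model

Real tissue is not distributable, so all tests run on synthetic scenes.
Each tissue endmember is a sum of Gaussian bands in wavenumber
(center/σ/amplitude in absorbance units):

| band | background | plaque deviation |
|---|---|---|
| Amide I 1655 | 28 / 1.00 | — |
| β-sheet shoulder 1630 | — | 15 / +0.30 |
| Amide II 1545 | 25 / 0.55 | — |
| lipid ester 1740 | 18 / 0.10 | 18 / −0.40 |
| C–H deformation 1455 | 20 / 0.15 | 20 / +0.60 |
| fingerprint 1240 | 30 / 0.12 | 30 / +0.65 |

Per pixel,

```
cube = background + density · contrast_scale · jitter · (plaque − background)
       + baseline + noise
```

with `contrast_scale = 0.15` (the differences should be subtle but
learnable), per-plaque amplitude jitter ±50 % (plaque spectra vary
strongly between deposits), i.i.d. Gaussian voxel noise (σ = 0.01
absorbance), and a per-pixel linear baseline (offset 0.05, slope
σ = 10⁻⁵ cm, truncated at 3σ so absorbance stays non-negative without
noise). Setting `contrast_scale = 0` makes plaque and background pixels
identically distributed — a property test. Plaque morphologies cycle
through classic cored (density-1 core with a 0.5 corona), compact (0.85
disk with soft rim) and diffuse (ragged 0.45 blob kept singly connected);
plaques are placed without overlap, so ground-truth components are exact.
Optional artifacts emulate tissue folds (thin curved lines, absorbance
× 1.8) and holes (bare-slide absorbance); they never intersect plaques,
and they render near-white in the pseudo-IHC (they are unstained).

The pseudo-IHC rendering drives the mask pipeline: the blue channel is
`background_blue − density · (background_blue − dab_blue_min)` (defaults
0.95 and 0.10), DAB brown keeps red > green > blue, and a Poisson sprinkle
of pale violet counterstain dots (radius 1–2 px, 400 /mm²) emulates cresyl
violet. The counterstain is deliberately pale (blue ≈ 0.8): in brightfield
the nuclear counterstain is far lighter than DAB, and the mask pipeline
relies on that separation.

What the phantom does **not** model: Mie/dispersion scattering artifacts,
detector-array tiling, water-vapor lines, spatial correlation of noise,
partial-volume spectra at plaque rims, and the full morphological variety
of human plaques. A model passing the phantom suite is therefore validated
for the *pipeline logic*, not for clinical performance on tissue.

## IHC mask preprocessing

Per ROI (or slide): take the blue channel, window [0.3, 0.9] → [0, 1] with
clipping, invert (DAB is dark in blue), binarize with Otsu's method on a
256-bin histogram, fill holes, remove components under 30 px (542 µm² at
4.25 µm), smooth by a morphological opening (disk radius 1 — the smallest
element that qualifies as smoothing; configurable), and dilate with a 3×3
kernel for 4 iterations so pixels surrounding Aβ structures join the mask.
Weak labels: stained fraction ≥ 5 % → positive; exactly 0 → negative with
an all-ones effective mask (avoiding a zero pooling denominator); the
ambiguous band (0, 5 %) is excluded from training but still scored at
inference. Otsu is computed per ROI by default (per slide for whole-slide
evaluation masks). A caveat discovered in testing: the chain
fill → area-filter → opening is only idempotent when components survive
the opening — the opening can shrink a kept component below 30 px, which
only the next application would remove.

In the phantom cohort the ROI sampler stands in for the neuropathologist's
manual curation: amyloid windows are centred on ground-truth components
and get mask *and* label from the IHC pipeline (dropping borderline
windows); amyloid-free windows are sampled from plaque-free area and are
labeled negative directly with the all-ones fallback. Labeling the
negatives through the mask pipeline instead would occasionally mislabel
them — clustered counterstain dots can exceed the 30 px/5 % thresholds —
which is precisely the error the manual curation step prevents.

## Network and loss

The segmenter is a depth-reduced U-Net over NHWC numpy arrays with a
self-contained reverse-mode autodiff engine (im2col convolutions as
matmuls, 2×2 max pooling, 2×2 stride-2 transposed convolutions, skip
connections, sigmoid head). Width doubles per level from `base_width`
(default 64: bottleneck 8 × 8 × 512 for 64 × 64 input; the reduced test
configuration uses width 8 → bottleneck 64). Activations are leaky ReLU
(slope 0.1). A fixed per-channel affine standardization, calibrated on
the training split and stored in the checkpoint, forms the input layer;
without it the strongly correlated absorbance channels (Amide I mean ≈ 1,
tail channels ≈ 0.05) condition the problem so badly that nothing is
learned within the epoch budget.

The activation map `a ∈ [0,1]^{64×64}` is pooled under the ROI's binary
mask `m` into the pooling neuron `q = Σ(a·m)/Σ(m)`, and a trapezoidal
transfer function

```
T(q) = clip((q − α)/ramp, 0, 1) − clip((q − (α+β))/ramp, 0, 1)
```

with α = 0.05, α + β = 0.8, ramp = 0.1, maps q to a class score: zero
below α, one on the plateau [α + ramp, α + β], decaying to zero above —
the upper bound prevents the degenerate solution of activating the entire
mask. The loss is

```
L = Σᵢ w_yᵢ · BCE(T(qᵢ), yᵢ) / Σᵢ w_yᵢ  (class term, weighted mean)
  + hinge on q for positive ROIs          (recovery term)
  + λ · mean over background pixels of penalty(a)   (background term)
```

with class weights `w_y = N/(2·N_y)` (unity for balanced data) and λ = 1.
Background pixels are the mask complement of positive ROIs plus every
pixel of negative ROIs.

Two stabilizers depart from the plain cross-entropy forms; both were
adopted after the plain forms demonstrably failed to train in the
small-step regime (they collapse within a few epochs into states where
every gradient path is flat):

- the **background penalty** is the margin `relu(a − 0.05)` rather than
  `−log(1 − a)`: it stops pushing once background activation reaches the
  floor, so background pixels are never driven into the saturated sigmoid
  tail where all gradients vanish (the floor sits at α, small enough not
  to disturb pooled negatives);
- the **recovery hinge** `relu((α + ramp) − q) + relu(q − (α+β))` for
  positive ROIs covers the transfer function's flat dead zones: if q
  falls below α (or overshoots past the upper ramp), T carries no
  gradient, and without the hinge a positive ROI that once leaves the
  ramp region can never return. A pure-margin class loss (`class_loss=
  "hinge"`) is available and performs equivalently.

Optimization is RMSprop (ρ = 0.9, ε = 10⁻⁸) with global gradient-norm
clipping at 1.0 — the clamped logs can emit gradient spikes of order
1/ε — at the published schedule: lr 5·10⁻⁴ decaying ×0.9 every 50 epochs,
batch 20, seeded shuffling, on-the-fly dihedral augmentation (uniform over
the 8 ops), early stopping on validation loss, a checkpoint and validation
metrics every epoch. The reduced study adds a two-epoch linear warm-up
(RMSprop's empty squared-gradient cache makes the first steps ~3× larger
than nominal, enough to kill a small network); with `warmup_epochs = 0`
(the default) the schedule is exactly the published one, including the
values 5·10⁻⁴ / 4.5·10⁻⁴ / 4.05·10⁻⁴ at epochs 0/50/100.

## Selection, whole-slide inference, evaluation

A ROI is classified positive iff α ≤ q ≤ α + β (endpoints inclusive); q
itself serves as the ROC score (the simplest monotone surrogate — AUC for
an interval classifier is otherwise ill-defined). The epoch with the
highest validation specificity is selected, ties broken by F1 and then by
earlier epoch. Whole slides are processed with a 64-px sliding window at
16-px overlap (stride 48), the last tile per axis clamped to the image
edge (no padded spectra ever reach the model), and overlaps resolved by
maximum — associative and commutative, so tile order is irrelevant.
Pixel-level evaluation against the binary IHC mask yields precision
PPV = TP/(TP+FP), prevalence PR = (TP+FN)/total and the purification
factor PF = PPV/PR. Per-sample PF values are averaged separately from the
pooled-confusion PF; the two generally differ. The evaluation
binarization threshold defaults to 0.5 (unspecified upstream; 0.9 is the
documented LMD threshold, kept distinct).

## LMD export

Activation maps are thresholded at 0.9 and passed through, in order:
remove components < 100 µm²; dilate by 15 µm; fill holes; erode by 10 µm
(net +5 µm margin compensating tissue loss during cutting); remove
components < 300 µm² or failing the shape filters. The printed exclusion
rule "eccentricity < 0.97 or solidity > 0.7" would discard round, solid —
plaque-like — objects; the default therefore excludes eccentricity > 0.97
*or* solidity < 0.7 (removing elongated folds and stringy debris), and
`literal_printed_rule=True` restores the verbatim behaviour. Micrometer
radii convert to pixel structuring elements by nearest-integer rounding
(disk elements). Component outlines are traced along pixel boundaries
(polygon area = pixel count · pixel_size², exactly), shape descriptors
are attached, and vertices are mapped to stage coordinates by a
four-parameter Helmert similarity fitted by closed-form least squares on
reference-point pairs (exact on true similarities; degenerate, coincident
sources rejected). A note on the second area cut: any disk passing the
first (≥ 100 µm², equivalent radius ≥ 5.64 µm) exceeds 300 µm² after the
+5 µm margin, so under the printed order that cut only removes non-convex
or borderline shapes, not disks.

## Reduced study configuration

The acceptance study runs 8 cases of 256 × 256 px at 16 spectral channels
(the full-range grid compressed to 16 points), 20 plaques per case, one
fold and one hole artifact, ~150 positive + ~150 negative ROIs, 4/2/2
case split, base width 8, ≤ 40 epochs with two warm-up epochs and
early stopping at patience 10 — sized so the whole study runs in a few
minutes on one CPU while leaving the published optimizer settings (lr,
decay, batch size) untouched. With seed 1 the selected model reaches
held-out ROI AUC 1.0, specificity 1.0, and touches every ground-truth
plaque component on held-out slides (hit = ≥ 10 % of component pixels
predicted at threshold 0.5).

## Known limitations

- The numpy U-Net is single-threaded and far slower than a GPU framework;
  the full-width 427-channel configuration builds and runs forward passes
  but is not practical to train here.
- The phantom's spectral simplicity means headline phantom metrics
  (AUC ≈ 1) say nothing about tissue-level performance; on real data the
  plaque/background separation is much harder.
- Max-merge stitching propagates each tile's most optimistic prediction;
  blending schemes are out of scope.
- The Otsu per-ROI/per-slide choice and the evaluation threshold are
  configurable because the upstream method description leaves them open.
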