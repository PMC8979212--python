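# Methods

`gtvcascade` implements a coarse-to-fine cascaded 3D convolutional pipeline
for delineating the gross tumor volume (GTV) of nasopharyngeal carcinoma in
head-and-neck planning CT, together with the preprocessing, training recipe,
evaluation metrics and a synthetic phantom generator that stands in for
clinical cohorts at desk scale.  This note records the model, the
parameters that matter, the numerical choices, and what the phantom-based
experiments do and do not demonstrate.

## Pipeline model

**Preprocessing.**  Planning CT covers head, neck and chest, but the tumor
sits in the head; preprocessing shrinks the grid before any network sees it.

1. *Body mask*: voxels above −300 HU, after erasing treatment-bed rails.
   Rails are found as straight lines (probabilistic Hough transform on
   axial slices, keeping lines longer than 40% of the field of view that
   lie outside the largest connected component), then a morphological
   closing with a 3-voxel ball, largest-component selection and hole
   filling.  The volume is edge-padded before closing so the morphology is
   neutral at grid borders.  The HU threshold and morphology radius are
   package choices; only the method family (Hough + threshold +
   morphology) is prescribed.
2. *Neck localization*: the per-slice body area along the cranio-caudal
   axis is smoothed with a 5-slice moving average; the neck is the interior
   minimum of this profile, searched strictly between the shoulder-driven
   area maximum and the head apex (the top 10% of occupied slices is
   excluded, where the profile necessarily collapses toward zero).  A
   profile without an interior minimum (e.g. a constant cylinder) is an
   error, not a guess.
3. *Crop*: slices from the neck to the apex are kept and the in-plane
   extent is tightened to the body bounding box.  Crop offsets, the cropped
   shape and the original grid are recorded so predictions can be restored.
4. *Resampling* to 0.952 × 0.952 × 3 mm: third-order spline for
   intensities, nearest-neighbour for masks.  Cropping precedes resampling
   (the order is a package choice and is recorded in the provenance).
5. *Normalization*: one global (mean, std) pair per channel, pooled over
   the body voxels of the whole training cohort, frozen at training time
   and reused verbatim at inference.  Per-case statistics are deliberately
   not used.

**Networks.**  Both stages are 3D Res-UNets with multiscale
dilated-convolution blocks on the skip connections.  With `levels`
resolution levels (default 5) the encoder has one Conv-block + Res-block
per level (the Conv-block is stride-2 past the first level) plus a
bottleneck Res-block; the decoder mirrors it with transposed-convolution
upsampling, skip concatenation and a Conv-block + Res-block per level; the
deepest decoder level merges without upsampling.  Every skip carries one
ASPP-family block.  This layout gives `2*levels+1` Res-blocks and `levels`
ASPP blocks — 11 and 5 at the default depth, which is the published block
inventory; the per-level layout itself (how the 11 and 5 distribute) is a
package design choice since only the totals are prescribed.  Feature widths
follow `min(32 * 2^level, cap)` with caps 512 (stage 1) and 1024 (stage 2).
At 5 levels and base 32 the maximum width is 512, so the stage-2 cap never
binds; it is implemented as specified and documented as non-binding at the
defaults.

Internals chosen by this package where the source architecture is silent:

- Res-blocks use pre-activation ordering (norm → leaky ReLU → conv, twice)
  with an identity shortcut; channel changes are handled by the preceding
  Conv-blocks so no projection shortcut is needed.
- Instance normalization everywhere (training runs at batch size 1), leaky
  ReLU slope 0.01.
- Stage-1 ASPP: parallel 1×1×1 path plus 3×3×3 dilated paths at rates
  (6, 12, 18), merged by a 1×1×1 convolution.  Stage-2 ASPP (the "v3+"
  variant): rates (1, 2, 4), an extra global image-pooling path, and
  dropout p = 0.3 after the merge; stage 2 also has dropout at the encoder
  end.  Dilation rates are halved per resolution level (floor 1), since a
  rate tuned for the full-resolution skip would be mostly padding at the
  deepest skip.
- Downsampling by stride-2 convolution; upsampling by kernel-2 stride-2
  transposed convolution.
- Sigmoid output; the networks return probabilities, training consumes
  pre-sigmoid scores for numerical stability.

The layers themselves (3D convolution with stride/dilation via
column-matrix GEMMs, transposed convolution, instance norm, dropout) are a
self-contained numpy implementation with hand-written backpropagation,
verified against float64 directional finite differences (relative error
~1e-7); training runs in float32.

**Cascade.**  Stage 1 tiles the preprocessed volume with 128×128×64
windows at stride 64×64×32 (the final window is clamped to each border so
every voxel is covered) and averages overlapping scores into S1 with equal
weights (a Gaussian-weighted alternative was considered and rejected as an
unprescribed complication).  The GTV centroid is the centroid of the
largest connected component of S1 ≥ 0.5 (the 0.6 threshold applies only to
the assembled map); centroids round half-up per axis.  A fixed 96×64×32 ROI
around it is scored by stage 2 into S2.  The final score is
S = ω·S1 + (1−ω)·S2 with ω = 0.5 inside the ROI and S = S1 outside —
treating the missing S2 as 0 outside the ROI would erase coarse detections
at the ROI edge.  Voxels with S ≥ 0.6 (inclusive: "lower than the
threshold" is background, so exactly 0.6 is foreground) become the mask,
which is binarized before restoration and then nearest-neighbour resized
and placed back on the original uncropped canvas.  A case with no coarse
detection yields an empty mask plus a warning flag so cohort evaluation
completes.

**Training.**  SGD with momentum 0.99, batch size 1, gradients averaged
over 2 consecutive samples per optimizer step (averaging rather than
summing makes accumulation=2 on duplicated samples exactly equal to a
single step, which is the tested contract).  Poly schedule
`lr = 0.01 · (1 − epoch/epoch_max)^0.9`, 120 epochs at full scale.  Loss =
binary cross-entropy + (1 − soft Dice), summed 1:1, Dice smoothing
ε = 1e-5 in numerator and denominator.  Kaiming-normal initialization with
the leaky-ReLU gain.  Augmentation (each transform gated independently at
p = 0.5, order scale → elastic → rotate → flip → noise): scaling 0.7–1.3,
elastic deformation (amplitude 34, smoothing 10), in-plane rotation ±10°,
random flips, and Gaussian (σ ∈ [0, 0.1]) or uniform (±0.1) intensity
noise on the image only.  Spatial augmentation transforms use linear-spline
interpolation for images and nearest-neighbour for labels; the
interpolation order for augmentation is not prescribed anywhere, and
linear keeps the augmentation cost well below the network cost.  Patches
per epoch default to 2 × the number of training cases (configurable; the
iteration count per epoch is not prescribed).  Fine-tuning resumes from a
checkpoint for 60 epochs at lr_ini = 0.001 on a seeded 70/30 split.
Cross-validation uses balanced random folds; fold statistics
(normalization included) are computed from training cases only.

**Metrics.**  DSC = 2|G∩A|/(|G|+|A|), PPR = |G∩A|/|A|, SEN = |G∩A|/|G|;
PPR of an empty prediction is reported as 0 with a warning.  Surfaces are
foreground voxels with a 6-connected background or out-of-bounds
neighbour.  ASSD is the symmetric mean of directed nearest-surface
distances, HD95 the symmetric 95th percentile (linear interpolation
between order statistics — the percentile convention is not fixed by the
defining formula), both between voxel centres in physical mm; mm rather
than voxel units because the evaluation grids are anisotropic and the
reference results are reported in mm.  Distance metrics of empty
predictions are excluded from cohort means and counted separately.  Cohort
summaries report mean ± sample SD (n−1; a single case reports SD 0).

## Phantom generator

Clinical head-and-neck cohorts are access-restricted, so the package ships
a seeded phantom generator that emulates exactly the features the pipeline
relies on: air at −1000 HU; a body at 0 HU built from a shoulder slab, a
waisted neck cylinder whose narrowest slice is a configured truth value,
and a head that is a sphere in mm (an ellipsoid in voxels on the
anisotropic grid); a treatment bed as two straight +800 HU rails posterior
to the body; an ellipsoidal tumor inside the head with per-case uniform
size draws (stage-like spread) and a logistic intensity ramp across its
boundary (width 0.08 in normalized ellipsoid radius) that makes the
boundary soft while keeping the ground truth exactly the ellipsoid
interior; Gaussian noise at σ = 20 HU.  The default tumor contrast is
+120 HU (CE channel: ×1.5), i.e. about 3.5 standard deviations of the body
intensity distribution after normalization — visible but noise-limited at
the boundary.

The default grid is the clinical 512 × 512 × 130 at 0.9 × 0.9 × 3 mm;
`PhantomSpec.desk()` is a proportionally reduced 128 × 128 × 64 grid
(head radius 38 mm, tumor semi-axes 5–18 mm) used by the tests, the
examples and the reproduction script so that the whole study runs on one
CPU.  Phantoms contain no bone, airways, nodes or CT artifacts beyond the
bed; tumor boundaries are smooth ellipsoids.  Passing phantom experiments
therefore demonstrates that the pipeline's machinery is correct and that
its assumptions (area-minimum neck, rail geometry, centred tumor) are
sufficient for recovery — not that clinical-grade accuracy is reached on
real anatomy.

## Desk-scale study conditions

The reference experiments (`gtvcascade.experiments`) fix the package's
scaled-down study:

- *Preprocessing recovery*: 20 seeded phantoms rendered at 1.1 × 1.1 ×
  2.7 mm (so resampling to the 0.952 × 0.952 × 3 mm target is a real
  operation); measures neck-localization error against the generator
  truth, bed-rail leakage into the body mask, the exactness of the output
  spacing, and the pooled normalized foreground statistics.
- *Two-stage study*: 30 training and 10 test phantoms from disjoint seed
  streams; tiny networks (3 levels, base width 8 — the block-count closed
  form then gives 7 Res-blocks and 3 ASPP blocks per stage); patches
  64×64×32 (stride 32×32×16) and 48×32×16; the full recipe otherwise
  (augmentation on, momentum 0.99, poly decay, accumulation 2); 8 epochs
  per stage with one patch per case per epoch, sized so the whole study
  fits a single-CPU session.  Evaluation runs the complete inference path
  (preprocess → S1 → centroid → ROI → S2 → assemble → threshold → restore
  to the original grid) and reports the assembled-cascade metrics, the
  stage-1-only ablation and the fraction of tumor voxels captured by the
  fine-stage crop.

Determinism: all randomness flows through explicitly seeded numpy
generators (per-case phantom seeds derive from a master seed; training,
jitter, augmentation and dropout share one per-run generator), so repeated
same-seed runs on one CPU thread are bit-identical, which the test suite
asserts on a reduced replica of the study.

## Numerical choices and degenerate inputs

- Crops are half-open `[start, start+size)`, voxel indexing 0-based;
  centroids round half-up.
- Patches extending past the grid are padded with the volume minimum
  (≈ normalized air) for images and 0 for labels; undersized volumes are
  padded before sliding-window inference and cropped back after.
- A resample to the volume's own spacing is returned as an exact copy.
- Empty body, empty ground truth, missing coarse detection, monotone area
  profiles and degenerate (zero-variance) normalization statistics are
  explicit errors with named messages, except at cohort inference where an
  empty prediction is a warning.
- The public `loss` clips probabilities at 1e-12 for the log; training
  computes the loss from logits instead and needs no clipping.

## Known limitations

- Phantom realism is deliberately minimal (see above); no metal artifacts,
  no registration errors between channels (channels are rendered
  co-registered, matching the pipeline's assumption of pre-aligned pCT and
  CE-CT).
- Whether the two CT channels enter as network channels or separate
  samples is not recoverable from the source description; this package
  represents them as a channel dimension on one network input, with the
  single-channel run as the degenerate case.
- The numpy networks are CPU-bound; full-scale (5-level, base-32) training
  on clinical grids is out of reach here by design — the full-scale
  architecture is constructed and structurally verified, but optimization
  experiments use the tiny configuration.
- DICOM reading assumes an axis-aligned series with uniform slice spacing;
  DICOM-RT structure sets are not written.
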