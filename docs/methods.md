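# Methods

`eomseg` implements a fully automated pipeline for segmenting the eight
extraocular rectus-muscle classes on coronal orbital CT and for measuring
per-muscle thickness and cross-sectional area from the predicted masks. This
note records the models, the parameters that matter, the numerical choices,
and what the synthetic testbed does and does not establish.

## Label taxonomy

Nine classes: background plus {medial rectus, lateral rectus, superior group,
inferior rectus} × {left, right}. The superior rectus and levator palpebrae
superioris are not reliably separable on CT and are treated as one "superior
group" class. Each muscle class carries a side and a measurement-axis tag
(horizontal for medial/lateral — their thickness is a horizontal diameter —
vertical for superior/inferior). The canonical index order (left before
right; medial, lateral, superior, inferior within a side) is fixed so one-hot
encodings and report rows are stable.

## Preprocessing

Coronal slices are resampled in-plane to 1×1 mm with order-3 spline
interpolation (labels nearest-neighbour), using the acquisition pixel spacing
from the DICOM/NIfTI header. Output dimensions are
`round_half_away_from_zero(dim · spacing / target)`; the rounding rule is
fixed for reproducibility. Intensities are then windowed with a soft-tissue
window of level 50 / width 250 HU — clipped to [−75, 175] HU and mapped
affinely to [0, 1]. Resampling precedes windowing so the spline operates on
calibrated HU; the reverse order would interpolate clipped values.

Training patches are 128×128 pixels, drawn at random offsets; half of each
batch intersects the orbit (operationalised as the per-slice bounding box of
non-background labels dilated by 8 px) and contains at least one muscle
pixel, half is disjoint from it. Augmentation applies rotation (±10°),
isotropic scaling (0.9–1.1), and Gaussian intensity noise with σ = 10 HU.
Noise is added in HU — the window is inverted, noise added, the window
re-applied — because physical noise precedes display windowing. Horizontal
flipping is never applied and no flip parameter exists: the network must
learn left/right muscle identity, which a flip would destroy.

## Network

A 2-D U-net: four 2×2 max-pooling stages, channel count doubling from
`base_filters` per stage, double 3×3 same-padding convolutions per block,
skip connections by concatenation, 2×2 stride-2 transposed-convolution
upsampling, and a 1×1 convolution with per-pixel softmax over 9 classes.
Inverted dropout (keep probability 0.8) acts in the two deepest encoder
blocks. Weights are truncated Glorot-normal, sd = √(2/(fan_in+fan_out)).
The minimum input size is 16 px and inputs must be divisible by 2⁴.

Every convolution is followed by **instance normalisation** before its ReLU.
This is a deliberate addition: a plain conv+ReLU stack of this depth with
Glorot initialisation attenuates activations by roughly 2.4× per stage
(measured logit rms ≈ 0.015 at initialisation), leaving the softmax
effectively uniform for any practical number of Adam steps at small learning
rates. Instance normalisation is the standard small-batch choice in medical
segmentation; unlike batch normalisation it keeps no running statistics, so
training and inference are identical and runs are reproducible.

The implementation is pure numpy with explicit backpropagation: convolutions
are lowered to BLAS matrix products via im2col, and per-layer buffers are
reused across steps so the hot path makes no large allocations. Analytic
gradients of every layer and every loss are verified against central finite
differences in the test suite.

## Losses

For probabilities `s`, one-hot truth `g`, class weights `w_c`, `N` pixels:

- **WCE**: −(1/N) Σ_c Σ_i w_c·g·log s, over all 9 classes, probabilities
  floored at 1e−12. `w_c` defaults to *square-root* inverse class frequency
  over the training set, normalised to mean 1. Background dominates ~99% of
  pixels and must be down-weighted, but with the raw inverse its normalised
  weight collapses to ~2e-3 and confident false positives on background go
  essentially unpunished — and the soft-Dice gradient on a false-positive
  region shrinks as the region grows, so such regions persist (observed as
  whole classes locked onto the bony rim). Square-root damping keeps
  background supervision effective (weight ≈ 0.05) while still up-weighting
  the rare muscle classes ~25:1.
- **Dice loss**: 1 − (2Σpg+ε)/(Σp+Σg+ε) per foreground class,
  macro-averaged. The numerator factor 2 is the standard Dice definition,
  so a perfect prediction scores 0.
- **IoU (Jaccard) loss**: 1 − Σpg/Σ(p+g−pg), pooled over foreground classes.
- **Focal-Tversky**: Σ_c (1−TI_c)^(1/γ) with
  TI_c = (Σpg+ε)/(Σpg + α·Σp(1−g) + β·Σ(1−p)g + ε); defaults α = 0.7,
  β = 0.3, γ = 4/3 with γ restricted to [1, 3]. At α = β = 0.5, γ = 1 it
  reduces to the Dice loss per class (asserted numerically).
- **Boundary loss**: Σ_Ω φ_G·s per class, where φ_G is the signed Euclidean
  distance to the ground-truth boundary (boundary pixels at 0, negative
  inside), averaged over the foreground classes present in the batch; a
  class with an empty or full mask has no level set and is skipped.
- **Compounds**: `wce+dice` and `dice+boundary`, members summed with weight
  1; the boundary term can optionally ramp linearly from 0 to 1 over
  training (off by default).

ε = 1e−6 throughout. Dice/IoU/Focal-Tversky run over foreground classes
only; WCE runs over all classes.

## Training protocol

Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e−8). Each step consumes 20 patches drawn
from 4 training volumes (5 per volume, orbit/non-orbit balanced per the
sampling rule above). An *epoch* is one pass in which every training volume
is drawn once as a member of a 4-volume step group — ⌈n/4⌉ steps per epoch.
Training runs to at most 100 epochs with early stopping on validation
macro-Dice (patience 10 epochs, min-delta 1e−4; best weights restored), and
an optional wall-clock cap analogous to bounding total training time on
shared hardware. 10-fold cross-validation partitions the cohort with
`np.array_split` (fold sizes differ by at most one; every volume validates
exactly once).

The library default learning rate is 1e−4. The **small preset**
(`small_config`: base_filters 16, wall-clock cap, WCE+Dice) uses 3e−3: the
appropriate rate was re-selected for this CPU implementation by preliminary
evaluation of convergence on training/validation phantoms — at 1e−4 the
instance-norm network needs thousands of steps to leave the near-uniform
regime, far beyond the desk-scale step budget, while 3e−3 converges stably
within ~100–200 steps.

## Inference

Full slices are reconstructed from 128×128 sliding windows (default stride
64, half-patch); edge windows are clamped to the border so every pixel is
covered. Each covering window casts one vote per pixel — its argmax class —
and the pixel takes the majority; ties are broken by the largest accumulated
softmax probability. Slices smaller than the patch are padded reflectively
and cropped after prediction. Overlap metrics are evaluated on the 1 mm
grid the network sees; size measurements are made after nearest-neighbour
restoration of the predicted labels to the native acquisition grid, because
size errors are dominated by the 1 mm resampling and the native grid is the
scale on which the clinical measurements are defined.

## Morphometry

Per muscle and coronal slice, thickness is the short side of the
minimum-area rotated rectangle enclosing the cross-section, and area is the
pixel count times the pixel area; per-muscle values are the maxima of these
profiles over all slices, with the achieving slice index reported. The
rectangle is fitted to the convex hull of the *pixel corners* (pixels as
unit squares) scaled per axis to millimetres, so an axis-aligned w×h-pixel
block measures exactly w×h and anisotropic spacing is handled exactly
without resampling. Implementation: rotating calipers over hull-edge
orientations (a side of the optimal rectangle is collinear with a hull
edge); exact area ties between orientations — common on symmetric
rasterisations — are broken toward the more elongated rectangle, whose short
side is the physically meaningful thickness. Multiple connected components
in one slice are anatomically spurious; the largest is measured and the
event logged. An empty mask is an absent-muscle signal, not an error.

Enclosing-rectangle thickness on a rasterised mask carries an irreducible
positive quantisation component: for a shape tilted by θ the rectangle
exceeds the continuous width by up to (|cos θ|+|sin θ|)·pixel, with phase
noise of roughly ±0.5 px (measured against analytic phantoms: bias +0.3 px,
sd 0.5 px). Per-draw recovery is therefore asserted within 2 pixel-widths
and cohort-mean recovery within 1 pixel; both predicted and ground-truth
masks are measured identically, so the bias largely cancels in the
prediction-vs-truth error statistics.

## Evaluation

Per-class Dice 2|P∩G|/(|P|+|G|) and IoU |P∩G|/|P∪G| over all voxels of a
volume; a class empty in both volumes is undefined and excluded from
averages (the count is reported). Cohort statistics are unweighted
mean ± sd across studies. The muscle-bearing slab is split into three
near-equal contiguous thirds — insertion, central part, origin (anterior to
posterior); a remainder of 1 goes to the central part, a remainder of 2 to
central then origin. Measurement agreement uses MAE = (1/n)Σ|x_pr−x_gt| and
MAPE = (1/n)Σ|x_pr−x_gt|/|x_gt| (percent), pooling (study, class) pairs;
zero ground-truth values are excluded from MAPE with a warning.
Noise robustness repeats the full evaluation with Gaussian HU noise
(σ ∈ {0, 5, 10}) added to the native volumes before preprocessing.
Condition comparisons (regions, noise levels) use Welch's unequal-variance
t-test on per-study pooled Dice; the choice of test is a convention of this
package, documented rather than asserted as equivalent to any external
analysis.

## Synthetic phantom testbed

No public dataset of annotated orbital CT exists, so the package ships a
parametric phantom. Each phantom is a coronal stack (default 20 slices at
3 mm) with two orbits: a high-attenuation bony rim (700 HU annulus), a
fat-filled cavity (−80 HU), a globe (35 HU) in the anterior third of the
muscle-bearing slab, surrounding soft tissue (30 HU), and four muscle
cross-sections per orbit (90 HU) modelled as rotated ellipses. Muscles
occupy the central 80% of slices and taper with a fixed profile (plateau of
1.0 over the central third, cosine fall-off to 0.35 at insertion/origin
ends). Medial/lateral recti are drawn long-axis-vertical (thickness =
horizontal diameter), superior/inferior long-axis-horizontal, each with ±15°
orientation jitter; the left orbit's muscles occupy the left image half.
Gaussian intensity noise (default σ = 5 HU) emulates scanner noise.

Belly sizes are calibrated to published population means for
contrast-enhanced orbital CT (thickness ≈ 4.7–5.9 mm, area ≈ 38–50 mm²);
the long axis derives from the ellipse model l = 4A/(πt). Cohorts draw
per-study thickness and area from normal distributions with the published
sds, re-deriving the long axis, and draw anisotropic in-plane spacing
uniformly from 0.30–0.40 mm (the native pixel-size range of the emulated
acquisitions). The generator returns the analytic sizes as a ground-truth
oracle, and all randomness is seed-derived (identical seed ⇒ bit-identical
volumes).

What the phantom does **not** emulate: CT physics (beam hardening,
sinogram-domain noise, partial-volume blur beyond resampling), inter-slice
muscle curvature (paths are straight with tapering only), pathology beyond
size scaling, optic nerve and other intraorbital structures, and
inter-patient anatomical variation beyond size/orientation jitter. Passing
the phantom testbed therefore demonstrates that the pipeline is correctly
assembled and can recover known geometry through training, inference and
measurement; it does not establish clinical performance.

## Desk-scale problem sizes

The shipped experiment configuration trains on 24 phantoms with 4 held out
for early-stopping validation, tests on 8 phantoms, uses base_filters 16
(the original U-net's 64 is configurable), and caps training wall-clock at 750 s in the small preset; inference uses stride 64. These sizes are the
package's default study conditions for the synthetic testbed and are chosen
so a complete train–predict–measure–evaluate cycle runs on a single CPU in
roughly a quarter of an hour.

## Known limitations

- The numpy backend is single-node, CPU-only; throughput, not correctness,
  limits scale.
- No post-processing (erosion/dilation/largest-component filtering) is
  applied to predictions; measurement reduces multi-component slices to the
  largest component but the label volumes themselves are raw votes.
- Thickness from enclosing rectangles is positively biased by up to one
  pixel diagonal on rasterised masks (see Morphometry).
- The boundary loss skips classes absent from a batch; a training run whose
  patches never contain some class receives no boundary gradient for it.
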