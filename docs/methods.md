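# Methods

## Coordinate contract

Array axis 0 is x (left–right), axis 1 is y (anterior–posterior, +y
anterior), axis 2 is z (superior–inferior, +z superior; the slice-stacking
direction). Voxel indices are 0-based and continuous; `world = origin +
index ⊙ spacing` with all world quantities in millimetres, so every radial
error is spacing-aware by construction. Volumes are reoriented to the
canonical axis order on load using only the NIfTI affine. The mapping of
x/y/z to anatomical directions is this package's convention, documented
rather than inherited: common usage labels planes (axial/sagittal/coronal)
rather than axes, and we bind axial slices to fixed z, sagittal to fixed x,
coronal to fixed y.

## Landmark catalogs

The CBCT catalog is the 14-marker osteodental set (8 skeletal midline
points: N, S, ANS, A, B, Pog, Me, Gn; 6 dental: UI, LI, U6L/R, L6L/R). The
SCT catalog has 41 entries — 21 midline singular landmarks and 10 bilateral
L/R pairs — partitioned into 26 bony, 6 dental and 9 soft-tissue points.
The counts and the partition are authoritative; the individual names beyond
those fixed by the CBCT set and the printed examples (PNS, Fz, Go, Pogs,
Mes) are completed from standard craniometric nomenclature and flagged as
reconstructed in the catalog docstring. Region assignments (upper / middle /
lower facial third) follow conventional anatomy and matter only for grouped
reporting.

## Synthetic skull phantom

The generator emulates the aspects of head CT that the detection pipeline
actually exercises, at desk scale:

* **Geometry** — a cranial ellipsoid shell with soft-tissue interior and an
  inflated soft envelope, a sella sphere at the ellipsoid center, a
  frontonasal boss marking N (real nasion is a suture junction, not a bare
  surface pole — without a marked feature the landmark is ill-posed at
  coarse resolution), maxillary and mandibular arch tubes carrying
  cylindrical tooth pegs, an anterior nasal spike (ANS) and a chin boss
  (Pog/Gn/Me/B). The lower arch radius is a configurable fraction of the
  upper (overjet); the tiny preset uses 0.85 plus a widened occlusal gap so
  upper and lower teeth remain separable at 0.5 mm voxels.
* **Ground truth** — landmark positions are computed on the continuous
  analytic geometry before voxelization, so truth is sub-voxel precise and
  the voxelization error (≈ half a voxel) bounds the best achievable MRE.
* **Intensities** — air −1000 HU, soft tissue 40 HU, bone 1200 HU, teeth
  1800 HU, metal 3000 HU; the soft and bone values sit inside the clinical
  segmentation windows (−700…225 and 226…2619 HU). Seeded Gaussian noise
  (default SD 20 HU) is added on a field independent of geometry, so
  corruptions re-render the scene without disturbing untouched voxels.
* **Per-case variation** — radii, centers and arch parameters are jittered
  (±6 % relative, seeded) so a trained model cannot rely purely on absolute
  position.
* **Corruptions** — malocclusion (M) rigidly translates the mandible
  component and exactly its landmarks; missing dental landmarks (MDL)
  removes tooth pegs and flags their truth absent; metal artifacts (MA)
  place a 3000 HU blob at a landmark with alternating bright/dark axial
  streak rays. Scenario labels record parameters exactly as applied.

What the phantom does **not** model: real anatomical shape variation,
beam-hardening physics, partial-volume blur at tissue interfaces, scanner
noise spectra, or age-dependent morphology. Passing the recovery exercise
therefore demonstrates that the pipeline's machinery — encoding, network,
fusion, presence logic, metrics — is correct and trainable, not that the
trained weights transfer to clinical CT.

## Heatmap codec

Targets are amplitude-1 (peak-normalized) Gaussians; σ is specified in grid
units. Peak normalization keeps the presence threshold interpretable on
[0, 1]. Decoding refines the arg-max with a separable three-point quadratic
fit, applied in log-space where the neighbourhood is positive (exact for a
noiseless Gaussian); plain arg-max is available for strict behaviour, and
ties break to the lowest lexicographic index. Absent landmarks are encoded
as identically-zero maps ("no landmark" supervision).

σ defaults: 20 grid units at full resolution; 5 for the 96-voxel phantom
preset; the tiny protocol uses 3 for the coarse stage and 2 for the 2D
branches — the sharper 2D targets keep adjacent teeth separable at phantom
scale.

## Network

The coarse stage is a U-Net (default depth 4, base 16 channels; tiny preset
depth 3, base 8) whose 3×3×3 convolutions are replaced by PA-P3D blocks:
a factorized kernel pair with instance normalization and ReLU after each
kernel, gated by planewise attention (per-axis mean descriptors → 1×1
bottleneck → sigmoid → broadcast → averaged multiplicative mask; the gate
design is this package's reconstruction and can be disabled). Two numerical
design points deserve record:

* **Factorization order and channel placement.** The pair runs the cheap
  through-plane 1×1×n kernel first at mid = min(c_in, c_out) channels and
  lets the in-plane n×n×1 kernel carry the channel change. The pair then
  costs `n·ci·mid + n²·mid·co` weights, strictly below the dense `n³·ci·co`
  for every stage (including the 1-channel stem, where in-plane-first
  expansion would exceed the dense count), and reduces to the n²+n identity
  at 1→1. The serial in-plane-first order is available behind a flag.
* **Head rank.** The output head is a linear 1×1(×1) convolution, so the L
  per-landmark maps live in the span of its input channels. The final
  decoder stage is therefore widened to at least L channels; with base 8 and
  L = 14 the unwidened head provably cannot represent all landmarks, and in
  practice the hardest channel (sella) never trains.

Each SS-P3D branch is an independent 2D encoder–decoder (two 3×3
conv-norm-relu layers per stage, no attention) mapping a 1-channel slice to
L same-size maps; the three branches are architecturally identical with
independently seeded weights.

Normalization is instance-style (per channel over space, batch-free) with
eps 1e-4 — near-constant slices (mostly air) otherwise amplify to overflow
in float32.

## Training

The standard recipe is SGD with momentum 0.9, lr 1e-3, weight decay 5e-4,
lr ×0.1 every 50 epochs, and early stopping armed from epoch 60 with
patience 20, hard stop at 150. The stopping phrase "end after 60 epochs if
the validation loss did not decrease for 20 epochs" is formalized as: stop
at the first epoch e ≥ 60 with e − best_epoch ≥ 20 (so best at 45 → stop at
65; monotone improvement → 150). Splits are 7:1:2 with rounded
validation/test sizes and the remainder to train. Gradients are clipped to
global norm 10 (guards the rare exploding step on degenerate slices);
training aborts with a diagnostic on non-finite loss.

Loss is MSE on the heatmaps (L1 available). Three supervision-balance
devices are used by the phantom protocol, all addressing the same imbalance
— absent teeth are a few percent of instances, and plain MSE leaves the
position-prior hallucination in place:

* coarse-stage channels of absent landmarks are upweighted (×8);
* the training cohort's MDL cases remove two teeth each, rotating through
  the dental catalog so every tooth appears absent at least once in
  training (validation/test removals stay randomly drawn);
* 2D branches train on window crops (24 px) centered on the landmark's
  jittered position (±2 voxels in all axes, a surrogate for coarse-stage
  error), with three kinds of crops: full-amplitude Gaussian targets at the
  (present) landmark, zero-target crops through the *nominal* site of an
  absent tooth (×6 replicas — the only view that shows the empty socket),
  and "decoy" crops centered on a *different* tooth with the geometrically
  correct target for the supervised channel (Gaussian at its own landmark
  if visible, zero otherwise).  Decoys teach a channel to fire only on its
  own landmark when the inference-time crop lands on a neighbour; the small
  window also hides the contralateral twin of bilateral landmarks, which a
  translation-equivariant network cannot otherwise tell apart.

## Inference

Coarse peaks are decoded with sub-voxel refinement and mapped to world mm.
For each landmark the three orthogonal native-resolution slices through the
coarse estimate are cropped to a window (default: the branch's input size)
shifted inside the volume at boundaries; each branch's decoded peak is a
plane candidate fixing two coordinates (axial x,y; sagittal y,z; coronal
x,z). A slab option evaluates a small stack of slices around the coarse
index and keeps the best-peak candidate per plane, compensating
slice-selection error. Fusion averages per coordinate over the planes that
observe it, dropping candidates whose peak is below τ, and falls back to
the coarse estimate for unobserved coordinates, keeping the pipeline total.
Presence is max(coarse peak, plane peaks) ≥ τ; raising τ never converts
absent to present. A gating option restricts refinement to landmarks whose
coarse peak reaches τ (refinement then cannot resurrect a rejected
landmark); it is off by default.

τ defaults to 0.35 and, in the recovery protocol, is calibrated on the
development (training + validation) phantoms by scanning (0, 1) and taking
the median of the interval maximizing dental presence-classification
accuracy; calibration falls back to the default when the development set
has no absent instance. The threshold is a single scalar, so fitting it on
development cases carries little overfitting risk, and including the
training cases keeps the handful of absent instances from dominating.

## Metrics

Exclusion rule: landmarks absent in the reference never enter MRE/SDR; they
appear only in the presence confusion. SDR uses strict inequality (e < t).
MRE's 95 % CI is the normal approximation mean ± 1.96·SD/√n, matching
symmetric printed intervals; a bootstrap would be preferable for strongly
skewed errors and is noted as a limitation. DL-ACC/DL-PRE are formalized as
presence-classification accuracy and precision over dental instances, with
an optional stricter variant requiring positional correctness for a TP.
ICC(3,1) is the consistency form from the two-way ANOVA decomposition;
WOVI is the per-case 95th-percentile symmetric Hausdorff distance between
two annotation sessions, aggregated as mean with CI. The sample-size
operation iterates n upward, evaluating exact noncentral-t power for the
two-sided one-sample test, and returns the smallest n reaching the target
(68 at δ = 0.4 mm, SD = 1 mm, α = 0.05, power 0.90). Rank tests
(Mann–Whitney, Kruskal–Wallis) are delegated to scipy where needed rather
than reimplemented.

## The scaled recovery exercise

`cephalo3d.experiments.run_recovery` generates 32 tiny phantoms
(48×48×40 at 0.5 mm; scenarios Normal/M/MDL/MA round-robin): 12 train, 4
validation (one per scenario), 16 test. Training MDL removals are
stratified over the dental catalog; validation and test removals are pure
seeded draws. It trains the tiny preset (base 8, depth 3; ~66 k parameters
vs ~197 k for the dense-conv twin) for 60 coarse epochs (lr 1.0, ×0.1 at
40) and 30 branch epochs (lr 0.03, ×0.1 at 24) on 24-px window crops,
calibrates τ on the development cases, then predicts the 16 held-out
phantoms with the full coarse-to-fine pipeline and reports MRE, SDR@2 mm
and MDL-stratum DL-ACC. Problem sizes were chosen so the whole exercise
runs in roughly a quarter of an hour on one CPU core with the numpy
engine; the learning rates differ from the clinical-scale recipe because
the loss scale of peak-normalized heatmaps on 10⁵-voxel grids is far
smaller than at clinical resolution. The exercise is stochastic but
seed-pinned end to end (cohort, initialization, batch order, crop jitter).

## Known limitations

* The numpy engine processes one sample per step; there is no batching or
  acceleration, which bounds feasible problem sizes.
* The phantom's presence task is intentionally hard at 0.5 mm (tooth
  crowns a few voxels across); presence separation relies on the pipeline
  peaks and the calibrated τ, and residual confusions between adjacent
  teeth (an empty socket next to a present neighbour) are the dominant
  presence-error source, with a modest margin to the accuracy bound.
* The exact planewise-attention design, the full 41-name SCT roster, and
  the DL-ACC/DL-PRE and WOVI formulas are reconstructions, as documented
  above and in the respective docstrings.
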