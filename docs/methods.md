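# Methods

This note documents the models, conventions and defaults behind `segcurate`,
the choices made where the design was genuinely open, and what the phantom
experiments can and cannot show about clinical data.

## Grid convention and I/O

All grids use a fixed axis order: axis 0 is the sagittal left→right axis
("lateral" motion is along axis 0, signed away from the grid's mid-sagittal
plane), axis 1 anterior→posterior, axis 2 inferior→superior. Volumes and
masks travel as NIfTI; images are reoriented to the closest canonical axis
order on load, and spacings (mm) round-trip losslessly. Masks are stored as
unsigned 8-bit and thresholded at > 0 on load so files from foreign writers
are tolerated. DICOM-RT is deliberately out of scope: corruption/curation
experiments need reproducible synthetic cohorts, not clinical provenance.

## Phantom cohorts

A phantom case is one organ in a CT-like volume (default 48³ voxels at 1 mm
isotropic):

- **shape** — a deformed ellipsoid: mean radius 6.0 mm (±0.5 mm per case),
  per-axis eccentricities drawn from [0.9, 1.1], plus a low-frequency radial
  perturbation (degree-≤2 harmonic basis, amplitude 1 mm). This captures
  organ-scale shape variability without anatomical data; no quantitative
  organ-shape statistics were available, so these defaults are acknowledged
  stand-ins chosen to give visually organ-like, single-component masks.
- **lateralisation** — the organ centre sits 3 mm off the mid-sagittal
  plane on a per-case side (p = 1/2 unless fixed); a high-intensity
  bone/skin slab (700) and a low-intensity air pocket (−900) sit laterally
  adjacent, so lateral over-segmentation sweeps through non-tissue
  intensities, the clinically observed failure mode.
- **intensities** — organ 80, soft-tissue background 30, Gaussian smoothing
  1 mm, additive Gaussian noise sd 20. The organ/background contrast of 50
  at noise sd 20 makes the organ learnable but not trivial after smoothing.
- **margins** — parameters must leave ≥ `margin_voxels` (default 12) of
  empty grid in all six directions around every mask so corruptions up to
  that magnitude never cross the boundary; generation fails loudly
  otherwise. Cohorts are pure functions of (parameters, master seed); each
  case draws a seed derived by stable hashing.
- **clean labels** — reference masks are exact phantom boundaries. A
  ±1-voxel observer-jitter knob exists but is off by default so the
  clean/corrupt distinction stays sharp for testing.
- **distribution shift** — external cohorts come from additive offsets to
  named parameters (e.g. radius +0.8 mm, noise −10), emulating an
  out-of-distribution population without new machinery.

Split allocation uses largest-remainder rounding with ties to the earlier
split (train first), so 180 cases at proportions 100/40/40 give exactly
100/40/40 and a single case lands in train.

## Corruption model

Directional morphology uses a line structuring element anchored at the
origin: dilation is the union of the mask shifted k·direction for k = 0..m;
erosion keeps voxels whose whole forward segment is foreground (exact
complement dual). A ball element would not be directional, and the
axis-aligned line matches the lateral / caudo-cranial character of the
errors being emulated.

- **systematic** (bias): lateral dilation, away from the midline, default
  magnitude 10 voxels (= 1.0 cm at 1 mm spacing). On anisotropic grids the
  magnitude is interpreted in voxels of the corruption axis.
- **random** (variance): operation dilate/erode with p = 1/2, direction
  uniform over the six signed axes (p = 1/6). Erosions use
  `round(0.8·m)` — 20 % smaller, 8 for m = 10 — compensating DSC's size
  sensitivity; rounding is half-away-from-zero and recorded. Whether an
  erosion should shave one face or act symmetrically was unspecified in the
  source material for this design; one-face erosion (the sampled direction)
  was chosen and is stored in each `CorruptionRecord`. An erosion that
  would empty a mask resamples its direction (≤ 6 attempts) before failing.
- **cohort corruption** selects `round(i·N)` training cases uniformly
  without replacement (no covariate stratification — none was specified)
  and never touches the rest (bit-identical pass-through).
- **calibration** finds the integer magnitude whose 100 %-corrupted median
  agreement DSC is closest to a target (ties toward smaller m), warning if
  the target is outside the achievable range. On default phantoms a target
  of 0.78 calibrates to m ≈ 5; the smaller-than-clinical organ radius means
  a smaller magnitude reaches the same relative severity.

## Metrics

Surfaces are foreground voxels with ≥ 1 of 6 face-neighbours background,
with the grid boundary counting as background; distances are Euclidean
between surface-voxel centres scaled by spacing (no sub-voxel mesh — the
convention consistent with the voxel-based corruption model). MSD is the
symmetric average of the two directed mean nearest-surface distances; HD is
the maximum (not a percentile variant). Degenerate conventions: DSC is 1
for two empty masks, 0 for empty-vs-nonempty; MSD/HD raise on empty input.
The quality rubric (scores 1–5 from shortcoming flags a–e) is encoded, and
a synthetic oracle maps corruption records onto it (lateral dilation →
bone/skin/air inclusion; low agreement adds a lobe flag) so
sensitivity/specificity against "quality < 4" stay exercisable on phantoms.

## Backends

The curation procedure only needs `init_segmenter` / `train` /
`predict_logits`; two reference implementations ship:

- **`kind="unet"`** — a numpy 3D encoder-decoder with hand-derived
  backpropagation: `depth` levels with `base_filters·2^i` filters, two
  3×3×3 Conv→ReLU→BatchNorm units per level (normalisation after the
  activation), 2³ max-pooling, nearest-neighbour upsampling with skip
  concatenation, a 1×1×1 head producing one pre-sigmoid channel, soft-Dice
  loss and Adam. Batch statistics are per-channel over the spatial grid
  (batch size one); inference uses frozen running statistics, so prediction
  is deterministic. Gradients are verified against numeric differentiation
  in the test suite. Intended for small grids/channel counts; a
  reference-scale configuration (depth 4, base 32, deepest stage 256
  filters) is constructible but not used by the experiments.
- **`kind="voxel"`** — a voxelwise logistic classifier over multiscale
  Gaussian features (raw and smoothed intensities at σ = 1, 2, 4 mm, their
  squares and gradient magnitudes). The squared features make a mid-range
  intensity band linearly representable, which is what excludes bone and
  air. Training uses per-case Adam steps on the same soft-Dice loss over
  shuffled epochs, so the "fraction of epochs" prompt semantics carry over.
  This is the default for experiment sweeps: it is orders of magnitude
  cheaper than the network and shows the same ranking behaviour, because
  corrupted references disagree with any model that has learned the organ's
  intensity signature.

Training losses are overlap-based only (soft-Dice, no distance term), so
effects observed in MSD/HD are indirect. Optimiser settings (Adam,
learning rate 0.3 for the voxel backend, ~1e-2 for the small network, no
augmentation) are package defaults, declared rather than claimed faithful
to any external training recipe. Convergence of the voxel backend scales
with optimiser steps = epochs × cases; small cohorts need proportionally
larger epoch budgets (the unit tests use 160–240 epochs on 6-case cohorts,
the 60-case experiments use the default E = 40).

## Auto-curation

1. prompt-train a fresh model for `ceil(0.25·E)` epochs;
2. rank **all** input training cases by DSC between the prompt model's
   prediction and the case's own — possibly corrupted — reference (this is
   the point of the method: no clean labels are needed);
3. remove the `floor(R·N)` lowest; ties break lexicographically by case id
   (determinism over randomness; no tie rule was prescribed);
4. re-initialise with a fresh derived seed and train the full budget on the
   kept cases. Validation/test cases are never removal candidates.

Sensitivity = |removed ∩ corrupted| / |corrupted|; specificity (in this
field's usage) = fraction of *removed* cases that truly warranted removal;
agreement = mean pairwise |A_i ∩ A_j| / k over repeated runs. The pairwise
intersection-over-k form was chosen because its expectation under uniform
random removal equals the curation rate k/N, giving the natural random
baseline anchor (verified by simulation in the tests). Ensembles take the
voxelwise mean of pre-sigmoid scores across models, thresholded at zero.

## Experiments and problem sizes

All pipelines are pure functions of (config, master seed); every sub-stream
(corruption selection, fold seeds, re-initialisation) uses a hashed derived
seed, and every run audits that no training id appears in the true/external
evaluation sets. The default corruption-impact grid is 21 fractions (0–100 %
in 5 % steps) × 2 modes = 42 configurations; the curation matrix runs the
seven clean/corrupted × removal conditions over seeded folds; rate sweeps
compare curation against random removal at rates 0–90 %, selecting the best
rate by external-set curation efficacy (ties toward the smaller rate).
Cross-validation scores every case exactly once out-of-fold and assigns DSC
quartiles Q1 (highest) … Q4 with near-equal sizes, ties by id.

Shipped experiment sizes are desk-scale by design: cohorts of tens of 48³
phantom cases, the voxel backend, E = 40. The scaled curation study used by
`scripts/acceptance.py` runs five seeded repeats of: 60 train / 20 clean
test cases, 30 % systematic corruption calibrated to agreement DSC ≈ 0.78,
prompt training, 30 % removal — reporting median sensitivity (and, in the
test suite, the curated vs non-curated clean-test comparison after full
retraining).

## Statistics

Two-sided Wilcoxon signed-rank tests with zero differences discarded (the
classical convention; Pratt's variant was not used), exact null for n ≤ 25
when |differences| are tie-free, otherwise the tie-corrected normal
approximation. Family-wise control adjusts the threshold to α/m (for
α = 0.05 and m = 27, displayed as 1.9e-3) rather than inflating p-values.
Repeated-run comparisons first reduce to per-case medians across
iterations. Star coding: \*, \*\*, \*\*\*, \*\*\*\* at p < 1e-3, 1e-6,
1e-9, 1e-12.

## What the phantom experiments do and do not show

Passing experiments demonstrate the *mechanics*: corrupted labels measurably
depress clean-test performance while same-distribution scoring masks the
damage; prompt-phase DSC ranking concentrates corrupted cases in the removed
tail (sensitivity near 1 on phantoms); curated retraining recovers clean-test
DSC directionally. They do not establish clinical effect sizes: phantom
organs are smaller and far more homogeneous than real anatomy, clean labels
are exactly clean (no inter-observer noise floor), the intensity model has
no texture/artifacts, and the desk-scale backends are far below clinical
capacity. Recovery margins on phantoms are accordingly small (the voxel
classifier is intrinsically robust to a corrupted minority), so recovery is
asserted as a directional, majority-of-seeds property, not an effect size.

## Known limitations

- The numpy network is single-volume-batch and CPU-bound; it exists as a
  verified reference implementation, not a performance tool.
- The voxel backend has no spatial prior, so it cannot reproduce
  architecture-specific noise-memorisation effects (e.g. a CNN eventually
  reproducing systematic bias is visible in grid experiments only as a
  shifted decision surface).
- Manifest round-trips keep corruption flags but not full corruption
  records; records live with in-memory cohorts and experiment outputs.
- Erosion-heavy random corruption at the default magnitudes is harsher on
  small phantom organs than on clinical-sized structures; calibrated
  magnitudes should be used when severity matters.
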