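# segcurate

Desk-scale toolkit for studying how imperfect reference segmentations hurt
trainable organ-at-risk segmenters, and for undoing part of the damage with a
simple **DSC-ranked auto-curation** step.

Clinical segmentation datasets (the motivating case: parotid glands contoured
on radiotherapy planning CTs) contain label noise with both a bias component
(systematic lateral over-segmentation that sweeps in skin/bone/air) and a
variance component (random over-/under-reach in arbitrary directions).
Training on such labels degrades performance on *clean* data, and the damage
is masked when models are validated on data drawn from the same noisy
distribution. `segcurate` packages everything needed to reproduce this
phenomenology without clinical data:

- a **phantom generator** for CT-like cohorts with exact organ masks
  (deformed, lateralised ellipsoids beside a bone slab and an air pocket),
  including shifted-parameter cohorts that play the out-of-distribution role;
- a **corruption simulator** with two operators: systematic lateral dilation
  (default 10 voxels = 1.0 cm at 1 mm spacing) and random dilation/erosion
  (operation p = 1/2, direction p = 1/6 over the six signed axes, erosions
  20 % smaller), plus calibration of the magnitude to a target agreement DSC;
- **metrics**: Dice similarity coefficient `DSC = 2|A∩B|/(|A|+|B|)`, mean
  surface distance (MSD, mm) and maximum Hausdorff distance (HD, mm) on
  voxel surfaces, and curation efficacy (curated − non-curated DSC);
- **trainable backends** behind a model-agnostic contract
  (`init_segmenter` / `train` / `predict_logits`): a numpy 3D
  encoder-decoder network (depth layers, filters doubling per depth, 3×3×3
  kernels, batch-norm after activation, soft-Dice loss) and a fast
  voxel-feature classifier for experiment sweeps;
- the **auto-curation procedure**: train for 25 % of the epoch budget,
  rank all training cases by DSC against their own (possibly corrupted)
  reference, remove the lowest `floor(R·N)`, re-initialise and retrain —
  with sensitivity/specificity/agreement scoring and mean-logit ensembling;
- **experiment pipelines**: the 42-model corruption-impact grid, the
  seven-condition curation matrix, curation-vs-random-removal rate sweeps,
  repeated random sub-sampling, repeated curation with median-model and
  ensemble comparisons, and k-fold cross-validation with DSC quartiles;
- **statistics**: two-sided Wilcoxon signed-rank tests (exact branch for
  small n), Bonferroni-adjusted thresholds (0.05/27 → 1.9e-3), per-case
  medians over repeated runs.

## Worked example

From `examples/05_auto_curation.py` — corrupt 30 % of 30 training labels
with calibrated systematic lateral dilation, curate at R = 0.30, retrain:

```
9 of 30 training labels corrupted (magnitude 5 voxels)
removed 9 cases; sensitivity=1.00 (corrupted cases caught), specificity=1.00 (removed cases truly corrupt)
clean-test median DSC: curated 0.962 vs non-curated 0.957
```

Sensitivity 1.00 means every corrupted training case ranked in the removed
tail after prompt training; the curated model recovers clean-test DSC
relative to training on the noisy set. `examples/07_corruption_impact_grid.py`
shows the masking effect: scored against clean labels, a fully
systematically corrupted training set collapses test DSC to 0.17 while the
score against the corrupted labels themselves stays high — noisy validation
data hides the damage.

The other examples cover cohort generation, corruption calibration, the
metric suite, backend training and the statistical workflow; each prints a
short interpretation of its numbers. A thin CLI mirrors the library
(`segcurate phantom | corrupt | evaluate | curate | experiment`), writing a
`resolved_config.json` beside every artifact.

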