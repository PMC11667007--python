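"""Train a segmenter on a phantom cohort and evaluate it.

The default desk-scale backend is a voxelwise classifier over multiscale
Gaussian intensity features; the numpy 3D encoder-decoder network
(kind="unet") implements the reference architecture and suits small grids.
Both emit per-voxel pre-sigmoid scores; masks are score > 0.
"""

from segcurate import (PhantomParams, SegmenterConfig, evaluate_cohort,
                       generate_cohort, init_segmenter, train)

cases, _ = generate_cohort(30, PhantomParams(), seed=13,
                           proportions=(20, 5, 5))
train_cases = [c for c in cases if c.split == "train"]
test_cases = [c for c in cases if c.split == "test_true"]

config = SegmenterConfig(kind="voxel", epochs=40)
model = init_segmenter(config, seed=0)
train(model, train_cases, epochs=config.epochs, seed=1)

report = evaluate_cohort(model, test_cases)
print("held-out test performance (median[IQR]):")
print(" ", report)
# DSC above ~0.95 on clean phantoms: the intensity signature of the organ is
# learnable, so degradations seen later come from label noise, not capacity.
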