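"""Trainable-segmenter contract and reference implementations.

The curation procedure is model-agnostic: anything exposing
``init_segmenter`` / ``train`` / ``predict_logits`` can be curated. Two
implementations ship with the package:

* ``kind="unet"`` — a 3D encoder-decoder convolutional network written in
  numpy with hand-derived backpropagation (:mod:`segcurate.backend.unet`):
  configurable depth layers, base filters doubling at each depth, 3x3x3
  kernels, batch normalisation after the non-linear activation, single
  pre-sigmoid output channel, soft-Dice loss. It realises the reference
  architecture at small scale and is exercised by overfit/gradient tests.
* ``kind="voxel"`` — a voxelwise logistic classifier over multiscale
  Gaussian intensity features (:mod:`segcurate.backend.voxel`), trained by
  per-case gradient steps on the same soft-Dice loss. It is orders of
  magnitude cheaper and is the default backend for desk-scale corruption /
  curation experiments.

Both are deterministic functions of (config, seed, training data), and both
emit a per-voxel pre-sigmoid score map; masks are score > 0 (equivalently,
sigmoid probability > 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Protocol, Sequence

import numpy as np

from ..types import Case, Mask, Volume

__all__ = [
    "SegmenterConfig", "TrainedSegmenter", "init_segmenter", "train",
    "predict_logits", "predict_mask", "filters_per_stage",
]


@dataclass(frozen=True)
class SegmenterConfig:
    """Backend configuration.

    ``depth``/``base_filters``/``kernel`` describe the network architecture
    (stage ``i`` carries ``base_filters * 2**i`` filters, ``i = 0..depth-1``);
    they are ignored by the ``voxel`` backend, which instead uses
    ``feature_sigmas_mm``. ``epochs`` is the full-training epoch budget E the
    curation prompt fraction refers to.
    """

    kind: str = "voxel"
    depth: int = 3
    base_filters: int = 8
    kernel: int = 3
    epochs: int = 40
    learning_rate: float = 0.3
    loss: str = "soft_dice"
    feature_sigmas_mm: tuple[float, ...] = (1.0, 2.0, 4.0)

    def __post_init__(self) -> None:
        if self.kind not in ("voxel", "unet"):
            raise ValueError(f"unknown backend kind {self.kind!r}")
        if self.depth < 1 or self.base_filters < 1:
            raise ValueError("depth and base_filters must be >= 1")
        if self.kernel % 2 != 1:
            raise ValueError("kernel size must be odd")
        if self.epochs < 4:
            raise ValueError("epoch budget must be >= 4 so a 25 % prompt is >= 1 epoch")
        if self.loss != "soft_dice":
            raise ValueError("only the overlap-based soft-Dice loss is supported")


def filters_per_stage(config: SegmenterConfig) -> list[int]:
    """Filters at encoder stages 0..depth-1 (doubling per depth layer)."""
    return [config.base_filters * 2**i for i in range(config.depth)]


class _Model(Protocol):
    def train_epochs(self, cases: Sequence[Case], epochs: int, seed: int) -> None: ...
    def logits(self, volume: Volume) -> np.ndarray: ...


@dataclass
class TrainedSegmenter:
    """A trained model plus its provenance."""

    model: _Model
    config: SegmenterConfig
    seed: int
    train_ids: tuple[str, ...] = ()
    epochs_trained: int = 0

    def predict_logits(self, volume: Volume) -> np.ndarray:
        z = self.model.logits(volume)
        if z.shape != volume.shape:
            raise ValueError("logit grid does not match the input grid")
        return z

    def predict_mask(self, volume: Volume) -> Mask:
        return Mask(self.predict_logits(volume) > 0.0, volume.spacing)


def init_segmenter(config: SegmenterConfig, seed: int) -> TrainedSegmenter:
    """Freshly initialised (untrained) segmenter; reproducible for a seed."""
    if config.kind == "voxel":
        from .voxel import VoxelFeatureModel
        model: _Model = VoxelFeatureModel(config, seed)
    else:
        from .unet import UNet3D
        model = UNet3D(depth=config.depth, base_filters=config.base_filters,
                       kernel=config.kernel, learning_rate=config.learning_rate,
                       seed=seed)
    return TrainedSegmenter(model=model, config=config, seed=seed)


def train(segmenter: TrainedSegmenter, cases: Sequence[Case], epochs: int,
          seed: int) -> TrainedSegmenter:
    """Train in place for ``epochs`` epochs; returns the segmenter with
    provenance updated."""
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    cases = list(cases)
    if not cases:
        raise ValueError("training split is empty")
    segmenter.model.train_epochs(cases, epochs, seed)
    segmenter.train_ids = tuple(c.case_id for c in cases)
    segmenter.epochs_trained += epochs
    return segmenter


def predict_logits(trained: TrainedSegmenter, volume: Volume) -> np.ndarray:
    return trained.predict_logits(volume)


def predict_mask(trained: TrainedSegmenter, volume: Volume) -> Mask:
    return trained.predict_mask(volume)
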