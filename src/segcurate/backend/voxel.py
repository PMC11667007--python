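"""Voxelwise logistic segmenter over multiscale Gaussian features.

A classical intensity-based voxel classifier: each voxel is described by its
raw intensity, Gaussian-smoothed intensities and Gaussian gradient
magnitudes at a few physical scales, plus the squares of the intensity
features (so a mid-range intensity band — tissue brighter than air but
darker than bone — is linearly representable), and a linear model maps the
standardised feature vector to a pre-sigmoid score. Training minimises the
soft-Dice loss with per-case Adam steps over shuffled epochs, so the
"epochs" notion (and the 25 %-of-epochs curation prompt) carries over
unchanged from the network backend.

The model deliberately has no spatial prior: it learns the organ's intensity
signature, which is exactly what makes corrupted reference masks (lateral
dilations sweeping in bone/skin/air, or erosions cutting organ tissue) score
visibly lower agreement than clean ones during the prompt phase.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy import ndimage

from ..types import Case, Volume

_ADAM_B1, _ADAM_B2, _ADAM_EPS = 0.9, 0.999, 1e-8


def _soft_dice_grad(z: np.ndarray, y: np.ndarray, eps: float = 1.0):
    """Soft-Dice loss on sigmoid(z) and its gradient wrt z (flat arrays)."""
    p = 1.0 / (1.0 + np.exp(-np.clip(z, -60.0, 60.0)))
    s1 = float((p * y).sum())
    s2 = float(p.sum() + y.sum())
    dice = (2.0 * s1 + eps) / (s2 + eps)
    # d(1-dice)/dp, then chain through the sigmoid
    dp = -(2.0 * y * (s2 + eps) - (2.0 * s1 + eps)) / (s2 + eps) ** 2
    dz = dp * p * (1.0 - p)
    return 1.0 - dice, dz


class VoxelFeatureModel:
    def __init__(self, config, seed: int) -> None:
        self.sigmas = tuple(config.feature_sigmas_mm)
        self.lr = float(config.learning_rate)
        n_feat = 2 + 3 * len(self.sigmas)
        rng = np.random.default_rng(seed)
        self.w = rng.normal(0.0, 0.01, size=n_feat)
        self.b = 0.0
        self.feat_mean: np.ndarray | None = None
        self.feat_std: np.ndarray | None = None
        self._adam_m = np.zeros(n_feat + 1)
        self._adam_v = np.zeros(n_feat + 1)
        self._adam_t = 0
        self._cache: dict[str, np.ndarray] = {}

    # ---- features --------------------------------------------------------
    def _raw_features(self, volume: Volume) -> np.ndarray:
        img = np.asarray(volume.voxels, dtype=np.float32)
        spacing = np.asarray(volume.spacing)
        feats = [img, img**2]
        for s_mm in self.sigmas:
            sigma = s_mm / spacing
            smooth = ndimage.gaussian_filter(img, sigma)
            feats += [smooth, smooth**2,
                      ndimage.gaussian_gradient_magnitude(img, sigma)]
        return np.stack([f.reshape(-1) for f in feats], axis=1)

    def _features(self, volume: Volume) -> np.ndarray:
        f = self._raw_features(volume)
        if self.feat_mean is None:
            raise RuntimeError("model has no feature statistics; train it first")
        return (f - self.feat_mean) / self.feat_std

    # ---- training --------------------------------------------------------
    def train_epochs(self, cases: Sequence[Case], epochs: int, seed: int) -> None:
        rng = np.random.default_rng(seed)
        feats, labels = [], []
        for case in cases:
            f = self._cache.get(case.case_id)
            if f is None:
                f = self._raw_features(case.volume)
                self._cache[case.case_id] = f
            feats.append(f)
            labels.append(case.mask.voxels.reshape(-1).astype(np.float32))
        if self.feat_mean is None:
            stacked_mean = np.mean([f.mean(axis=0) for f in feats], axis=0)
            stacked_sq = np.mean([(f**2).mean(axis=0) for f in feats], axis=0)
            self.feat_mean = stacked_mean
            self.feat_std = np.sqrt(np.maximum(stacked_sq - stacked_mean**2, 1e-8))
        order = np.arange(len(feats))
        for _epoch in range(epochs):
            rng.shuffle(order)
            for i in order:
                fstd = (feats[i] - self.feat_mean) / self.feat_std
                z = fstd @ self.w + self.b
                _loss, dz = _soft_dice_grad(z, labels[i])
                grad = np.concatenate([fstd.T @ dz, [dz.sum()]])
                self._adam_step(grad)

    def _adam_step(self, grad: np.ndarray) -> None:
        self._adam_t += 1
        self._adam_m = _ADAM_B1 * self._adam_m + (1 - _ADAM_B1) * grad
        self._adam_v = _ADAM_B2 * self._adam_v + (1 - _ADAM_B2) * grad**2
        mhat = self._adam_m / (1 - _ADAM_B1**self._adam_t)
        vhat = self._adam_v / (1 - _ADAM_B2**self._adam_t)
        step = self.lr * mhat / (np.sqrt(vhat) + _ADAM_EPS)
        self.w -= step[:-1]
        self.b -= float(step[-1])

    # ---- inference -------------------------------------------------------
    def logits(self, volume: Volume) -> np.ndarray:
        z = self._features(volume) @ self.w + self.b
        return z.reshape(volume.shape)
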