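"""DSC-ranked auto-curation of noisy training segmentations.

Networks initially fit the dominant, correct samples before memorising a
corrupted minority, so cases whose reference labels disagree with an
early-training model are suspect. The procedure:

1. **prompt training** — train a fresh model for a fraction of the full
   epoch budget (default 25 %);
2. **ranking** — evaluate the prompt model on *all* input training cases,
   scoring DSC against each case's own (possibly corrupted) reference label;
3. **removal** — drop the ``floor(R * N)`` lowest-DSC cases (R is the
   curation rate), ties broken by case id;
4. **retraining** — re-initialise the weights with a fresh derived seed and
   train the full budget on the kept cases only.

Validation and test cases are never candidates for removal. When ground
truth about which cases were corrupted exists, the result carries curation
sensitivity (fraction of corrupted cases removed) and specificity (fraction
of removed cases that truly warranted removal). ``curation_agreement``
quantifies the stability of the removed set across repeated runs; under
purely random removal its expectation equals the curation rate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np

from .backend import SegmenterConfig, TrainedSegmenter, init_segmenter, train
from .metrics import dsc
from .seeds import derive_seed
from .types import Case, Mask, Volume

__all__ = [
    "CurationConfig", "CurationResult", "prompt_train", "rank_training_cases",
    "curate_and_retrain", "random_removal", "curation_sensitivity",
    "curation_specificity", "curation_agreement", "ensemble_predict",
]


@dataclass(frozen=True)
class CurationConfig:
    """Curation parameters: removal rate R and prompt fraction of epochs."""

    removal_rate: float = 0.30
    prompt_fraction: float = 0.25

    def __post_init__(self) -> None:
        if not 0.0 <= self.removal_rate < 1.0:
            raise ValueError("removal rate must lie in [0, 1)")
        if not 0.0 < self.prompt_fraction < 1.0:
            raise ValueError("prompt fraction must lie in (0, 1)")


@dataclass
class CurationResult:
    removed_ids: tuple[str, ...]
    kept_ids: tuple[str, ...]
    prompt_dsc: dict[str, float]
    model: TrainedSegmenter
    sensitivity: float | None = None
    specificity: float | None = None
    seed: int = 0
    config: CurationConfig = field(default_factory=CurationConfig)


def prompt_epochs(full_epochs: int, prompt_fraction: float) -> int:
    """Epochs of the prompt phase: ``ceil(fraction * E)`` (at least one)."""
    return max(1, math.ceil(prompt_fraction * full_epochs))


def prompt_train(cases: Sequence[Case], config: SegmenterConfig,
                 prompt_fraction: float = 0.25, seed: int = 0) -> TrainedSegmenter:
    """Train a fresh model for the prompt fraction of the full epoch budget."""
    cases = list(cases)
    if not cases:
        raise ValueError("training split is empty")
    epochs = prompt_epochs(config.epochs, prompt_fraction)
    model = init_segmenter(config, derive_seed(seed, "prompt-init"))
    return train(model, cases, epochs, derive_seed(seed, "prompt-train"))


def rank_training_cases(prompt_model: TrainedSegmenter,
                        cases: Sequence[Case]) -> list[tuple[str, float]]:
    """(case_id, DSC) ascending: prompt prediction vs the case's own
    (possibly corrupted) reference label. Ties break lexicographically."""
    scored = [(case.case_id, dsc(prompt_model.predict_mask(case.volume), case.mask))
              for case in cases]
    return sorted(scored, key=lambda t: (t[1], t[0]))


def curate_and_retrain(cases: Sequence[Case], backend_config: SegmenterConfig,
                       curation_config: CurationConfig = CurationConfig(),
                       seed: int = 0,
                       corrupted_ids: set[str] | None = None) -> CurationResult:
    """Run the full curate-and-retrain pipeline on a training split."""
    cases = list(cases)
    n = len(cases)
    k = math.floor(curation_config.removal_rate * n)
    if curation_config.removal_rate > 0 and k == 0:
        warnings.warn("removal rate rounds to zero cases; curation is a no-op",
                      stacklevel=2)
    prompt = prompt_train(cases, backend_config, curation_config.prompt_fraction, seed)
    ranking = rank_training_cases(prompt, cases)
    removed = tuple(cid for cid, _ in ranking[:k])
    removed_set = set(removed)
    kept_cases = [c for c in cases if c.case_id not in removed_set]
    kept = tuple(c.case_id for c in kept_cases)

    # fresh weights, fresh derived seed: training restarts from scratch
    model = init_segmenter(backend_config, derive_seed(seed, "retrain-init"))
    model = train(model, kept_cases, backend_config.epochs,
                  derive_seed(seed, "retrain"))

    sens = spec = None
    if corrupted_ids:
        sens = curation_sensitivity(removed_set, corrupted_ids)
        if removed_set:
            spec = curation_specificity(removed_set, corrupted_ids)
    return CurationResult(removed_ids=removed, kept_ids=kept,
                          prompt_dsc=dict(ranking), model=model,
                          sensitivity=sens, specificity=spec,
                          seed=seed, config=curation_config)


def random_removal(cases: Sequence[Case], rate: float, seed: int = 0) -> list[Case]:
    """Uniform without-replacement removal of ``floor(rate * N)`` cases —
    the baseline that isolates the effect of reduced training-set size."""
    cases = list(cases)
    n = len(cases)
    k = math.floor(rate * n)
    if k >= n:
        raise ValueError("cannot remove the whole training split")
    if rate > 0 and k == 0:
        warnings.warn("removal rate rounds to zero cases", stacklevel=2)
    rng = np.random.default_rng(seed)
    drop = set(rng.choice(n, size=k, replace=False).tolist())
    return [c for i, c in enumerate(cases) if i not in drop]


def curation_sensitivity(removed_ids: set[str], corrupted_ids: set[str]) -> float:
    """Fraction of truly corrupted/poor-quality cases that were removed."""
    if not corrupted_ids:
        raise ValueError("corrupted id set is empty")
    return len(set(removed_ids) & set(corrupted_ids)) / len(corrupted_ids)


def curation_specificity(removed_ids: set[str], poor_quality_ids: set[str]) -> float:
    """Fraction of removed cases that truly warranted removal (quality < 4)."""
    removed_ids = set(removed_ids)
    if not removed_ids:
        raise ValueError("removed id set is empty")
    return len(removed_ids & set(poor_quality_ids)) / len(removed_ids)


def curation_agreement(removed_sets: Sequence[set[str]]) -> float:
    """Mean pairwise overlap ``|A_i ∩ A_j| / k`` over all unordered pairs of
    repeated curation runs removing the same count k from the same pool.

    1 means identical removal across iterations; for uniform random removal
    of k out of N the expectation is k/N (the curation rate).
    """
    sets = [set(s) for s in removed_sets]
    if len(sets) < 2:
        raise ValueError("agreement needs at least two iterations")
    k = len(sets[0])
    if any(len(s) != k for s in sets):
        raise ValueError("all iterations must remove the same number of cases")
    if k == 0:
        raise ValueError("removal sets are empty")
    overlaps = [len(a & b) / k for a, b in combinations(sets, 2)]
    return float(np.mean(overlaps))


def ensemble_predict(models: Sequence[TrainedSegmenter], volume: Volume) -> Mask:
    """Ensemble mask: voxelwise mean of pre-sigmoid scores across models,
    thresholded at zero (mean-logit sigmoid > 0.5 in the binary case)."""
    models = list(models)
    if not models:
        raise ValueError("ensemble needs at least one model")
    acc = None
    for model in models:
        z = model.predict_logits(volume)
        if acc is None:
            acc = z.astype(float).copy()
        elif z.shape != acc.shape:
            raise ValueError("ensemble members disagree on the grid shape")
        else:
            acc += z
    return Mask(acc / len(models) > 0.0, volume.spacing)
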