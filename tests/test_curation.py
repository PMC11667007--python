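"""Curation bookkeeping, ranking, removal counts, quality scores, ensembles."""

import math

import numpy as np
import pytest

from segcurate import (CurationConfig, Mask, SegmenterConfig, Volume,
                       curation_agreement, curation_sensitivity,
                       curation_specificity, curate_and_retrain,
                       ensemble_predict, random_removal, rank_training_cases)
from segcurate.curation import prompt_epochs


class _OracleModel:
    """Stand-in segmenter returning a fixed mask per volume id."""

    def __init__(self, lookup):
        self.lookup = lookup

    def predict_mask(self, volume):
        return self.lookup[id(volume)]


class _ConstantLogits:
    def __init__(self, value, shape=(4, 4, 4)):
        self.value, self.shape = value, shape

    def predict_logits(self, volume):
        return np.full(volume.shape, self.value)

    def predict_mask(self, volume):
        return Mask(self.predict_logits(volume) > 0, volume.spacing)


def test_prompt_epochs_arithmetic():
    assert prompt_epochs(40, 0.25) == 10
    assert prompt_epochs(5, 0.25) == 2     # ceil
    assert prompt_epochs(4, 0.25) == 1


def test_ranking_is_ascending_with_id_tiebreak(tiny_cohort):
    cases, _ = tiny_cohort
    sub = cases[:4]
    # oracle model that reproduces every reference exactly: all DSC = 1
    lookup = {id(c.volume): c.mask for c in sub}
    ranking = rank_training_cases(_OracleModel(lookup), sub)
    assert [cid for cid, _ in ranking] == sorted(c.case_id for c in sub)
    assert all(d == 1.0 for _, d in ranking)
    # permuting the input order leaves the ranking unchanged
    ranking2 = rank_training_cases(_OracleModel(lookup), sub[::-1])
    assert ranking2 == ranking


def test_corrupted_case_ranks_first_under_oracle(tiny_cohort):
    from segcurate import corrupt_systematic
    cases, _ = tiny_cohort
    sub = list(cases[:4])
    corrupted = corrupt_systematic(sub[2], 6)
    sub[2] = corrupted
    # model predicting the *clean* reference for every case
    lookup = {id(c.volume): c.mask for c in cases[:4]}
    ranking = rank_training_cases(_OracleModel(lookup), sub)
    assert ranking[0][0] == corrupted.case_id
    assert ranking[0][1] < 1.0


def test_removal_count_floor_and_partition(tiny_cohort):
    cases, _ = tiny_cohort
    train = [c for c in cases if c.split == "train"]  # 6 cases
    cfg = SegmenterConfig(kind="voxel", epochs=8)
    res = curate_and_retrain(train, cfg, CurationConfig(removal_rate=0.30), seed=1)
    n = len(train)
    assert len(res.removed_ids) == math.floor(0.30 * n)
    assert set(res.removed_ids) | set(res.kept_ids) == {c.case_id for c in train}
    assert not set(res.removed_ids) & set(res.kept_ids)
    # removed cases are the lowest prompt-DSC ones
    ordered = sorted(res.prompt_dsc, key=lambda c: (res.prompt_dsc[c], c))
    assert list(res.removed_ids) == ordered[:len(res.removed_ids)]


def test_zero_rate_warns_and_keeps_all(tiny_cohort):
    cases, _ = tiny_cohort
    train = [c for c in cases if c.split == "train"]
    cfg = SegmenterConfig(kind="voxel", epochs=8)
    with pytest.warns(UserWarning, match="no-op"):
        res = curate_and_retrain(train[:3], cfg, CurationConfig(removal_rate=0.2),
                                 seed=0)
    assert len(res.removed_ids) == 0
    assert len(res.kept_ids) == 3


def test_random_removal_counts_and_determinism(tiny_cohort):
    cases, _ = tiny_cohort
    pool = cases  # 10 cases
    kept = random_removal(pool, 0.30, seed=5)
    assert len(kept) == len(pool) - math.floor(0.30 * len(pool))
    assert random_removal(pool, 0.0, seed=5) == pool
    a = [c.case_id for c in random_removal(pool, 0.5, seed=9)]
    b = [c.case_id for c in random_removal(pool, 0.5, seed=9)]
    assert a == b


def test_sensitivity_specificity_formulas():
    assert curation_sensitivity({"a", "b", "c"}, {"a", "b"}) == 1.0
    assert curation_sensitivity({"x"}, {"a", "b"}) == 0.0
    # 30 corrupted, 29 of them removed
    corrupted = {f"c{i}" for i in range(30)}
    removed = {f"c{i}" for i in range(29)} | {"other"}
    assert curation_sensitivity(removed, corrupted) == pytest.approx(29 / 30)
    # 50 removed, 40 of them poor quality
    removed50 = {f"r{i}" for i in range(50)}
    poor = {f"r{i}" for i in range(40)} | {"unremoved1"}
    assert curation_specificity(removed50, poor) == pytest.approx(0.80)
    assert curation_specificity({"a"}, {"a"}) == 1.0
    assert curation_specificity({"a"}, {"b"}) == 0.0
    with pytest.raises(ValueError):
        curation_sensitivity({"a"}, set())
    with pytest.raises(ValueError):
        curation_specificity(set(), {"a"})


def test_agreement_identical_disjoint_and_errors():
    assert curation_agreement([{"a", "b"}, {"a", "b"}, {"a", "b"}]) == 1.0
    assert curation_agreement([{"a", "b"}, {"c", "d"}]) == 0.0
    with pytest.raises(ValueError):
        curation_agreement([{"a"}])
    with pytest.raises(ValueError):
        curation_agreement([{"a"}, {"a", "b"}])


def test_random_removal_agreement_converges_to_rate():
    """Mean pairwise overlap of random removal sets approaches k/N."""
    rng = np.random.default_rng(0)
    n_pool, k, repeats = 100, 20, 200
    sets = [set(map(int, rng.choice(n_pool, size=k, replace=False)))
            for _ in range(repeats)]
    agreement = curation_agreement(sets)
    assert agreement == pytest.approx(k / n_pool, abs=0.01)


def test_ensemble_identities_and_mean_logit():
    vol = Volume(np.zeros((4, 4, 4), np.float32))
    single = _ConstantLogits(1.0)
    assert ensemble_predict([single], vol).count() == 64
    # k identical copies equal the single model
    assert np.array_equal(ensemble_predict([single] * 3, vol).voxels,
                          single.predict_mask(vol).voxels)
    # logits {2, -1, 1}: mean 0.667 > 0 -> foreground
    trio = [_ConstantLogits(2.0), _ConstantLogits(-1.0), _ConstantLogits(1.0)]
    assert ensemble_predict(trio, vol).count() == 64
    duo = [_ConstantLogits(2.0), _ConstantLogits(-3.0)]
    assert ensemble_predict(duo, vol).count() == 0
    with pytest.raises(ValueError):
        ensemble_predict([], vol)
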