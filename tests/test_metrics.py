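"""Metric correctness against brute-force oracles and stated conventions."""

import numpy as np
import pytest

from segcurate import Mask, dsc, hausdorff, msd, surface_voxels
from segcurate.metrics import (QualityScore, curation_efficacy,
                               quality_from_flags, surface_distances,
                               synthetic_quality_score)
from segcurate.types import Case, CorruptionRecord, Volume

from conftest import random_blob_mask


# ---- independent oracles --------------------------------------------------

def brute_dsc(a: Mask, b: Mask) -> float:
    fa = {tuple(v) for v in np.argwhere(a.voxels)}
    fb = {tuple(v) for v in np.argwhere(b.voxels)}
    if not fa and not fb:
        return 1.0
    return 2 * len(fa & fb) / (len(fa) + len(fb))


def brute_surface(mask: Mask) -> set:
    fg = {tuple(v) for v in np.argwhere(mask.voxels)}
    shape = mask.shape
    surf = set()
    for v in fg:
        for axis in range(3):
            for step in (1, -1):
                n = list(v)
                n[axis] += step
                if tuple(n) not in fg or not all(0 <= n[i] < shape[i] for i in range(3)):
                    surf.add(v)
    return surf


def brute_surface_metrics(a: Mask, b: Mask) -> tuple[float, float]:
    """All-pairs O(n^2) mean surface distance and Hausdorff distance."""
    sp = np.asarray(a.spacing)
    pa = np.array(sorted(brute_surface(a))) * sp
    pb = np.array(sorted(brute_surface(b))) * sp
    d = np.sqrt(((pa[:, None, :] - pb[None, :, :]) ** 2).sum(-1))
    d_ab, d_ba = d.min(axis=1), d.min(axis=0)
    return (d_ab.mean() + d_ba.mean()) / 2, max(d_ab.max(), d_ba.max())


# ---- DSC ------------------------------------------------------------------

def test_dsc_identity_disjoint_and_half_overlap():
    grid = np.zeros((8, 8, 8), bool)
    a = grid.copy(); a[0:2, 0, 0] = True; a[0:2, 1, 0] = True    # |A| = 4
    b = grid.copy(); b[0:2, 1, 0] = True; b[0:2, 2, 0] = True    # |B| = 4, overlap 2
    assert dsc(Mask(a), Mask(a)) == 1.0
    assert dsc(Mask(a), Mask(grid)) == 0.0  # empty vs nonempty
    assert dsc(Mask(a), Mask(b)) == pytest.approx(0.5)


def test_dsc_empty_conventions():
    empty = Mask(np.zeros((4, 4, 4), bool))
    assert dsc(empty, empty) == 1.0
    nonempty = np.zeros((4, 4, 4), bool); nonempty[1, 1, 1] = True
    assert dsc(empty, Mask(nonempty)) == 0.0


def test_dsc_shape_mismatch_errors():
    with pytest.raises(ValueError):
        dsc(Mask(np.ones((3, 3, 3), bool)), Mask(np.ones((4, 4, 4), bool)))


def test_dsc_matches_brute_force_and_is_symmetric():
    rng = np.random.default_rng(0)
    for _ in range(100):
        a = random_blob_mask(rng, shape=(10, 10, 10))
        b = random_blob_mask(rng, shape=(10, 10, 10))
        expected = brute_dsc(a, b)
        assert dsc(a, b) == pytest.approx(expected, abs=0)
        assert dsc(b, a) == dsc(a, b)
        assert 0.0 <= dsc(a, b) <= 1.0


# ---- surfaces and distances ----------------------------------------------

def test_surface_single_voxel_and_cube():
    vox = np.zeros((5, 5, 5), bool)
    vox[2, 2, 2] = True
    assert [tuple(v) for v in surface_voxels(Mask(vox))] == [(2, 2, 2)]
    cube = np.zeros((5, 5, 5), bool)
    cube[1:4, 1:4, 1:4] = True
    surf = surface_voxels(Mask(cube))
    assert len(surf) == 26                       # all but the centre
    assert (2, 2, 2) not in {tuple(v) for v in surf}


def test_surface_grid_boundary_counts_as_background():
    full = Mask(np.ones((4, 4, 4), bool))
    surf = {tuple(v) for v in surface_voxels(full)}
    inner = {(i, j, k) for i in (1, 2) for j in (1, 2) for k in (1, 2)}
    assert surf == {tuple(v) for v in np.argwhere(np.ones((4, 4, 4)))} - inner


def test_single_voxels_5mm_apart():
    a = np.zeros((8, 8, 8), bool); a[1, 1, 1] = True
    b = np.zeros((8, 8, 8), bool); b[6, 1, 1] = True
    ma, mb = Mask(a, (1, 1, 1)), Mask(b, (1, 1, 1))
    assert msd(ma, mb) == pytest.approx(5.0)
    assert hausdorff(ma, mb) == pytest.approx(5.0)
    assert msd(ma, ma) == 0.0
    assert hausdorff(ma, ma) == 0.0


def test_distances_match_brute_force_oracle():
    rng = np.random.default_rng(7)
    for i in range(30):
        spacing = (1.0, 1.0, 2.0) if i % 3 == 0 else (1.0, 1.0, 1.0)
        a = random_blob_mask(rng, shape=(12, 12, 12), spacing=spacing)
        b = random_blob_mask(rng, shape=(12, 12, 12), spacing=spacing)
        exp_msd, exp_hd = brute_surface_metrics(a, b)
        assert msd(a, b) == pytest.approx(exp_msd, abs=1e-9)
        assert hausdorff(a, b) == pytest.approx(exp_hd, abs=1e-9)
        assert hausdorff(a, b) >= msd(a, b)


def test_translation_invariance():
    rng = np.random.default_rng(3)
    a = random_blob_mask(rng, shape=(10, 10, 10))
    b = random_blob_mask(rng, shape=(10, 10, 10))
    pad = ((2, 2), (2, 2), (2, 2))
    a2 = Mask(np.pad(a.voxels, pad), a.spacing)
    b2 = Mask(np.pad(b.voxels, pad), b.spacing)
    assert dsc(a2, b2) == pytest.approx(dsc(a, b))
    assert msd(a2, b2) == pytest.approx(msd(a, b), abs=1e-12)
    assert hausdorff(a2, b2) == pytest.approx(hausdorff(a, b), abs=1e-12)


def test_empty_mask_distances_error():
    empty = Mask(np.zeros((4, 4, 4), bool))
    one = np.zeros((4, 4, 4), bool); one[0, 0, 0] = True
    with pytest.raises(ValueError):
        msd(empty, Mask(one))
    with pytest.raises(ValueError):
        surface_voxels(empty)


# ---- curation efficacy ----------------------------------------------------

def test_curation_efficacy_arithmetic_and_id_join():
    delta, med = curation_efficacy({"a": 0.9, "b": 0.8}, {"a": 0.85, "b": 0.8})
    assert delta == {"a": pytest.approx(0.05), "b": 0.0}
    assert med == pytest.approx(0.025)
    # permuted key order gives the same answer
    delta2, med2 = curation_efficacy({"b": 0.8, "a": 0.9}, {"a": 0.85, "b": 0.8})
    assert delta2 == delta and med2 == med
    with pytest.raises(ValueError):
        curation_efficacy({"a": 1.0}, {"b": 1.0})


# ---- quality rubric -------------------------------------------------------

def test_quality_rubric_flag_to_score_mapping():
    assert quality_from_flags(set()).score == 4
    assert quality_from_flags(set(), good=True).score == 5
    assert quality_from_flags({"a"}).score == 3
    assert quality_from_flags({"a", "e"}).score == 2
    assert quality_from_flags({"a", "b", "e"}).score == 1
    assert quality_from_flags({"a", "b", "c", "d"}).score == 1


def test_quality_score_invariants_enforced():
    with pytest.raises(ValueError):
        QualityScore(5, frozenset({"a"}))      # flags forbid scores 4-5
    with pytest.raises(ValueError):
        QualityScore(2, frozenset({"a"}))      # one flag means score 3
    with pytest.raises(ValueError):
        QualityScore(3, frozenset({"x"}))      # unknown flag


def test_synthetic_quality_oracle_scores_corruption_below_threshold():
    vol = Volume(np.zeros((6, 6, 6), np.float32))
    vox = np.zeros((6, 6, 6), bool); vox[2:4, 2:4, 2:4] = True
    rec = CorruptionRecord(op="dilate", direction=(1, 0, 0), magnitude=5,
                           agreement_dsc=0.78)
    case = Case("c1", vol, Mask(vox), corrupted=True, record=rec)
    score = synthetic_quality_score(case)
    assert score.score < 4 and "e" in score.flags
    clean = Case("c2", vol, Mask(vox))
    assert synthetic_quality_score(clean).score == 5
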