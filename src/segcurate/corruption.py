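"""Segmentation-corruption simulator.

Two corruption operators emulate the error modes seen in clinical contouring:

* **systematic** (bias-type): the reference mask is dilated laterally —
  along the sagittal axis, away from the grid midline — by a fixed number of
  voxels (default 10 voxels = 1.0 cm at 1 mm spacing), emulating lateral
  fan-out that sweeps in skin/bone/air;
* **random** (variance-type): the mask is dilated or eroded (p = 1/2 each)
  in one of the six signed Cartesian directions (p = 1/6 each). Dilations use
  the systematic magnitude; erosions are 20 % smaller (``round(0.8 * m)``) to
  compensate for the size-sensitivity of DSC loss.

Directional morphology uses a line structuring element anchored at the
origin: dilation is the union of the mask shifted by ``k * direction`` for
``k = 0..m``; erosion is its dual (voxels whose whole forward line segment is
foreground), so only the face in the sampled direction moves.

Cohort corruption selects ``round(i * N)`` training cases uniformly without
replacement, and :func:`calibrate_magnitude` searches the integer magnitude
whose 100 %-corrupted median agreement DSC is closest to a target (the
lowest-agreement-quartile median of a baseline cross-validation).
"""

from __future__ import annotations

import math
import warnings

import numpy as np

from .metrics import dsc
from .seeds import derive_seed
from .types import DIRECTIONS, Case, CorruptionRecord, CorruptionSpec, Mask

__all__ = [
    "directional_dilate", "directional_erode", "corrupt_systematic",
    "corrupt_random", "corrupt_cohort", "calibrate_magnitude",
    "lateral_direction", "round_half_away",
]


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (so 0.5 -> 1)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def _shift(mask: np.ndarray, step: tuple[int, int, int]) -> np.ndarray:
    """Shift a binary grid by one signed unit step, zero-filling the edge."""
    out = np.zeros_like(mask)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    for axis, s in enumerate(step):
        if s == 1:
            src[axis], dst[axis] = slice(0, -1), slice(1, None)
        elif s == -1:
            src[axis], dst[axis] = slice(1, None), slice(0, -1)
    out[tuple(dst)] = mask[tuple(src)]
    return out


def _check_direction(direction) -> tuple[int, int, int]:
    d = tuple(int(v) for v in direction)
    if d not in DIRECTIONS:
        raise ValueError(f"direction must be one of the 6 signed unit steps, got {direction}")
    return d


def directional_dilate(mask: Mask, direction, m: int, strict: bool = True) -> Mask:
    """Dilate with a length-``m`` line element along ``direction``.

    The result is the union of the input shifted by ``k * direction`` for
    ``k = 0..m`` — a superset of the input. With ``strict`` (the default),
    raises if any foreground voxel would be pushed across the grid boundary;
    with ``strict=False`` shifted voxels falling outside the grid are
    clipped, the semantics under which erosion is the exact complement dual.
    """
    d = _check_direction(direction)
    if m < 0:
        raise ValueError("magnitude must be >= 0")
    vox = mask.voxels
    if strict and m > 0 and vox.any():
        axis = next(i for i, s in enumerate(d) if s != 0)
        idx = np.nonzero(vox.any(axis=tuple(a for a in range(3) if a != axis)))[0]
        if d[axis] > 0:
            room = vox.shape[axis] - 1 - idx.max()
        else:
            room = idx.min()
        if m > room:
            raise ValueError(
                f"dilation by {m} along {d} would cross the grid boundary (room {room})")
    out = vox.copy()
    shifted = vox
    for _ in range(m):
        shifted = _shift(shifted, d)
        out |= shifted
    return Mask(out, mask.spacing)


def directional_erode(mask: Mask, direction, m: int) -> Mask:
    """Erode with a length-``m`` line element along ``direction``.

    Keeps voxels ``v`` with ``v + k * direction`` foreground for all
    ``k = 0..m`` (grid boundary counts as background), i.e. only the face in
    ``direction`` is shaved. Dual to :func:`directional_dilate` on the
    complement with the opposite direction. An empty result is allowed.
    """
    d = _check_direction(direction)
    if m < 0:
        raise ValueError("magnitude must be >= 0")
    neg = tuple(-s for s in d)
    out = mask.voxels.copy()
    shifted = mask.voxels
    for _ in range(m):
        shifted = _shift(shifted, neg)
        out &= shifted
    return Mask(out, mask.spacing)


def lateral_direction(case: Case) -> tuple[int, int, int]:
    """Signed sagittal step pointing away from the grid's mid-sagittal plane."""
    return (1, 0, 0) if case.side == "right" else (-1, 0, 0)


def corrupt_systematic(case: Case, m: int) -> Case:
    """Apply the bias-type corruption: lateral dilation by ``m`` voxels."""
    d = lateral_direction(case)
    corrupted = directional_dilate(case.mask, d, m)
    rec = CorruptionRecord(op="dilate", direction=d, magnitude=m,
                           agreement_dsc=dsc(corrupted, case.mask))
    return case.with_mask(corrupted, rec)


def corrupt_random(case: Case, m: int, erosion_factor: float = 0.8,
                   seed: int = 0) -> Case:
    """Apply the variance-type corruption: random-direction dilate/erode.

    The operation is sampled with p = 1/2 each and the direction uniformly
    over the six signed axes. Erosion magnitude is ``round(erosion_factor *
    m)``. If an erosion would empty the mask, the direction is resampled (up
    to 6 attempts) before raising.
    """
    rng = np.random.default_rng(seed)
    op = "dilate" if rng.random() < 0.5 else "erode"
    m_ero = round_half_away(erosion_factor * m)
    for _attempt in range(6):
        d = DIRECTIONS[rng.integers(6)]
        if op == "dilate":
            corrupted, mag = directional_dilate(case.mask, d, m), m
        else:
            corrupted, mag = directional_erode(case.mask, d, m_ero), m_ero
        if not corrupted.is_empty() or case.mask.is_empty():
            rec = CorruptionRecord(op=op, direction=d, magnitude=mag,
                                   agreement_dsc=dsc(corrupted, case.mask))
            return case.with_mask(corrupted, rec)
    raise ValueError(f"erosion by {m_ero} emptied the mask of case {case.case_id} "
                     "in all 6 directions")


def corrupt_cohort(cases: list[Case], spec: CorruptionSpec) -> tuple[list[Case], set[str]]:
    """Corrupt ``round(fraction * N)`` cases, selected uniformly without
    replacement; others pass through untouched.

    Returns the new case list (original order) and the ground-truth set of
    corrupted case ids for later sensitivity scoring.
    """
    n = len(cases)
    k = round_half_away(spec.fraction * n)
    if spec.fraction > 0 and k == 0:
        warnings.warn("fraction rounds to zero corrupted cases", stacklevel=2)
    rng = np.random.default_rng(derive_seed(spec.seed, "select"))
    chosen = set(rng.choice(n, size=k, replace=False).tolist()) if k else set()
    out: list[Case] = []
    corrupted_ids: set[str] = set()
    for i, case in enumerate(cases):
        if i in chosen:
            if spec.mode == "systematic_lateral":
                out.append(corrupt_systematic(case, spec.magnitude))
            else:
                out.append(corrupt_random(case, spec.magnitude, spec.erosion_factor,
                                          seed=derive_seed(spec.seed, "case", case.case_id)))
            corrupted_ids.add(case.case_id)
        else:
            out.append(case)
    return out, corrupted_ids


def calibrate_magnitude(cases: list[Case], target_dsc: float,
                        mode: str = "systematic_lateral",
                        search_range: range = range(0, 16),
                        erosion_factor: float = 0.8, seed: int = 0) -> int:
    """Find the integer magnitude whose 100 %-corrupted median agreement DSC
    is closest to ``target_dsc``; ties break toward smaller magnitude.

    Warns (and still returns the best magnitude) when the achieved median
    does not bracket the target anywhere in the search range.
    """
    if not cases:
        raise ValueError("cohort must be nonempty")
    if not 0.0 < target_dsc <= 1.0:
        raise ValueError("target DSC must lie in (0, 1]")
    best_m, best_err = None, np.inf
    medians = []
    for m in search_range:
        spec = CorruptionSpec(mode=mode, magnitude=m, erosion_factor=erosion_factor,
                              fraction=1.0, seed=seed)
        corrupted, _ = corrupt_cohort(cases, spec)
        med = float(np.median([c.record.agreement_dsc for c in corrupted]))
        medians.append(med)
        err = abs(med - target_dsc)
        if err < best_err - 1e-12:
            best_m, best_err = m, err
    if target_dsc < min(medians) or target_dsc > max(medians):
        warnings.warn(
            f"target DSC {target_dsc} outside achievable range "
            f"[{min(medians):.3f}, {max(medians):.3f}]; returning closest magnitude",
            stacklevel=2)
    return int(best_m)
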