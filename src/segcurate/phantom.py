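"""Synthetic CT-like phantom cohorts with organ-shaped reference masks.

The phantom emulates the statistical structure the corruption and curation
experiments need, not anatomy: each case carries one lateralised organ — a
deformed ellipsoid with a low-frequency radial boundary perturbation,
standing in for a parotid-gland-like structure — embedded in a soft-tissue
background, with a high-intensity bone/skin slab and a low-intensity air
pocket placed laterally adjacent to the organ. Lateral over-segmentation of
the reference mask therefore sweeps in "bone/skin/air", the failure mode the
corruption simulator reproduces.

Reference masks are exact phantom boundaries ("clean" labels); an optional
observer-jitter knob adds ±1-voxel boundary noise but is off by default so
the clean/corrupt distinction stays sharp. Cohort generation is a pure
function of (parameters, master seed); out-of-distribution cohorts come from
:func:`shift_distribution`, which offsets phantom parameters.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .seeds import derive_seed
from .types import Case, Mask, Volume

__all__ = ["PhantomParams", "generate_case", "generate_cohort", "shift_distribution"]

_FACE_STRUCTURE = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


@dataclass(frozen=True)
class PhantomParams:
    """Phantom cohort parameters (lengths in mm, intensities CT-like)."""

    grid_shape: tuple[int, int, int] = (48, 48, 48)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    radius_mm: float = 6.0              # mean organ radius
    radius_jitter_mm: float = 0.5       # per-case uniform radius variation
    ecc_range: tuple[float, float] = (0.9, 1.1)   # per-axis eccentricity
    deform_amp_mm: float = 1.0          # low-frequency radial perturbation
    lateral_offset_mm: float = 3.0      # organ centre offset from midline
    organ_intensity: float = 80.0
    background_intensity: float = 30.0
    bone_intensity: float = 700.0
    air_intensity: float = -900.0
    noise_sd: float = 20.0
    smooth_mm: float = 1.0
    side: str | None = None             # None -> sampled per case (p = 1/2)
    margin_voxels: int = 12             # room reserved for corruption dilations
    boundary_jitter: bool = False       # optional ±1-voxel observer noise

    def __post_init__(self) -> None:
        if self.radius_mm <= 0 or self.radius_jitter_mm < 0:
            raise ValueError("organ radius must be positive, jitter non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if not 0 < self.ecc_range[0] <= self.ecc_range[1]:
            raise ValueError("eccentricity range must be positive and ordered")
        if self.side not in (None, "left", "right"):
            raise ValueError("side must be None, 'left' or 'right'")
        if any(n < 8 for n in self.grid_shape):
            raise ValueError("grid too small for a phantom organ")


def _harmonic_field(n_hat: np.ndarray, coeffs: np.ndarray) -> np.ndarray:
    """Low-frequency (degree <= 2 harmonic-like) angular perturbation in [-1, 1]."""
    x, y, z = n_hat[..., 0], n_hat[..., 1], n_hat[..., 2]
    basis = np.stack([x * y, y * z, x * z, x * x - y * y, 3 * z * z - 1.0], axis=-1)
    field = basis @ coeffs
    norm = np.abs(coeffs).sum() + 1e-12
    return field / max(norm, 1.0)


def generate_case(params: PhantomParams, seed: int, case_id: str = "case_0000") -> Case:
    """Generate one phantom case deterministically from (params, seed)."""
    rng = np.random.default_rng(seed)
    shape = params.grid_shape
    spacing = np.asarray(params.spacing, dtype=float)

    side = params.side or ("right" if rng.random() < 0.5 else "left")
    sign = 1.0 if side == "right" else -1.0
    radius = params.radius_mm + rng.uniform(-1, 1) * params.radius_jitter_mm
    ecc = rng.uniform(*params.ecc_range, size=3)
    coeffs = rng.uniform(-1.0, 1.0, size=5)

    centre_mm = (np.asarray(shape) - 1) * spacing / 2.0
    centre_mm = centre_mm + np.array([sign * params.lateral_offset_mm, 0.0, 0.0])
    # small random centre wobble keeps cohorts from being perfectly registered
    centre_mm = centre_mm + rng.uniform(-1.0, 1.0, size=3) * spacing

    idx = np.indices(shape).transpose(1, 2, 3, 0).astype(float)
    pos_mm = idx * spacing
    delta = pos_mm - centre_mm
    dist = np.linalg.norm(delta, axis=-1)
    with np.errstate(invalid="ignore"):
        n_hat = np.where(dist[..., None] > 0, delta / np.maximum(dist[..., None], 1e-9), 0.0)

    radii = radius * ecc  # per-axis semi-axes in mm
    rho = np.sqrt(((delta / radii) ** 2).sum(axis=-1))
    perturb = params.deform_amp_mm * _harmonic_field(n_hat, coeffs)
    mask_arr = rho <= 1.0 + perturb / radius

    if params.boundary_jitter:
        # ±1-voxel observer noise: randomly toggle boundary voxels
        boundary = mask_arr ^ ndimage.binary_erosion(mask_arr, _FACE_STRUCTURE)
        outer = ndimage.binary_dilation(mask_arr, _FACE_STRUCTURE) ^ mask_arr
        flip = rng.random(shape) < 0.5
        mask_arr = mask_arr ^ (boundary & flip) | (outer & flip & (rng.random(shape) < 0.5))

    labels, n_comp = ndimage.label(mask_arr, structure=_FACE_STRUCTURE)
    if n_comp != 1:
        # perturbation amplitudes are small relative to the radius, so a split
        # mask indicates invalid params rather than bad luck
        raise ValueError(f"phantom mask is not a single 6-connected component ({n_comp})")

    _check_interior_margin(mask_arr, params.margin_voxels, case_id)

    # ---- intensity model -------------------------------------------------
    image = np.full(shape, params.background_intensity, dtype=float)
    image[mask_arr] = params.organ_intensity

    nx = shape[0]
    if side == "right":
        bone_slab = slice(nx - 6, nx - 2)
        air_x = nx - 9
    else:
        bone_slab = slice(2, 6)
        air_x = 8
    image[bone_slab, :, :] = params.bone_intensity
    # small air pocket between organ and bone at the organ's axial level
    cy, cz = int(round(centre_mm[1] / spacing[1])), int(round(centre_mm[2] / spacing[2]))
    air = np.zeros(shape, dtype=bool)
    air[max(air_x - 1, 0):air_x + 2, max(cy - 2, 0):cy + 3, max(cz - 2, 0):cz + 3] = True
    air &= ~mask_arr
    image[air] = params.air_intensity

    sigma = np.asarray(params.smooth_mm) / spacing
    image = ndimage.gaussian_filter(image, sigma=sigma)
    image = image + rng.normal(0.0, params.noise_sd, size=shape)

    return Case(case_id=case_id,
                volume=Volume(image.astype(np.float32), tuple(spacing)),
                mask=Mask(mask_arr, tuple(spacing)),
                side=side)


def _check_interior_margin(mask_arr: np.ndarray, margin: int, case_id: str) -> None:
    """Every mask must leave `margin` voxels of room along all six directions."""
    for axis in range(3):
        other = tuple(a for a in range(3) if a != axis)
        occupied = np.nonzero(mask_arr.any(axis=other))[0]
        lo, hi = occupied.min(), occupied.max()
        room_neg, room_pos = lo, mask_arr.shape[axis] - 1 - hi
        if min(room_neg, room_pos) < margin:
            raise ValueError(
                f"phantom {case_id} violates interior margin: axis {axis} room "
                f"({room_neg}, {room_pos}) < margin {margin}")


def _split_counts(n: int, proportions: tuple[float, ...]) -> list[int]:
    """Largest-remainder allocation; ties favour earlier splits (train first)."""
    total = float(sum(proportions))
    targets = [n * p / total for p in proportions]
    counts = [int(np.floor(t)) for t in targets]
    remainder = n - sum(counts)
    order = sorted(range(len(targets)),
                   key=lambda i: (-(targets[i] - counts[i]), i))
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def generate_cohort(n: int, params: PhantomParams, seed: int,
                    proportions: tuple[float, ...] = (100, 40, 40),
                    split_names: tuple[str, ...] = ("train", "val", "test_true"),
                    id_prefix: str = "case") -> tuple[list[Case], pd.DataFrame]:
    """Generate ``n`` cases with per-case seeds derived from ``seed`` and
    split labels allocated by ``proportions`` (largest remainder, train first).

    Returns the cases and an in-memory manifest table (paths are left blank
    until the cohort is written to disk).
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    if len(proportions) != len(split_names):
        raise ValueError("proportions and split_names must align")
    counts = _split_counts(n, proportions)
    split_of = []
    for name, c in zip(split_names, counts):
        split_of.extend([name] * c)

    cases, rows = [], []
    for i in range(n):
        cid = f"{id_prefix}_{i:04d}"
        case = generate_case(params, derive_seed(seed, "case", i), case_id=cid)
        case = dataclasses.replace(case, split=split_of[i])
        cases.append(case)
        rows.append({"case_id": cid, "volume": f"{cid}_ct.nii.gz",
                     "mask": f"{cid}_mask.nii.gz", "split": split_of[i],
                     "corrupted": False, "quality": pd.NA, "side": case.side})
    return cases, pd.DataFrame(rows)


def shift_distribution(params: PhantomParams, shift_spec: dict[str, float]) -> PhantomParams:
    """Offset named phantom parameters (additively) to emulate an
    out-of-distribution cohort; validation re-runs on the result."""
    updates = {}
    for name, offset in shift_spec.items():
        if not hasattr(params, name):
            raise ValueError(f"unknown phantom parameter {name!r}")
        value = getattr(params, name)
        if isinstance(value, tuple):
            if np.isscalar(offset):
                updates[name] = tuple(v + offset for v in value)
            else:
                updates[name] = tuple(v + o for v, o in zip(value, offset))
        else:
            updates[name] = value + offset
    return replace(params, **updates)
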