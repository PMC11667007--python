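"""Core domain containers shared across the package.

Grid convention
---------------
All 3D grids use a fixed axis order:

* axis 0 — sagittal axis, increasing left -> right ("lateral" moves along
  this axis, with sign pointing away from the mid-sagittal plane of the grid);
* axis 1 — increasing anterior -> posterior;
* axis 2 — increasing inferior -> superior (caudo-cranial).

Spacings are physical voxel sizes in millimetres along these axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

SPLITS = ("train", "val", "test_true", "test_apparent", "external")

#: the six signed Cartesian unit steps a directional corruption may take
DIRECTIONS: tuple[tuple[int, int, int], ...] = (
    (1, 0, 0), (-1, 0, 0),
    (0, 1, 0), (0, -1, 0),
    (0, 0, 1), (0, 0, -1),
)


def _check_spacing(spacing: tuple[float, float, float]) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be three positive numbers, got {spacing}")
    return spacing


@dataclass
class Volume:
    """A 3D scalar image (CT-like intensities) with voxel spacing in mm."""

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or self.voxels.size == 0:
            raise ValueError("volume must be a non-empty 3D grid")
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class Mask:
    """A binary 3D grid aligned with a :class:`Volume`."""

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.voxels)
        if arr.ndim != 3 or arr.size == 0:
            raise ValueError("mask must be a non-empty 3D grid")
        if arr.dtype != bool:
            uniq = np.unique(arr)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError("mask voxels must be binary (0/1)")
            arr = arr.astype(bool)
        self.voxels = arr
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def count(self) -> int:
        return int(self.voxels.sum())

    def is_empty(self) -> bool:
        return not bool(self.voxels.any())

    def copy(self) -> "Mask":
        return Mask(self.voxels.copy(), self.spacing)


@dataclass
class CorruptionRecord:
    """Provenance of one applied corruption operation."""

    op: str                              # "dilate" | "erode"
    direction: tuple[int, int, int]      # one of the 6 signed unit steps
    magnitude: int                       # voxels actually applied
    agreement_dsc: float                 # DSC of corrupted vs clean mask

    def __post_init__(self) -> None:
        if self.op not in ("dilate", "erode"):
            raise ValueError(f"unknown corruption op {self.op!r}")
        if tuple(self.direction) not in DIRECTIONS:
            raise ValueError(f"direction must be a signed Cartesian unit step, got {self.direction}")
        self.direction = tuple(self.direction)
        if not 0.0 <= self.agreement_dsc <= 1.0:
            raise ValueError("agreement DSC must lie in [0, 1]")


@dataclass
class CorruptionSpec:
    """Parameters of the cohort-level segmentation-corruption simulator.

    ``mode`` selects the bias-type operator (systematic lateral dilation) or
    the variance-type operator (random dilation/erosion); ``magnitude`` is the
    dilation extent in voxels (10 voxels = 1.0 cm at the default 1 mm grid);
    erosions are scaled down by ``erosion_factor`` (default 0.8, i.e. 20 %
    smaller); ``fraction`` is the share of training cases corrupted.
    """

    mode: str = "systematic_lateral"
    magnitude: int = 10
    erosion_factor: float = 0.8
    fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("systematic_lateral", "random"):
            raise ValueError(f"unknown corruption mode {self.mode!r}")
        if self.magnitude < 0:
            raise ValueError("magnitude must be >= 0")
        if not 0.0 < self.erosion_factor <= 1.0:
            raise ValueError("erosion_factor must lie in (0, 1]")
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("fraction must lie in [0, 1]")


@dataclass
class Case:
    """One patient-organ unit: image, reference mask and provenance."""

    case_id: str
    volume: Volume
    mask: Mask
    side: str = "left"                     # which lateral half the organ sits in
    corrupted: bool = False
    record: Optional[CorruptionRecord] = None
    quality_score: Optional[int] = None    # 1..5 when assigned
    split: Optional[str] = None

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")
        if self.volume.shape != self.mask.shape:
            raise ValueError("mask grid must match its paired volume")
        if self.corrupted != (self.record is not None):
            raise ValueError("corrupted flag must be set iff a corruption record is present")
        if self.quality_score is not None and self.quality_score not in (1, 2, 3, 4, 5):
            raise ValueError("quality score must be in 1..5")

    def with_mask(self, mask: Mask, record: Optional[CorruptionRecord] = None) -> "Case":
        """Return a copy with a replaced reference mask (and optional record)."""
        return replace(
            self,
            mask=mask,
            record=record if record is not None else self.record,
            corrupted=(record is not None) or self.corrupted,
        )
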