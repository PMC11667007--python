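"""Reading and writing volumes, masks and cohort manifests.

Volumes and masks travel as NIfTI (.nii / .nii.gz); manifests are plain CSV
with columns ``case_id,volume,mask,split,corrupted,quality`` (extra columns
are preserved but ignored). On load, images are reoriented to the closest
canonical (RAS-like) axis order so that axis 0 is the sagittal left->right
axis of the package convention; loading an already-canonical file is a no-op.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import nibabel as nib
import numpy as np
import pandas as pd

from .types import SPLITS, Case, CorruptionRecord, Mask, Volume

MANIFEST_COLUMNS = ("case_id", "volume", "mask", "split", "corrupted", "quality")


def _load_canonical(path: str | os.PathLike) -> tuple[np.ndarray, tuple[float, float, float]]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    img = nib.as_closest_canonical(img)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"non-3D image ({data.ndim}D) in {path}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    if any(s <= 0 for s in spacing):
        raise ValueError(f"non-positive voxel spacing {spacing} in {path}")
    return data, spacing


def read_volume(path: str | os.PathLike) -> Volume:
    """Read a NIfTI scalar volume; spacing comes from the header zooms."""
    data, spacing = _load_canonical(path)
    return Volume(np.asarray(data, dtype=np.float32), spacing)


def read_mask(path: str | os.PathLike) -> Mask:
    """Read a NIfTI label image as a binary mask (foreground = value > 0)."""
    data, spacing = _load_canonical(path)
    return Mask(np.asarray(data) > 0, spacing)


def _ras_affine(spacing: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def write_volume(volume: Volume, path: str | os.PathLike) -> None:
    img = nib.Nifti1Image(np.asarray(volume.voxels, dtype=np.float32),
                          _ras_affine(volume.spacing))
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def write_mask(mask: Mask, path: str | os.PathLike) -> None:
    """Write a binary mask as unsigned 8-bit NIfTI (values 0/1)."""
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), _ras_affine(mask.spacing))
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))


@dataclass
class CohortManifest:
    """A table of cases (paths + split/corruption/quality bookkeeping)."""

    table: pd.DataFrame
    root: Path

    def __post_init__(self) -> None:
        missing = [c for c in MANIFEST_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"manifest missing required columns {missing}")
        ids = self.table["case_id"].astype(str)
        if ids.duplicated().any():
            dupes = sorted(ids[ids.duplicated()].unique())
            raise ValueError(f"duplicate case_ids in manifest: {dupes}")
        bad = set(self.table["split"]) - set(SPLITS)
        if bad:
            raise ValueError(f"unknown split labels {sorted(bad)}; allowed: {SPLITS}")

    def split_counts(self) -> dict[str, int]:
        counts = self.table["split"].value_counts().to_dict()
        return {s: int(counts.get(s, 0)) for s in SPLITS if counts.get(s, 0)}

    def case_ids(self, split: str | None = None) -> list[str]:
        t = self.table if split is None else self.table[self.table["split"] == split]
        return [str(c) for c in t["case_id"]]

    def load_case(self, case_id: str) -> Case:
        row = self.table[self.table["case_id"].astype(str) == str(case_id)]
        if row.empty:
            raise KeyError(f"unknown case_id {case_id!r}")
        row = row.iloc[0]
        volume = read_volume(self.root / str(row["volume"]))
        mask = read_mask(self.root / str(row["mask"]))
        quality = row["quality"]
        corrupted = bool(row["corrupted"])
        record = None
        if corrupted:
            # manifests do not carry the full corruption record; attach a
            # minimal placeholder so the corrupted-iff-record invariant holds
            record = CorruptionRecord(op=str(row["corruption_op"]) if "corruption_op" in row.index
                                      else "dilate",
                                      direction=(1, 0, 0), magnitude=0, agreement_dsc=1.0)
        return Case(
            case_id=str(row["case_id"]),
            volume=volume,
            mask=mask,
            side=str(row["side"]) if "side" in row.index else "left",
            corrupted=corrupted,
            record=record,
            quality_score=None if pd.isna(quality) else int(quality),
            split=str(row["split"]),
        )

    def iter_cases(self, split: str | None = None) -> Iterator[Case]:
        for cid in self.case_ids(split):
            yield self.load_case(cid)


def load_cohort(manifest_path: str | os.PathLike) -> CohortManifest:
    """Load a CSV cohort manifest; paths are resolved relative to the CSV."""
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FileNotFoundError(manifest_path)
    table = pd.read_csv(manifest_path)
    return CohortManifest(table=table, root=manifest_path.parent)


def save_cohort(manifest: CohortManifest | pd.DataFrame, manifest_path: str | os.PathLike) -> None:
    table = manifest.table if isinstance(manifest, CohortManifest) else manifest
    table.to_csv(manifest_path, index=False)
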