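"""Agreement metrics between binary masks and derived curation quantities.

The three standard segmentation-agreement measures are implemented on the
voxel grid:

* DSC — Dice similarity coefficient, ``2|A∩B| / (|A|+|B|)``;
* MSD — mean surface distance: the symmetric average of the two directed
  mean nearest-surface-point distances, in mm;
* HD — (maximum) Hausdorff distance: the larger of the two directed maximum
  nearest-surface distances, in mm.

Surfaces are the sets of foreground voxels with at least one of their six
face-neighbours in the background (the grid boundary counts as background),
and distances are measured between surface-voxel centres scaled by the voxel
spacing. Conventions for degenerate inputs: DSC of two empty masks is 1,
empty-vs-nonempty is 0; MSD/HD require both masks nonempty.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .types import Case, Mask

__all__ = [
    "dsc", "surface_voxels", "msd", "hausdorff", "surface_distances",
    "curation_efficacy", "evaluate_cohort", "MetricsReport",
    "QualityScore", "quality_from_flags", "synthetic_quality_score",
]


def _check_same_grid(a: Mask, b: Mask) -> None:
    if a.shape != b.shape:
        raise ValueError(f"mask grids differ: {a.shape} vs {b.shape}")


def dsc(a: Mask, b: Mask) -> float:
    """Dice similarity coefficient between two binary masks."""
    _check_same_grid(a, b)
    na, nb = a.count(), b.count()
    if na == 0 and nb == 0:
        return 1.0
    inter = int(np.logical_and(a.voxels, b.voxels).sum())
    return 2.0 * inter / (na + nb)


def surface_voxels(mask: Mask) -> np.ndarray:
    """Indices (k, 3) of foreground voxels with a background face-neighbour."""
    if mask.is_empty():
        raise ValueError("surface of an empty mask is undefined")
    m = mask.voxels
    padded = np.pad(m, 1, constant_values=False)
    interior = np.ones_like(m)
    for axis in range(3):
        for step in (1, -1):
            shifted = np.roll(padded, step, axis=axis)[1:-1, 1:-1, 1:-1]
            interior &= shifted
    surface = m & ~interior
    return np.argwhere(surface)


def surface_distances(a: Mask, b: Mask) -> tuple[np.ndarray, np.ndarray]:
    """Directed nearest-surface distances (a->b, b->a) in mm."""
    _check_same_grid(a, b)
    if a.is_empty() or b.is_empty():
        raise ValueError("surface distances require both masks nonempty")
    spacing = np.asarray(a.spacing)
    pa = surface_voxels(a) * spacing
    pb = surface_voxels(b) * spacing
    d_ab = cKDTree(pb).query(pa, k=1)[0]
    d_ba = cKDTree(pa).query(pb, k=1)[0]
    return d_ab, d_ba


def msd(a: Mask, b: Mask, spacing: tuple[float, float, float] | None = None) -> float:
    """Symmetric mean surface distance in mm."""
    if spacing is not None:
        a, b = Mask(a.voxels, spacing), Mask(b.voxels, spacing)
    d_ab, d_ba = surface_distances(a, b)
    return float((d_ab.mean() + d_ba.mean()) / 2.0)


def hausdorff(a: Mask, b: Mask, spacing: tuple[float, float, float] | None = None) -> float:
    """Maximum (symmetric) Hausdorff distance in mm."""
    if spacing is not None:
        a, b = Mask(a.voxels, spacing), Mask(b.voxels, spacing)
    d_ab, d_ba = surface_distances(a, b)
    return float(max(d_ab.max(), d_ba.max()))


def curation_efficacy(curated_dsc: dict[str, float],
                      noncurated_dsc: dict[str, float]) -> tuple[dict[str, float], float]:
    """Per-case curated-minus-noncurated DSC and its median.

    Positive values mean curation helped. Inputs are keyed by case id and
    joined on ids, so ordering is irrelevant.
    """
    if set(curated_dsc) != set(noncurated_dsc):
        raise ValueError("curated and non-curated results cover different case ids")
    delta = {cid: curated_dsc[cid] - noncurated_dsc[cid] for cid in curated_dsc}
    return delta, float(np.median(list(delta.values())))


@dataclass
class MetricsReport:
    """Per-case metric rows plus median[IQR] aggregates."""

    rows: pd.DataFrame  # columns: case_id, dsc, msd_mm, hd_mm

    def aggregates(self) -> dict[str, dict[str, float]]:
        out: dict[str, dict[str, float]] = {}
        for col in ("dsc", "msd_mm", "hd_mm"):
            vals = self.rows[col].dropna().to_numpy()
            if vals.size == 0:
                continue
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            out[col] = {
                "median": float(med), "iqr_low": float(q1), "iqr_high": float(q3),
                "min": float(vals.min()), "max": float(vals.max()),
            }
        return out

    def __str__(self) -> str:  # median[IQR] reporting style
        parts = []
        for col, agg in self.aggregates().items():
            parts.append(f"{col}: {agg['median']:.3f}[{agg['iqr_low']:.3f}-{agg['iqr_high']:.3f}]")
        return "; ".join(parts)


def evaluate_cohort(segmenter, cases: list[Case], with_distances: bool = True) -> MetricsReport:
    """Apply a trained segmenter to each case and score against its reference.

    ``segmenter`` is anything with ``predict_mask(volume) -> Mask``. Distance
    metrics are NaN when either prediction or reference is empty.
    """
    records = []
    for case in cases:
        pred = segmenter.predict_mask(case.volume)
        row = {"case_id": case.case_id, "dsc": dsc(pred, case.mask),
               "msd_mm": np.nan, "hd_mm": np.nan}
        if with_distances and not pred.is_empty() and not case.mask.is_empty():
            d_ab, d_ba = surface_distances(pred, case.mask)
            row["msd_mm"] = float((d_ab.mean() + d_ba.mean()) / 2.0)
            row["hd_mm"] = float(max(d_ab.max(), d_ba.max()))
        records.append(row)
    return MetricsReport(pd.DataFrame.from_records(records))


# ---------------------------------------------------------------------------
# quality rubric
# ---------------------------------------------------------------------------

#: shortcoming codes: the segmentation excludes considerable portions of the
#: (a) medial lobe, (b) anterior lobe, (c) caudal tissue, (d) dorsal tissue,
#: or (e) includes substantial bone/skin/air.
SHORTCOMINGS = ("a", "b", "c", "d", "e")


@dataclass(frozen=True)
class QualityScore:
    """Specialist-review quality rubric: score 1-5 plus shortcoming flags.

    1 defective (>= three shortcomings), 2 poor (two), 3 insufficient (one),
    4 satisfactory (1-2 mm inaccuracies, no shortcoming), 5 good.
    """

    score: int
    flags: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.score not in (1, 2, 3, 4, 5):
            raise ValueError("score must be in 1..5")
        if not set(self.flags) <= set(SHORTCOMINGS):
            raise ValueError(f"unknown shortcoming flags {set(self.flags) - set(SHORTCOMINGS)}")
        n = len(self.flags)
        expected = 1 if n >= 3 else {2: 2, 1: 3}.get(n, None)
        if expected is None and self.score not in (4, 5):
            raise ValueError("scores 4-5 require zero shortcoming flags")
        if expected is not None and self.score != expected:
            raise ValueError(f"{n} flags imply score {expected}, got {self.score}")

    @property
    def acceptable(self) -> bool:
        """Only severe errors (score < 4) warrant exclusion from training."""
        return self.score >= 4


def quality_from_flags(flags: set[str], good: bool = False) -> QualityScore:
    """Map a shortcoming-flag set onto the 1-5 rubric."""
    flags = frozenset(flags)
    n = len(flags)
    if n >= 3:
        return QualityScore(1, flags)
    if n == 2:
        return QualityScore(2, flags)
    if n == 1:
        return QualityScore(3, flags)
    return QualityScore(5 if good else 4, flags)


# flag assignment for synthetic corruptions: which anatomical shortcoming a
# directional operation emulates on the package's axis convention
_DIRECTION_FLAGS = {
    (0, 1, 0): "d",   # posterior over/under-reach -> dorsal tissue
    (0, -1, 0): "b",  # anterior -> anterior lobe
    (0, 0, -1): "c",  # inferior -> caudal tissue
    (0, 0, 1): "c",   # superior expansion treated as caudo-cranial tissue error
}


def synthetic_quality_score(case: Case, severe_dsc: float = 0.85) -> QualityScore:
    """Rubric oracle for phantom cases with known corruption provenance.

    Clean reference labels score 5. A corrupted case receives the shortcoming
    flag its operation emulates (lateral dilation includes bone/skin/air ->
    flag e; medial erosion -> flag a; etc.); agreement DSC below
    ``severe_dsc`` adds the paired-lobe flag so heavily corrupted cases score
    at most 2. This synthetic stand-in exists so sensitivity/specificity
    definitions stay exercisable without specialist review.
    """
    if not case.corrupted or case.record is None:
        return QualityScore(5, frozenset())
    rec = case.record
    lateral = rec.direction in ((1, 0, 0), (-1, 0, 0))
    if lateral:
        # lateral dilation sweeps in skin/bone/air; lateral erosion cuts the
        # medial or lateral lobe — map both erosion signs onto the medial lobe
        primary = "e" if rec.op == "dilate" else "a"
    else:
        primary = _DIRECTION_FLAGS[rec.direction]
    flags = {primary}
    if rec.agreement_dsc < severe_dsc:
        flags.add("a" if primary != "a" else "e")
    return quality_from_flags(flags)
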