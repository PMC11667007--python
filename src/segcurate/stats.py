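"""Paired significance testing and aggregation for segmentation metrics.

DSC distributions are not normal, so paired conditions are compared with
two-sided Wilcoxon signed-rank tests; family-wise error over m comparisons is
controlled by adjusting the significance threshold to alpha/m (Bonferroni).
For experiments with repeated iterations, per-case medians over iterations
are tested instead of pooled raw repeats, so data points stay independent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PairedComparison", "wilcoxon_signed_rank", "bonferroni_threshold",
    "format_threshold", "aggregate_repeats", "significance_stars",
]

_EXACT_N_MAX = 25


@dataclass
class PairedComparison:
    """Aligned per-case paired metric values for one labelled comparison."""

    x: np.ndarray
    y: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("paired samples must be 1D arrays of equal length")

    @property
    def n(self) -> int:
        return int(self.x.size)


def wilcoxon_signed_rank(pairs: PairedComparison | tuple) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired values.

    Zero differences are discarded (the classical Wilcoxon convention). The
    exact null distribution is used for n <= 25 when the absolute differences
    are tie-free; otherwise the normal approximation with tie correction.
    Returns (W, p) where W is the smaller signed-rank sum.
    """
    if not isinstance(pairs, PairedComparison):
        pairs = PairedComparison(*pairs)
    diffs = pairs.x - pairs.y
    diffs = diffs[diffs != 0]
    if diffs.size == 0:
        raise ValueError("degenerate comparison: all zero differences")
    if diffs.size < 2:
        raise ValueError("need at least 2 nonzero differences")
    has_ties = np.unique(np.abs(diffs)).size < diffs.size
    method = "exact" if (diffs.size <= _EXACT_N_MAX and not has_ties) else "approx"
    res = sps.wilcoxon(diffs, alternative="two-sided", method=method, correction=False)
    return float(res.statistic), float(res.pvalue)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise adjusted significance threshold alpha/m."""
    if m < 1:
        raise ValueError("number of comparisons must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    return alpha / m


def format_threshold(threshold: float, sig_figs: int = 2) -> str:
    """Display form with 2 significant figures, e.g. 0.0018518... -> '1.9e-3'."""
    s = np.format_float_scientific(threshold, precision=sig_figs - 1, exp_digits=1)
    return s.replace("e+0", "e").replace("e-0", "e-").replace("e+", "e")


def aggregate_repeats(per_iteration: Sequence[dict[str, float]] | pd.DataFrame) -> dict[str, float]:
    """Per-case median across repeated iterations (the "median model" view).

    Accepts a list of {case_id: value} dicts (one per iteration) or a long
    DataFrame with columns (iteration, case_id, value). Case ids must align
    across iterations.
    """
    if isinstance(per_iteration, pd.DataFrame):
        frames = [dict(zip(g["case_id"], g["value"]))
                  for _, g in per_iteration.groupby("iteration")]
    else:
        frames = [dict(d) for d in per_iteration]
    if not frames:
        raise ValueError("no iterations provided")
    ids = set(frames[0])
    for f in frames[1:]:
        if set(f) != ids:
            raise ValueError("case ids are misaligned across iterations")
    return {cid: float(np.median([f[cid] for f in frames])) for cid in sorted(ids)}


def significance_stars(p: float) -> str:
    """Figure-caption star coding: thresholds 1e-3, 1e-6, 1e-9, 1e-12."""
    for stars, cut in (("****", 1e-12), ("***", 1e-9), ("**", 1e-6), ("*", 1e-3)):
        if p < cut:
            return stars
    return "ns"
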