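"""Paired significance testing the way segmentation comparisons are reported.

Per-case DSC distributions are compared with two-sided Wilcoxon signed-rank
tests; the significance threshold is Bonferroni-adjusted for the number of
comparisons (alpha/m), and repeated runs are reduced to per-case medians
before testing so data points stay independent.
"""

import numpy as np

from segcurate import (aggregate_repeats, bonferroni_threshold,
                       format_threshold, significance_stars,
                       wilcoxon_signed_rank)

rng = np.random.default_rng(0)
n_cases = 40
baseline = rng.beta(14, 2, size=n_cases)            # skewed, DSC-like
improved = np.clip(baseline + rng.normal(0.012, 0.01, size=n_cases), 0, 1)

w, p = wilcoxon_signed_rank((improved, baseline))
alpha = bonferroni_threshold(0.05, 27)
print(f"Wilcoxon signed-rank: W={w:.0f}, p={p:.2e} {significance_stars(p)}")
print(f"Bonferroni threshold for 27 comparisons: {format_threshold(alpha)}")
print("significant after correction:", p < alpha)

# repeated runs: test medians over iterations, not pooled repeats
runs = [{f"case{i}": float(baseline[i] + rng.normal(0, 0.005))
         for i in range(n_cases)} for _ in range(5)]
medians = aggregate_repeats(runs)
print(f"median-model values cover {len(medians)} cases; "
      f"example: case0 -> {medians['case0']:.3f}")
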