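"""Experiment orchestration: grid enumeration, truth-set hygiene,
cross-validation partitioning and desk-scale pipeline smoke checks."""

import numpy as np
import pandas as pd
import pytest

from segcurate import (CorruptionSpec, ExperimentGrid, SegmenterConfig,
                       build_truth_sets, run_corruption_grid,
                       run_cross_validation, run_curation_matrix,
                       run_rate_sweep, run_repeated_curation, split_cases)
from segcurate.experiments import CONDITIONS, TruthSets, _best_rate


FAST = SegmenterConfig(kind="voxel", epochs=8)


def test_default_grid_enumerates_42_configurations():
    grid = ExperimentGrid()
    configs = grid.enumerate_configs()
    assert len(configs) == 42
    assert len(grid.fractions) == 21
    assert grid.fractions[0] == 0.0 and grid.fractions[-1] == 1.0
    assert set(m for m, _ in configs) == {"systematic_lateral", "random"}
    assert len(set(configs)) == 42            # no collisions


def test_grid_validation():
    with pytest.raises(ValueError):
        ExperimentGrid(fractions=(0.0, 1.5))
    with pytest.raises(ValueError):
        ExperimentGrid(curation_rates=(0.95,))


def test_curation_matrix_has_seven_conditions():
    assert sorted(CONDITIONS) == [1, 2, 3, 4, 5, 6, 7]
    clean = [c for c in CONDITIONS.values() if c[0] == "clean"]
    corrupt = [c for c in CONDITIONS.values() if c[0] == "corrupt"]
    assert len(clean) == 3 and len(corrupt) == 4


def test_truth_sets_construction(tiny_cohort):
    cases, _ = tiny_cohort
    spec = CorruptionSpec(mode="systematic_lateral", magnitude=4, fraction=1.0)
    before = {c.case_id: c.mask.voxels.copy()
              for c in cases if c.split == "test_true"}
    truth = build_truth_sets(cases, spec, seed=3)
    # true-performance masks are bit-identical before/after
    for c in truth.true:
        assert np.array_equal(c.mask.voxels, before[c.case_id])
    # fraction 1 -> every apparent label corrupted
    assert all(c.corrupted for c in truth.apparent)
    zero = build_truth_sets(cases, CorruptionSpec(fraction=0.0), seed=3)
    assert not any(c.corrupted for c in zero.apparent)


def test_truth_sets_with_external_cohort(tiny_cohort, tiny_params):
    from segcurate import shift_distribution
    cases, _ = tiny_cohort
    spec = CorruptionSpec(fraction=0.5, magnitude=4)
    ext_params = shift_distribution(tiny_params, {"radius_mm": 0.5})
    truth = build_truth_sets(cases, spec, seed=1,
                             external_params=ext_params, external_n=3)
    assert len(truth.external) == 3
    assert {c.split for c in truth.external} == {"external"}


def test_cross_validation_partition_and_quartiles(tiny_cohort):
    cases, _ = tiny_cohort
    table = run_cross_validation(cases[:8], k=4, backend_config=FAST, seed=2)
    # every case scored exactly once out-of-fold
    assert sorted(table["case_id"]) == sorted(c.case_id for c in cases[:8])
    assert table["fold"].value_counts().max() == 2
    sizes = table["quartile"].value_counts()
    assert sizes.max() - sizes.min() <= 1
    # Q1 holds the highest agreements
    q1 = table[table["quartile"] == "Q1"]["dsc"].min()
    q4 = table[table["quartile"] == "Q4"]["dsc"].max()
    assert q1 >= q4 - 1e-12
    with pytest.raises(ValueError):
        run_cross_validation(cases[:3], k=9, backend_config=FAST, seed=0)


def test_corruption_grid_desk_scale_smoke(tiny_cohort):
    cases, _ = tiny_cohort
    grid = ExperimentGrid(fractions=(0.0, 1.0), modes=("systematic_lateral",))
    # a converged model is needed for the directional check; with only six
    # training cases that takes a larger epoch budget
    config = SegmenterConfig(kind="voxel", epochs=160)
    table = run_corruption_grid(cases, grid, config, seed=4, magnitude=5)
    assert set(table["fraction"]) == {0.0, 1.0}
    assert set(table["split"]) == {"test_true", "train_dist"}
    # true DSC with fully corrupted training labels drops below the clean run
    med = table[table["split"] == "test_true"].groupby("fraction")["dsc"].median()
    assert med[1.0] < med[0.0]


def test_rate_sweep_structure(tiny_cohort):
    cases, _ = tiny_cohort
    truth = build_truth_sets(cases, CorruptionSpec(fraction=0.0), seed=0)
    table, best = run_rate_sweep(cases, rates=(0.0, 0.3), backend_config=FAST,
                                 seed=5, truth=truth)
    # both arms cover both rates with equal series lengths
    counts = table.groupby(["arm", "rate"]).size()
    assert counts.loc["curation"].tolist() == counts.loc["random_removal"].tolist()
    assert best in (0.0, 0.3)


def test_best_rate_tie_prefers_smaller():
    table = pd.DataFrame([
        {"arm": "curation", "split": "true", "rate": r, "dsc": d}
        for r, d in [(0.0, 0.8), (0.1, 0.9), (0.2, 0.9)]
    ])
    assert _best_rate(table) == 0.1


def test_repeated_curation_folds_and_bonferroni_wiring(tiny_cohort):
    cases, _ = tiny_cohort
    truth = build_truth_sets(cases, CorruptionSpec(fraction=0.0), seed=0)
    out = run_repeated_curation(cases, best_rate=0.3, folds=2,
                                backend_config=FAST, seed=6, truth=truth)
    comps = out["comparisons"]
    assert out["n_comparisons"] == len(comps)
    assert out["alpha_adjusted"] == pytest.approx(0.05 / len(comps))
    # median-model DSC table covers both conditions on the true set
    assert ("curated", "true") in out["median_dsc"]
    assert ("none", "true") in out["median_dsc"]


def test_matrix_desk_scale_with_two_conditions(tiny_cohort):
    cases, _ = tiny_cohort
    rows, summaries = run_curation_matrix(cases, FAST, seed=9, magnitude=5,
                                          folds=1, conditions=(1, 5))
    assert set(rows["condition"]) == {1, 5}
    sens = summaries[summaries["condition"] == 5]["sensitivity"].iloc[0]
    assert sens is None or 0.0 <= sens <= 1.0
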