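"""Seeded, config-driven experiment pipelines over synthetic cohorts.

Four experiment families mirror the study design at desk scale:

* **corruption grid** — train one model per (mode, corruption fraction)
  cell; the default grid of 21 fractions (0–100 % in 5 % steps) times two
  corruption modes enumerates 42 configurations. Each model is scored on
  the clean test split ("true" performance) and against the corrupted
  training labels themselves ("train-distribution" performance), exposing
  how label noise masks its own damage.
* **curation matrix** — the seven-condition comparison: clean baseline,
  clean + random removal, clean + auto-curation, then 30 %-corrupted
  training data (systematic and random) each without and with 30 %
  auto-curation; every condition repeated over seeded folds.
* **rate sweep / RRSS** — auto-curation vs random removal at a range of
  removal rates, scored on true / apparent / external sets; repeated random
  sub-sampling re-runs the sweep on seeded training subsets and reports
  medians (and IQRs for the curation arm) over repeats.
* **repeated curation** — the best-rate condition repeated over folds, with
  per-case median-model metrics and mean-logit ensembles.

Evaluation-set hygiene: "true" test labels are never touched, "apparent"
validation labels are corrupted with the training corruption distribution
under an independent derived seed, and no pipeline ever trains on test or
external cases (every run audits its training ids against them).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .backend import SegmenterConfig, TrainedSegmenter, init_segmenter, train
from .corruption import corrupt_cohort
from .curation import (CurationConfig, curate_and_retrain, ensemble_predict,
                       random_removal)
from .metrics import dsc, evaluate_cohort
from .phantom import PhantomParams, generate_cohort
from .seeds import derive_seed
from .stats import aggregate_repeats, bonferroni_threshold, wilcoxon_signed_rank
from .types import Case, CorruptionSpec

__all__ = [
    "ExperimentGrid", "TruthSets", "split_cases", "build_truth_sets",
    "run_corruption_grid", "run_curation_matrix", "run_rate_sweep",
    "run_rrss", "run_repeated_curation", "run_cross_validation",
    "run_scaled_curation_study",
]

DEFAULT_FRACTIONS = tuple(round(0.05 * i, 2) for i in range(21))   # 0.00 .. 1.00
DEFAULT_RATES = tuple(round(0.05 * i, 2) for i in range(19))       # 0.00 .. 0.90
MODES = ("systematic_lateral", "random")


@dataclass(frozen=True)
class ExperimentGrid:
    """Grid of corruption fractions x modes plus sweep/repeat settings."""

    fractions: tuple[float, ...] = DEFAULT_FRACTIONS
    modes: tuple[str, ...] = MODES
    folds: int = 5
    curation_rates: tuple[float, ...] = DEFAULT_RATES
    rrss_size: int = 100
    rrss_repeats: int = 10

    def __post_init__(self) -> None:
        if any(not 0.0 <= f <= 1.0 for f in self.fractions):
            raise ValueError("corruption fractions must lie in [0, 1]")
        if any(not 0.0 <= r <= 0.9 for r in self.curation_rates):
            raise ValueError("curation rates must lie in [0, 0.9]")

    def enumerate_configs(self) -> list[tuple[str, float]]:
        """All (mode, fraction) cells; the default grid has 42 entries."""
        return [(mode, frac) for mode in self.modes for frac in self.fractions]


@dataclass
class TruthSets:
    """Evaluation sets: clean true-performance test cases, corrupted
    apparent-performance validation cases, and out-of-distribution cases."""

    true: list[Case]
    apparent: list[Case]
    external: list[Case] = field(default_factory=list)


def split_cases(cases: Sequence[Case]) -> dict[str, list[Case]]:
    out: dict[str, list[Case]] = {}
    for c in cases:
        out.setdefault(c.split or "train", []).append(c)
    return out


def _audit_no_leakage(train_cases: Sequence[Case], truth: TruthSets) -> None:
    train_ids = {c.case_id for c in train_cases}
    held = {c.case_id for c in truth.true} | {c.case_id for c in truth.external}
    leaked = train_ids & held
    if leaked:
        raise RuntimeError(f"training on held-out cases: {sorted(leaked)}")


def build_truth_sets(cases: Sequence[Case], spec: CorruptionSpec, seed: int,
                     external_params: PhantomParams | None = None,
                     external_n: int = 0) -> TruthSets:
    """Construct evaluation sets from a cohort with val/test splits.

    True-performance labels are the untouched test_true cases. The apparent
    set corrupts the validation labels with the training corruption mode and
    fraction under an independent derived seed. The external set, if
    requested, is generated from (shifted) phantom parameters.
    """
    by_split = split_cases(cases)
    if "test_true" not in by_split or "val" not in by_split:
        raise ValueError("cohort must provide test_true and val splits")
    apparent_spec = replace(spec, seed=derive_seed(seed, "apparent"))
    apparent, _ = corrupt_cohort(by_split["val"], apparent_spec)
    external: list[Case] = []
    if external_params is not None and external_n > 0:
        external, _ = generate_cohort(external_n, external_params,
                                      derive_seed(seed, "external"),
                                      proportions=(1,), split_names=("external",),
                                      id_prefix="ext")
    return TruthSets(true=list(by_split["test_true"]), apparent=apparent,
                     external=external)


def _train_fresh(cases: Sequence[Case], config: SegmenterConfig, seed: int) -> TrainedSegmenter:
    model = init_segmenter(config, derive_seed(seed, "init"))
    return train(model, list(cases), config.epochs, derive_seed(seed, "train"))


def _dsc_rows(model: TrainedSegmenter, cases: Sequence[Case], **tags) -> list[dict]:
    return [{**tags, "case_id": c.case_id,
             "dsc": dsc(model.predict_mask(c.volume), c.mask)} for c in cases]


def run_corruption_grid(cases: Sequence[Case], grid: ExperimentGrid,
                        backend_config: SegmenterConfig, seed: int,
                        magnitude: int = 10) -> pd.DataFrame:
    """Train/evaluate one model per grid cell with a fixed train/val/test
    allocation shared across all cells. Long-format result rows."""
    by_split = split_cases(cases)
    train_cases, test_cases = by_split["train"], by_split["test_true"]
    rows: list[dict] = []
    for mode, fraction in grid.enumerate_configs():
        spec = CorruptionSpec(mode=mode, magnitude=magnitude, fraction=fraction,
                              seed=derive_seed(seed, "corrupt", mode, fraction))
        corrupted_train, _ids = corrupt_cohort(train_cases, spec)
        model = _train_fresh(corrupted_train, backend_config,
                             derive_seed(seed, "fit", mode, fraction))
        rows += _dsc_rows(model, test_cases, mode=mode, fraction=fraction,
                          split="test_true")
        rows += _dsc_rows(model, corrupted_train, mode=mode, fraction=fraction,
                          split="train_dist")
    return pd.DataFrame(rows)


CONDITIONS = {
    1: ("clean", None, 0.0, "none"),
    2: ("clean", None, 0.30, "random_removal"),
    3: ("clean", None, 0.30, "curation"),
    4: ("corrupt", "systematic_lateral", 0.0, "none"),
    5: ("corrupt", "systematic_lateral", 0.30, "curation"),
    6: ("corrupt", "random", 0.0, "none"),
    7: ("corrupt", "random", 0.30, "curation"),
}


def run_curation_matrix(cases: Sequence[Case], backend_config: SegmenterConfig,
                        seed: int, magnitude: int = 10, folds: int = 5,
                        corruption_fraction: float = 0.30,
                        conditions: Sequence[int] = tuple(CONDITIONS),
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """The seven-condition curation-efficacy comparison, repeated over folds.

    Returns (per-case DSC rows on the clean test split, per-run summary with
    curation sensitivity where ground truth exists).
    """
    by_split = split_cases(cases)
    train_cases, test_cases = by_split["train"], by_split["test_true"]
    truth = TruthSets(true=test_cases, apparent=[])
    rows: list[dict] = []
    summaries: list[dict] = []
    for cond in conditions:
        data_kind, mode, rate, removal = CONDITIONS[cond]
        for fold in range(folds):
            fold_seed = derive_seed(seed, "cond", cond, "fold", fold)
            corrupted_ids: set[str] = set()
            train_pool = list(train_cases)
            if data_kind == "corrupt":
                spec = CorruptionSpec(mode=mode, magnitude=magnitude,
                                      fraction=corruption_fraction,
                                      seed=derive_seed(seed, "corrupt", cond))
                train_pool, corrupted_ids = corrupt_cohort(train_pool, spec)
            sens = None
            if removal == "none":
                _audit_no_leakage(train_pool, truth)
                model = _train_fresh(train_pool, backend_config, fold_seed)
            elif removal == "random_removal":
                kept = random_removal(train_pool, rate,
                                      derive_seed(fold_seed, "rr"))
                _audit_no_leakage(kept, truth)
                model = _train_fresh(kept, backend_config, fold_seed)
            else:
                result = curate_and_retrain(
                    train_pool, backend_config,
                    CurationConfig(removal_rate=rate), seed=fold_seed,
                    corrupted_ids=corrupted_ids or None)
                model, sens = result.model, result.sensitivity
            rows += _dsc_rows(model, test_cases, condition=cond, fold=fold)
            summaries.append({"condition": cond, "fold": fold,
                              "sensitivity": sens,
                              "n_train": len(train_pool)
                              if removal == "none" else
                              len(train_pool) - math.floor(rate * len(train_pool))})
    return pd.DataFrame(rows), pd.DataFrame(summaries)


def _eval_sets(model: TrainedSegmenter, truth: TruthSets, **tags) -> list[dict]:
    rows = []
    for split_name, split_cases_ in (("true", truth.true),
                                     ("apparent", truth.apparent),
                                     ("external", truth.external)):
        if not split_cases_:
            continue
        report = evaluate_cohort(model, split_cases_)
        for rec in report.rows.to_dict("records"):
            rows.append({**tags, "split": split_name, **rec})
    return rows


def run_rate_sweep(cases: Sequence[Case], rates: Sequence[float],
                   backend_config: SegmenterConfig, seed: int,
                   truth: TruthSets) -> tuple[pd.DataFrame, float]:
    """Auto-curation vs random removal across removal rates.

    Returns long-format metric rows and the best rate: the rate maximising
    external-set curation efficacy (curated minus rate-0 baseline median
    DSC), ties toward the smaller rate.
    """
    train_cases = [c for c in cases if (c.split or "train") == "train"]
    rows: list[dict] = []
    for rate in rates:
        rate_seed = derive_seed(seed, "rate", round(rate, 3))
        if rate == 0:
            base = _train_fresh(train_cases, backend_config, rate_seed)
            for arm in ("curation", "random_removal"):
                rows += _eval_sets(base, truth, rate=rate, arm=arm)
            continue
        result = curate_and_retrain(train_cases, backend_config,
                                    CurationConfig(removal_rate=rate),
                                    seed=rate_seed)
        _audit_no_leakage([c for c in train_cases if c.case_id in result.kept_ids], truth)
        rows += _eval_sets(result.model, truth, rate=rate, arm="curation")
        kept = random_removal(train_cases, rate, derive_seed(rate_seed, "rr"))
        model = _train_fresh(kept, backend_config, derive_seed(rate_seed, "rr-fit"))
        rows += _eval_sets(model, truth, rate=rate, arm="random_removal")
    table = pd.DataFrame(rows)
    best_rate = _best_rate(table)
    return table, best_rate


def _best_rate(table: pd.DataFrame) -> float:
    split = "external" if (table["split"] == "external").any() else "true"
    cur = table[(table["arm"] == "curation") & (table["split"] == split)]
    med = cur.groupby("rate")["dsc"].median()
    base = med.get(0.0, med.iloc[0])
    efficacy = med - base
    best = efficacy[efficacy == efficacy.max()]
    return float(min(best.index))


def run_rrss(cases: Sequence[Case], subsample_n: int, repeats: int,
             rates: Sequence[float], backend_config: SegmenterConfig,
             seed: int, truth: TruthSets) -> pd.DataFrame:
    """Repeated random sub-sampling: per-repeat rate sweeps on seeded
    training subsets; reports median over repeats per (rate, arm, split),
    with IQR for the curation arm."""
    train_cases = [c for c in cases if (c.split or "train") == "train"]
    if subsample_n > len(train_cases):
        raise ValueError("subsample larger than the training split")
    all_rows = []
    for rep in range(repeats):
        rng = np.random.default_rng(derive_seed(seed, "rrss", rep))
        idx = rng.choice(len(train_cases), size=subsample_n, replace=False)
        sub = [train_cases[i] for i in sorted(idx)]
        table, _ = run_rate_sweep(sub, rates, backend_config,
                                  derive_seed(seed, "rrss-sweep", rep), truth)
        table["repeat"] = rep
        all_rows.append(table)
    long = pd.concat(all_rows, ignore_index=True)
    per_repeat = (long.groupby(["rate", "arm", "split", "repeat"])["dsc"]
                  .median().reset_index())
    agg = (per_repeat.groupby(["rate", "arm", "split"])["dsc"]
           .agg(median="median",
                iqr_low=lambda v: float(np.percentile(v, 25)),
                iqr_high=lambda v: float(np.percentile(v, 75)))
           .reset_index())
    return agg


def run_repeated_curation(cases: Sequence[Case], best_rate: float, folds: int,
                          backend_config: SegmenterConfig, seed: int,
                          truth: TruthSets) -> dict:
    """Repeat (no-curation, curation at the best rate) over folds.

    Produces per-case median-model DSC for both conditions, ensemble masks
    from mean pre-sigmoid scores, and the Wilcoxon comparison of the two
    median-model distributions on each evaluation set, with the Bonferroni
    threshold for the number of comparisons actually made.
    """
    train_cases = [c for c in cases if (c.split or "train") == "train"]
    models = {"none": [], "curated": []}
    for fold in range(folds):
        fold_seed = derive_seed(seed, "repeat", fold)
        models["none"].append(_train_fresh(train_cases, backend_config, fold_seed))
        result = curate_and_retrain(train_cases, backend_config,
                                    CurationConfig(removal_rate=best_rate),
                                    seed=fold_seed)
        models["curated"].append(result.model)

    eval_sets = [("true", truth.true), ("apparent", truth.apparent),
                 ("external", truth.external)]
    medians: dict[tuple[str, str], dict[str, float]] = {}
    ensembles: dict[tuple[str, str], dict[str, float]] = {}
    for cond, mods in models.items():
        for split_name, split_cases_ in eval_sets:
            if not split_cases_:
                continue
            per_iter = []
            for model in mods:
                per_iter.append({c.case_id: dsc(model.predict_mask(c.volume), c.mask)
                                 for c in split_cases_})
            medians[(cond, split_name)] = aggregate_repeats(per_iter)
            ensembles[(cond, split_name)] = {
                c.case_id: dsc(ensemble_predict(mods, c.volume), c.mask)
                for c in split_cases_}

    comparisons = []
    for split_name, split_cases_ in eval_sets:
        if not split_cases_:
            continue
        for view, store in (("median_model", medians), ("ensemble", ensembles)):
            a = store[("curated", split_name)]
            b = store[("none", split_name)]
            ids = sorted(a)
            try:
                w, p = wilcoxon_signed_rank((np.array([a[i] for i in ids]),
                                             np.array([b[i] for i in ids])))
            except ValueError:
                w, p = float("nan"), float("nan")
            comparisons.append({"split": split_name, "view": view, "W": w, "p": p,
                                "median_delta": float(np.median(
                                    [a[i] - b[i] for i in ids]))})
    m = len(comparisons)
    threshold = bonferroni_threshold(0.05, m) if m else float("nan")
    for comp in comparisons:
        comp["significant"] = bool(comp["p"] < threshold) if np.isfinite(comp["p"]) else False
    return {"median_dsc": medians, "ensemble_dsc": ensembles,
            "comparisons": pd.DataFrame(comparisons),
            "alpha_adjusted": threshold, "n_comparisons": m}


def run_scaled_curation_study(master_seed: int, repeats: int = 5,
                              n_train: int = 60, n_test: int = 20,
                              corruption_fraction: float = 0.30,
                              removal_rate: float = 0.30,
                              target_agreement_dsc: float = 0.78,
                              backend_config: SegmenterConfig | None = None,
                              phantom_params: PhantomParams | None = None,
                              with_retraining: bool = True) -> dict:
    """Desk-scale curation-efficacy study on seeded phantom cohorts.

    For each repeat: generate a fresh cohort (``n_train`` train, ``n_test``
    clean test cases), corrupt 30 % of the training segmentations with
    systematic lateral dilation at a magnitude calibrated so the per-case
    agreement DSC sits near the target, prompt-train for 25 % of epochs,
    rank all training cases by DSC and remove the lowest 30 %; sensitivity
    is the fraction of corrupted cases among the removed. With
    ``with_retraining`` the curated and non-curated models are fully trained
    and compared on the clean test split (the recovery comparison).
    """
    from .corruption import calibrate_magnitude
    from .curation import prompt_train, rank_training_cases

    config = backend_config or SegmenterConfig(kind="voxel", epochs=40)
    params = phantom_params or PhantomParams()
    out: dict = {"repeats": [], "n_train": n_train}
    for rep in range(repeats):
        s = derive_seed(master_seed, "scaled-curation", rep)
        cases, _ = generate_cohort(n_train + n_test, params,
                                   derive_seed(s, "cohort"),
                                   proportions=(n_train, 0, n_test))
        train_cases = [c for c in cases if c.split == "train"]
        test_cases = [c for c in cases if c.split == "test_true"]
        magnitude = calibrate_magnitude(train_cases, target_agreement_dsc,
                                        search_range=range(0, params.margin_voxels))
        spec = CorruptionSpec(mode="systematic_lateral", magnitude=magnitude,
                              fraction=corruption_fraction,
                              seed=derive_seed(s, "corrupt"))
        corrupted_train, corrupted_ids = corrupt_cohort(train_cases, spec)

        prompt = prompt_train(corrupted_train, config, 0.25,
                              seed=derive_seed(s, "prompt"))
        ranking = rank_training_cases(prompt, corrupted_train)
        k = math.floor(removal_rate * len(corrupted_train))
        removed = {cid for cid, _ in ranking[:k]}
        sensitivity = len(removed & corrupted_ids) / len(corrupted_ids)
        rep_result = {"seed": s, "magnitude": magnitude,
                      "median_agreement": float(np.median(
                          [c.record.agreement_dsc for c in corrupted_train
                           if c.corrupted])),
                      "sensitivity": sensitivity}

        if with_retraining:
            kept = [c for c in corrupted_train if c.case_id not in removed]
            curated = _train_fresh(kept, config, derive_seed(s, "curated"))
            noncur = _train_fresh(corrupted_train, config,
                                  derive_seed(s, "noncurated"))
            rep_result["curated_test_dsc"] = float(np.median(
                [dsc(curated.predict_mask(c.volume), c.mask) for c in test_cases]))
            rep_result["noncurated_test_dsc"] = float(np.median(
                [dsc(noncur.predict_mask(c.volume), c.mask) for c in test_cases]))
        out["repeats"].append(rep_result)

    out["median_sensitivity"] = float(np.median(
        [r["sensitivity"] for r in out["repeats"]]))
    if with_retraining:
        out["recovery_wins"] = sum(
            r["curated_test_dsc"] >= r["noncurated_test_dsc"]
            for r in out["repeats"])
    return out


def run_cross_validation(cases: Sequence[Case], k: int,
                         backend_config: SegmenterConfig, seed: int) -> pd.DataFrame:
    """k-fold cross-validation: each case is scored exactly once out-of-fold
    and ranked into agreement quartiles Q1 (highest DSC) .. Q4 (lowest)."""
    cases = list(cases)
    n = len(cases)
    if k < 2 or k > n:
        raise ValueError("need 2 <= k <= number of cases")
    rng = np.random.default_rng(derive_seed(seed, "cv-assign"))
    order = rng.permutation(n)
    fold_of = np.empty(n, dtype=int)
    for pos, idx in enumerate(order):
        fold_of[idx] = pos % k
    rows = []
    for fold in range(k):
        train_pool = [c for c, f in zip(cases, fold_of) if f != fold]
        held = [c for c, f in zip(cases, fold_of) if f == fold]
        model = _train_fresh(train_pool, backend_config, derive_seed(seed, "cv", fold))
        for c in held:
            rows.append({"case_id": c.case_id, "fold": fold,
                         "dsc": dsc(model.predict_mask(c.volume), c.mask)})
    table = pd.DataFrame(rows)
    # quartiles on DSC rank, ties broken by case id (descending DSC first)
    table = table.sort_values(["dsc", "case_id"],
                              ascending=[False, True]).reset_index(drop=True)
    qsize = [n // 4 + (1 if i < n % 4 else 0) for i in range(4)]
    labels = []
    for qi, size in enumerate(qsize, start=1):
        labels += [f"Q{qi}"] * size
    table["quartile"] = labels
    return table.sort_values("case_id").reset_index(drop=True)
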