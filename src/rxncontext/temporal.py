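"""Imbalance statistics, per-year context usage, and temporal validation.

Context usage in ELN-like data drifts over calendar time: new
catalyst/ligand systems enter use and replace older ones. These analyses
quantify that drift (per-year usage matrix) and measure its consequence: a
model trained on years that exclude the test era degrades sharply relative
to one trained on the test era.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .datamodel import Dataset
from .featurize import DEFAULT_FP_CONFIG, featurize_examples
from .models import ModelConfig, predict, train
from .pipeline import (
    DEFAULT_MIN_YIELD,
    CuratedLists,
    LabelSpace,
    filter_and_label,
    variation_context_table,
)
from . import evaluate

logger = logging.getLogger(__name__)

#: MeanIR above this flags a multi-label dataset as imbalanced
#: (Charte et al. criterion).
IMBALANCE_FLAG_THRESHOLD = 1.5


@dataclass
class ImbalanceSummary:
    per_label_ir: dict[int, float]
    mean_ir: float
    var_ir: float
    cv_ir: float
    cardinality: float
    density: float
    imbalanced: bool


def imbalance_summary(multi_table, label_space: LabelSpace) -> ImbalanceSummary:
    """Imbalance ratios, label cardinality and label density.

    IR(λ) = count of the most frequent label / count of λ, over label
    occurrences in the multi-label table; labels with zero count are excluded
    (with a warning). Cardinality is the mean number of set bits per example;
    density is cardinality / number of labels.
    """
    if not multi_table:
        raise ValueError("empty table")
    Y = np.stack([ex.label_vector for ex in multi_table])
    counts = Y.sum(axis=0).astype(float)
    if (counts == 0).any():
        logger.warning(
            "%d label(s) with zero count excluded from IR", int((counts == 0).sum())
        )
    nonzero = counts > 0
    ir = {
        int(i): float(counts.max() / counts[i])
        for i in np.flatnonzero(nonzero)
    }
    values = np.array(list(ir.values()))
    cardinality = float(Y.sum(axis=1).mean())
    density = cardinality / len(label_space)
    return ImbalanceSummary(
        per_label_ir=ir,
        mean_ir=float(values.mean()),
        var_ir=float(values.var(ddof=0)),
        cv_ir=float(values.std(ddof=0) / values.mean()),
        cardinality=cardinality,
        density=density,
        imbalanced=bool(values.mean() > IMBALANCE_FLAG_THRESHOLD),
    )


@dataclass
class YearContextMatrix:
    years: list[int]
    counts: np.ndarray          # |years| x |labels| integers
    relative: np.ndarray        # row-normalized (within-year frequency)
    n_undated: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self.years,
            columns=[f"context_{i}" for i in range(self.counts.shape[1])],
        )


def year_context_matrix(
    ds: Dataset,
    label_space: LabelSpace,
    curated: CuratedLists | None = None,
    min_yield: float = DEFAULT_MIN_YIELD,
) -> YearContextMatrix:
    """Counts of surviving variations per (year, context).

    The relative matrix is normalized within each year, reproducing the
    usual heatmap semantics (brightness = relative frequency of a context in
    that year).
    """
    rows = variation_context_table(ds, curated=curated, min_yield=min_yield)
    rows = [r for r in rows if r[2] in label_space]
    if not rows:
        raise ValueError("no surviving variation falls in the label space")
    years = sorted({year for _, year, _, _ in rows})
    year_index = {y: i for i, y in enumerate(years)}
    counts = np.zeros((len(years), len(label_space)), dtype=int)
    for _, year, key, _ in rows:
        counts[year_index[year], label_space.index(key)] += 1
    totals = counts.sum(axis=1, keepdims=True)
    relative = counts / np.maximum(totals, 1)
    return YearContextMatrix(years=years, counts=counts, relative=relative)


def temporal_experiment(
    ds: Dataset,
    train_ranges: list[tuple[int, int]],
    test_range: tuple[int, int],
    cfg: ModelConfig,
    n_runs: int = 3,
    k: int = 30,
    min_yield: float = DEFAULT_MIN_YIELD,
    curated: CuratedLists | None = None,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Year-ranged retraining: accuracy on a fixed test era per train range.

    The label space is fixed from the full-range data so rows are comparable.
    The split is at the record level using the single-label variation's year:
    a record in the test era never contributes training examples, even when a
    train range overlaps the test era.
    """
    result = filter_and_label(ds, k=k, min_yield=min_yield, curated=curated)
    table = result.single_table
    if not table:
        raise ValueError("no records survive filtering")
    X = featurize_examples(table)
    Y = np.stack([ex.label_vector for ex in table])
    years = np.array([ex.year for ex in table])

    t0, t1 = test_range
    test_mask = (years >= t0) & (years <= t1)
    if not test_mask.any():
        raise ValueError(f"empty test slice {test_range}")
    rows = []
    for (y0, y1) in train_ranges:
        train_mask = (years >= y0) & (years <= y1) & ~test_mask
        if not train_mask.any():
            raise ValueError(f"empty train slice {y0}-{y1}")
        top1_runs, top3_runs = [], []
        for run in range(n_runs):
            run_cfg = replace(cfg, seed=base_seed + 101 * run + cfg.seed)
            bundle = train(
                [table[i] for i in np.flatnonzero(train_mask)],
                X[train_mask],
                run_cfg,
                result.label_space,
                split_seed=base_seed,
                fp_config=DEFAULT_FP_CONFIG,
                validation_fraction=0.0,
            )
            scores = predict(bundle, X[test_mask])
            top1_runs.append(evaluate.topk_accuracy(scores, Y[test_mask], 1))
            top3_runs.append(
                evaluate.topk_accuracy(scores, Y[test_mask],
                                       min(3, Y.shape[1]))
            )
        rows.append({
            "train_range": f"{y0}-{y1}",
            "n_train": int(train_mask.sum()),
            "n_test": int(test_mask.sum()),
            "top1_mean": float(np.mean(top1_runs)),
            "top1_sd": float(np.std(top1_runs, ddof=1)) if n_runs > 1 else 0.0,
            "top3_mean": float(np.mean(top3_runs)),
            "top3_sd": float(np.std(top3_runs, ddof=1)) if n_runs > 1 else 0.0,
        })
        logger.info("train %s-%s: top1=%.3f top3=%.3f", y0, y1,
                    rows[-1]["top1_mean"], rows[-1]["top3_mean"])
    return pd.DataFrame(rows)
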