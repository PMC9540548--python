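"""Metrics and analyses for context-prediction models.

Covers top-k accuracy, label ranking average precision (LRAP),
samples-averaged Jaccard, the multi-label rank curve (rank of the
lowest-scored ground truth divided by the number of ground truths),
per-context sensitivity/specificity, top-k confusion likelihood matrices,
partial-agreement scoring between predicted and true contexts, and
popularity baselines.

Ranking convention everywhere: descending score, ties broken by the lower
label index (label indices are popularity-ordered, so the more popular
context wins a tie).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _stats

from .datamodel import ROLE_BASE, ROLE_CATALYST, ROLE_LIGAND, ROLE_PRECATALYST, ROLE_SOLVENT
from .pipeline import ChemicalContext

DEFAULT_THRESHOLD = 0.5

#: Categories compared by partial agreement; catalyst and pre-catalyst are
#: merged into one category.
AGREEMENT_CATEGORIES = ("catalyst", "ligand", "base", "solvent")


def _check_shapes(scores: np.ndarray, truth: np.ndarray) -> None:
    scores, truth = np.asarray(scores), np.asarray(truth)
    if scores.shape != truth.shape:
        raise ValueError(f"shape mismatch: {scores.shape} vs {truth.shape}")


def _rank_order(scores_row: np.ndarray) -> np.ndarray:
    """Label indices from best to worst rank (ties -> lower index first)."""
    # stable sort on -score keeps lower indices first among ties
    return np.argsort(-scores_row, kind="stable")


def ranks(scores: np.ndarray) -> np.ndarray:
    """1-based rank of every label per row under the ranking convention."""
    scores = np.asarray(scores, dtype=float)
    out = np.empty(scores.shape, dtype=int)
    for i, row in enumerate(scores):
        order = _rank_order(row)
        out[i, order] = np.arange(1, len(row) + 1)
    return out


def topk_accuracy(scores: np.ndarray, truth: np.ndarray, k: int) -> float:
    """Fraction of rows whose (single) true label ranks within the top *k*."""
    _check_shapes(scores, truth)
    scores, truth = np.asarray(scores, float), np.asarray(truth)
    n_labels = scores.shape[1]
    if not (1 <= k <= n_labels):
        raise ValueError(f"k={k} outside [1, {n_labels}]")
    if not np.all(truth.sum(axis=1) == 1):
        raise ValueError("top-k accuracy needs exactly one true label per row")
    true_idx = truth.argmax(axis=1)
    r = ranks(scores)
    true_rank = r[np.arange(len(scores)), true_idx]
    return float((true_rank <= k).mean())


def lrap(scores: np.ndarray, truth: np.ndarray) -> float:
    """Label ranking average precision.

    Per row and true label y: the fraction of labels scored >= score(y) that
    are themselves true; averaged over true labels, then over rows.
    """
    _check_shapes(scores, truth)
    scores = np.asarray(scores, float)
    truth = np.asarray(truth).astype(bool)
    if not truth.any(axis=1).all():
        raise ValueError("every row needs at least one true label")
    row_values = []
    for s, t in zip(scores, truth):
        precisions = []
        for y in np.flatnonzero(t):
            geq = s >= s[y]
            precisions.append(t[geq].sum() / geq.sum())
        row_values.append(np.mean(precisions))
    return float(np.mean(row_values))


def jaccard_samples(
    pred_positive: np.ndarray, truth: np.ndarray
) -> float:
    """Samples-averaged Jaccard: per row |P∩T| / |P∪T| (1 when both empty)."""
    _check_shapes(pred_positive, truth)
    P = np.asarray(pred_positive).astype(bool)
    T = np.asarray(truth).astype(bool)
    inter = (P & T).sum(axis=1)
    union = (P | T).sum(axis=1)
    per_row = np.where(union == 0, 1.0, inter / np.maximum(union, 1))
    return float(per_row.mean())


def threshold_positives(
    scores: np.ndarray, threshold: float = DEFAULT_THRESHOLD
) -> np.ndarray:
    return (np.asarray(scores, float) >= threshold).astype(np.int8)


def rank_curve(
    scores: np.ndarray, truth: np.ndarray, k_max: int | None = None
) -> dict[int, float]:
    """Cumulative fraction of rows whose *effective rank* is <= k.

    The effective rank of a row is the 1-based rank of its lowest-scored true
    label divided by the number of true labels; for single-truth rows the
    curve equals top-k accuracy.
    """
    _check_shapes(scores, truth)
    scores = np.asarray(scores, float)
    truth = np.asarray(truth).astype(bool)
    if not truth.any(axis=1).all():
        raise ValueError("every row needs at least one true label")
    k_max = k_max or scores.shape[1]
    r = ranks(scores)
    effective = np.array([
        r[i, t].max() / t.sum() for i, t in enumerate(truth)
    ])
    return {k: float((effective <= k).mean()) for k in range(1, k_max + 1)}


def sensitivity_specificity(
    scores: np.ndarray,
    truth: np.ndarray,
    positive_rule: str = "top1",
    threshold: float = DEFAULT_THRESHOLD,
) -> list[dict]:
    """Per-context sensitivity and specificity.

    A prediction is positive for context c under ``top1`` (argmax) or
    ``threshold`` (score >= threshold). Contexts with zero support have
    undefined sensitivity, reported as None rather than 0.
    """
    _check_shapes(scores, truth)
    scores = np.asarray(scores, float)
    truth = np.asarray(truth).astype(bool)
    if positive_rule == "top1":
        pred = np.zeros_like(truth)
        pred[np.arange(len(scores)), scores.argmax(axis=1)] = True
    elif positive_rule == "threshold":
        pred = threshold_positives(scores, threshold).astype(bool)
    else:
        raise ValueError(f"unknown positive_rule {positive_rule!r}")
    rows = []
    for c in range(scores.shape[1]):
        tp = int((pred[:, c] & truth[:, c]).sum())
        fn = int((~pred[:, c] & truth[:, c]).sum())
        fp = int((pred[:, c] & ~truth[:, c]).sum())
        tn = int((~pred[:, c] & ~truth[:, c]).sum())
        support = tp + fn
        rows.append({
            "context": c,
            "support": support,
            "sensitivity": tp / support if support else None,
            "specificity": tn / (tn + fp) if (tn + fp) else None,
        })
    return rows


def confusion_likelihood(
    scores: np.ndarray, truth: np.ndarray, k: int = 1
) -> np.ndarray:
    """Likelihood matrix: entry (y, x) = P(x in top-k | ground truth is y).

    Rows with ground truth y are those whose single true label is y; in
    multi-label settings pass the highest-scored truth as the one-hot. Each
    row of the matrix sums to k (for ground truths with support); the
    support-weighted diagonal mean equals the top-k accuracy.
    """
    _check_shapes(scores, truth)
    scores = np.asarray(scores, float)
    truth = np.asarray(truth)
    if not np.all(truth.sum(axis=1) == 1):
        raise ValueError("confusion likelihood needs one true label per row")
    n_labels = scores.shape[1]
    true_idx = truth.argmax(axis=1)
    r = ranks(scores)
    topk = r <= k
    matrix = np.zeros((n_labels, n_labels))
    for y in range(n_labels):
        rows = true_idx == y
        if rows.any():
            matrix[y] = topk[rows].mean(axis=0)
    return matrix


def highest_scored_truth(scores: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """One-hot of the best-ranked true label per row (for multi-label rows)."""
    _check_shapes(scores, truth)
    scores = np.asarray(scores, float)
    truth = np.asarray(truth).astype(bool)
    out = np.zeros(truth.shape, dtype=np.int8)
    r = ranks(scores)
    for i, t in enumerate(truth):
        idx = np.flatnonzero(t)
        out[i, idx[np.argmin(r[i, idx])]] = 1
    return out


def partial_agreement(
    pred_context: ChemicalContext, true_context: ChemicalContext
) -> tuple[float, dict[str, bool]]:
    """Fraction of context categories whose species lists agree exactly.

    Catalyst and pre-catalyst are compared as one merged category; two empty
    lists count as agreement.
    """
    def merged(ctx: ChemicalContext, category: str) -> tuple[str, ...]:
        if category == "catalyst":
            return tuple(sorted(
                set(ctx.species(ROLE_CATALYST)) | set(ctx.species(ROLE_PRECATALYST))
            ))
        role = {"ligand": ROLE_LIGAND, "base": ROLE_BASE,
                "solvent": ROLE_SOLVENT}[category]
        return ctx.species(role)

    flags = {
        cat: merged(pred_context, cat) == merged(true_context, cat)
        for cat in AGREEMENT_CATEGORIES
    }
    score = sum(flags.values()) / len(flags)
    return score, flags


def partial_agreement_analysis(
    scores: np.ndarray,
    truth: np.ndarray,
    contexts_by_index: list[ChemicalContext],
    k: int = 3,
) -> dict:
    """Partial agreement between top-1 prediction and truth on hard rows.

    Considers only rows whose (highest-scored) true label is outside the
    top-*k* predictions, and compares the top-1 predicted context with the
    true context per category. Returns the mean score and per-category
    agreement likelihoods (None if no row qualifies).
    """
    _check_shapes(scores, truth)
    scores = np.asarray(scores, float)
    onehot = highest_scored_truth(scores, truth)
    true_idx = onehot.argmax(axis=1)
    r = ranks(scores)
    true_rank = r[np.arange(len(scores)), true_idx]
    hard = true_rank > k
    pred_idx = scores.argmax(axis=1)
    scores_list, flags_acc = [], {cat: [] for cat in AGREEMENT_CATEGORIES}
    for i in np.flatnonzero(hard):
        s, flags = partial_agreement(
            contexts_by_index[pred_idx[i]], contexts_by_index[true_idx[i]]
        )
        scores_list.append(s)
        for cat, ok in flags.items():
            flags_acc[cat].append(ok)
    if not scores_list:
        return {"n_rows": 0, "mean_score": None,
                "category_likelihood": {c: None for c in AGREEMENT_CATEGORIES}}
    return {
        "n_rows": len(scores_list),
        "mean_score": float(np.mean(scores_list)),
        "category_likelihood": {
            cat: float(np.mean(v)) for cat, v in flags_acc.items()
        },
    }


def popularity_baselines(
    label_counts: np.ndarray, truth: np.ndarray
) -> tuple[float, float]:
    """Top-1/top-3 accuracy of ranking contexts by training popularity."""
    truth = np.asarray(truth)
    counts = np.asarray(label_counts, dtype=float)
    scores = np.tile(counts / max(counts.sum(), 1.0), (truth.shape[0], 1))
    return (
        topk_accuracy(scores, truth, k=1),
        topk_accuracy(scores, truth, k=min(3, truth.shape[1])),
    )


def paired_ttest(a, b) -> tuple[float, float]:
    """Two-sided paired t-test; returns (statistic, p-value)."""
    res = _stats.ttest_rel(np.asarray(a, float), np.asarray(b, float))
    return float(res.statistic), float(res.pvalue)


@dataclass
class EvalReport:
    """All headline metrics for one model on one evaluation table."""

    topk: dict[int, float] = field(default_factory=dict)
    lrap: float | None = None
    jaccard: float | None = None
    rank_curve: dict[int, float] = field(default_factory=dict)
    per_context: list = field(default_factory=list)
    confusion_top1: np.ndarray | None = None
    confusion_top3: np.ndarray | None = None
    agreement: dict = field(default_factory=dict)
    predicted_cardinality: float | None = None

    def to_dict(self) -> dict:
        return {
            "topk": self.topk,
            "lrap": self.lrap,
            "jaccard": self.jaccard,
            "rank_curve": self.rank_curve,
            "per_context": self.per_context,
            "confusion_top1": None if self.confusion_top1 is None
            else self.confusion_top1.tolist(),
            "confusion_top3": None if self.confusion_top3 is None
            else self.confusion_top3.tolist(),
            "agreement": self.agreement,
            "predicted_cardinality": self.predicted_cardinality,
        }


def evaluate_report(
    scores: np.ndarray,
    truth: np.ndarray,
    mode: str,
    contexts_by_index: list[ChemicalContext] | None = None,
    threshold: float = DEFAULT_THRESHOLD,
) -> EvalReport:
    """Assemble the full report for one score/truth pair."""
    scores = np.asarray(scores, float)
    truth = np.asarray(truth)
    report = EvalReport()
    single_truth = bool(np.all(truth.sum(axis=1) == 1))
    onehot = truth if single_truth else highest_scored_truth(scores, truth)
    n_labels = scores.shape[1]
    for k in (1, 3, 5):
        if k <= n_labels:
            report.topk[k] = topk_accuracy(scores, onehot, k)
    report.rank_curve = rank_curve(scores, truth, k_max=min(n_labels, 10))
    if mode == "multi":
        report.lrap = lrap(scores, truth)
        pred = threshold_positives(scores, threshold)
        report.jaccard = jaccard_samples(pred, truth)
        report.predicted_cardinality = float(pred.sum(axis=1).mean())
    rule = "top1" if mode == "single" else "threshold"
    report.per_context = sensitivity_specificity(
        scores, truth, positive_rule=rule, threshold=threshold
    )
    report.confusion_top1 = confusion_likelihood(scores, onehot, k=1)
    if n_labels >= 3:
        report.confusion_top3 = confusion_likelihood(scores, onehot, k=3)
    if contexts_by_index is not None:
        report.agreement = partial_agreement_analysis(
            scores, truth, contexts_by_index, k=3
        )
    return report
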