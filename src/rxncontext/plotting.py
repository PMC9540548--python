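"""Optional plots: context popularity, rank curves, sensitivity bars, drift.

All functions take pre-computed results and write a PNG/SVG; nothing here
recomputes anything.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np


def plot_context_popularity(context_counts: dict[str, int], path: str) -> None:
    """Bar chart of per-context usage counts, most popular first."""
    counts = list(context_counts.values())
    fig, ax = plt.subplots(figsize=(8, 3))
    ax.bar(np.arange(1, len(counts) + 1), counts)
    ax.set_xlabel("context index (by popularity)")
    ax.set_ylabel("variations")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_rank_curves(curves: dict[str, dict[int, float]], path: str) -> None:
    """Cumulative accuracy against rank for one or more models."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for label, curve in curves.items():
        ks = sorted(curve)
        ax.plot(ks, [curve[k] for k in ks], marker="o", label=label)
    ax.set_xlabel("rank k")
    ax.set_ylabel("cumulative accuracy")
    ax.set_ylim(0, 1.02)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_sensitivity_specificity(per_context: list[dict], path: str) -> None:
    """Per-context sensitivity and specificity bars."""
    idx = [row["context"] for row in per_context]
    sens = [row["sensitivity"] if row["sensitivity"] is not None else np.nan
            for row in per_context]
    spec = [row["specificity"] if row["specificity"] is not None else np.nan
            for row in per_context]
    x = np.arange(len(idx))
    fig, ax = plt.subplots(figsize=(8, 3))
    ax.bar(x - 0.2, sens, width=0.4, label="sensitivity")
    ax.bar(x + 0.2, spec, width=0.4, label="specificity")
    ax.set_xlabel("context index")
    ax.set_ylim(0, 1.02)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_year_context_heatmap(matrix, path: str) -> None:
    """Within-year relative context usage over time (drift heatmap)."""
    fig, ax = plt.subplots(figsize=(8, 4))
    im = ax.imshow(matrix.relative.T, aspect="auto", origin="lower",
                   cmap="viridis",
                   extent=(matrix.years[0] - 0.5, matrix.years[-1] + 0.5,
                           -0.5, matrix.counts.shape[1] - 0.5))
    ax.set_xlabel("year")
    ax.set_ylabel("context index")
    fig.colorbar(im, ax=ax, label="relative frequency within year")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
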