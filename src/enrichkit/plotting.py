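"""Publication-style figures for the evaluation pipeline.

All functions write a figure file and return its path; they are thin
matplotlib wrappers and deliberately hold no analysis logic.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .metrics import PROCResult


def plot_proc_curves(results: Mapping[str, PROCResult], path: str | Path) -> Path:
    """Semi-log ROC curves (log10 false-positive axis), one line per label."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for label, res in results.items():
        x = [pt[0] for pt in res.curve]
        y = [pt[1] for pt in res.curve]
        ax.step([x[0]] + x, [0.0] + y, where="post", label=f"{label} (pROC-AUC {res.auc:.2f})")
    ax.set_xlabel("log10(decoy fraction)")
    ax.set_ylabel("fraction of bioactives recovered")
    ax.legend(fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_pair_scatter(
    records: pd.DataFrame,
    value: str,
    path: str | Path,
    role: str | None = None,
    labels: tuple[str, str] = ("first", "second"),
) -> Path:
    """Scatter of a paired quantity (``rank`` or ``score``) between two
    preparations, with the identity line."""
    df = records if role is None else records[records["role"] == role]
    x = df[f"{value}_first"].to_numpy(dtype=float)
    y = df[f"{value}_second"].to_numpy(dtype=float)
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(x, y, s=12, alpha=0.6, edgecolors="none")
    lo = np.nanmin([x.min(), y.min()])
    hi = np.nanmax([x.max(), y.max()])
    ax.plot([lo, hi], [lo, hi], color="grey", lw=0.8, ls="--")
    ax.set_xlabel(f"{value} ({labels[0]})")
    ax.set_ylabel(f"{value} ({labels[1]})")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_pair_box(
    records: pd.DataFrame,
    value: str,
    path: str | Path,
    role: str | None = None,
    labels: tuple[str, str] = ("first", "second"),
) -> Path:
    """Side-by-side box plot of a quantity under the two preparations."""
    df = records if role is None else records[records["role"] == role]
    data = [
        df[f"{value}_first"].dropna().to_numpy(dtype=float),
        df[f"{value}_second"].dropna().to_numpy(dtype=float),
    ]
    fig, ax = plt.subplots(figsize=(3.5, 4))
    ax.boxplot(data, tick_labels=list(labels))
    ax.set_ylabel(value)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_score_vs_nha(
    scores: Sequence[float],
    nha: Sequence[int],
    path: str | Path,
    normalized_scores: Sequence[float] | None = None,
) -> Path:
    """Score against heavy-atom count, optionally alongside the normalized
    score with its mean line (size-bias diagnostic)."""
    ncols = 2 if normalized_scores is not None else 1
    fig, axes = plt.subplots(1, ncols, figsize=(4.5 * ncols, 4), squeeze=False)
    axes[0][0].scatter(nha, scores, s=14, alpha=0.7, edgecolors="none")
    axes[0][0].set_xlabel("heavy atoms (N)")
    axes[0][0].set_ylabel("score")
    if normalized_scores is not None:
        ax = axes[0][1]
        ax.scatter(nha, normalized_scores, s=14, alpha=0.7, edgecolors="none")
        ax.axhline(float(np.mean(normalized_scores)), color="grey", ls="--", lw=0.8)
        ax.set_xlabel("heavy atoms (N)")
        ax.set_ylabel("normalized score")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_delta_vs_mean_nha(
    mean_nha: Sequence[float],
    deltas: Sequence[float],
    path: str | Path,
    margin: float = 0.05,
    labels: Sequence[str] | None = None,
) -> Path:
    """Normalization delta per benchmark against bioactive-set mean NHA,
    with the non-significance band shaded."""
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.axhspan(-margin, margin, color="lightgrey", alpha=0.6)
    ax.axhline(0.0, color="grey", lw=0.6)
    ax.scatter(mean_nha, deltas, s=20)
    if labels is not None:
        for x, y, lab in zip(mean_nha, deltas, labels):
            ax.annotate(lab, (x, y), fontsize=6, xytext=(2, 2), textcoords="offset points")
    ax.set_xlabel("mean heavy atoms of bioactive set")
    ax.set_ylabel("Delta pROC-AUC (normalized - original)")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_grid(cells: Mapping[tuple, float], path: str | Path) -> Path:
    """Eight-point match/mismatch layout: AUC per (target, bioactives,
    decoys) preparation combination."""
    keys = sorted(cells)
    fig, ax = plt.subplots(figsize=(6.5, 4))
    xs = np.arange(len(keys))
    ax.scatter(xs, [cells[k] for k in keys], marker="x", s=60)
    ax.set_xticks(xs)
    ax.set_xticklabels(["/".join(k) for k in keys], rotation=45, ha="right", fontsize=7)
    ax.set_ylabel("pROC-AUC")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
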