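"""Static figures: thresholded t-maps, similarity and confusion heatmaps."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .classify import ClassificationReport
from .similarity import SimilarityMatrix
from .stats import GroupMap
from .template import BodyTemplate


def plot_group_map(gm: GroupMap, template: BodyTemplate, path: str | Path) -> None:
    """Render a thresholded t-map: warm colours = significant activation,
    cool = significant deactivation, non-significant pixels transparent
    over the silhouette outline."""
    shown = np.where(gm.sig_mask, gm.t, np.nan)
    vmax = np.nanmax(np.abs(shown)) if gm.sig_mask.any() else 1.0
    fig, ax = plt.subplots(figsize=(3, 5))
    ax.imshow(template.mask, cmap="gray_r", alpha=0.15, interpolation="nearest")
    im = ax.imshow(shown, cmap="RdBu_r", vmin=-vmax, vmax=vmax, interpolation="nearest")
    ax.set_title(f"{gm.stimulus}\n(n={gm.n_subjects}, FDR α={gm.alpha})", fontsize=9)
    ax.axis("off")
    fig.colorbar(im, ax=ax, shrink=0.7, label="t")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def plot_similarity(sim: SimilarityMatrix, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(8, 7))
    im = ax.imshow(sim.r, cmap="RdBu_r", vmin=-1, vmax=1)
    ax.set_xticks(range(len(sim.labels)), sim.labels, rotation=90, fontsize=7)
    ax.set_yticks(range(len(sim.labels)), sim.labels, fontsize=7)
    fig.colorbar(im, ax=ax, label="Spearman r")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def plot_confusion(report: ClassificationReport, path: str | Path) -> None:
    """Confusion heatmap with below-chance cells blanked."""
    shown = np.where(report.confusion_pct >= report.chance, report.confusion_pct, np.nan)
    fig, ax = plt.subplots(figsize=(8, 7))
    im = ax.imshow(shown, cmap="viridis", vmin=0)
    ax.set_xticks(range(len(report.labels)), report.labels, rotation=90, fontsize=7)
    ax.set_yticks(range(len(report.labels)), report.labels, fontsize=7)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    ax.set_title(
        f"mean accuracy {report.mean_accuracy:.2f}% "
        f"(chance {report.chance:.1f}%)", fontsize=9
    )
    fig.colorbar(im, ax=ax, label="% of true class")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
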