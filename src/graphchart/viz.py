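"""Publication-style plots: graph chart diagrams and ROC curves."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .geometry import GraphChartDiagram, assign_plane_markers
from .model import PROXY_TARGETS

__all__ = ["plot_diagram", "plot_diagram_panel", "plot_roc"]

_MARKER_STYLE = {
    "FOUR_CV": dict(marker="D", color="tab:blue", s=45, zorder=3, label="4CV"),
    "THREE_VTV": dict(marker="s", color="tab:red", s=45, zorder=3, label="3VTV"),
}


def _draw(ax, diagram: GraphChartDiagram, marker_threshold: float | None = 0.15):
    pts = diagram.points
    ax.plot(pts[:, 0], pts[:, 1], "-", color="0.6", lw=0.8, zorder=1)
    ax.scatter(pts[:, 0], pts[:, 1], s=18, color="0.45", zorder=2)
    if marker_threshold is not None:
        if diagram.plane_markers is None:
            assign_plane_markers(diagram, marker_threshold)
        for plane, style in _MARKER_STYLE.items():
            mask = np.array(diagram.plane_markers) == plane
            if mask.any():
                ax.scatter(pts[mask, 0], pts[mask, 1], **style)
    for plane, (tx, ty) in PROXY_TARGETS.items():
        ax.scatter([tx], [ty], marker="*", s=120, color=_MARKER_STYLE[plane]["color"],
                   alpha=0.4, zorder=0)
    ax.set_xlabel("neuron 1")
    ax.set_ylabel("neuron 2")
    ax.set_title(f"{diagram.level} — {diagram.video_id}", fontsize=9)
    ax.set_aspect("equal", adjustable="datalim")


def plot_diagram(
    diagram: GraphChartDiagram,
    path: str | Path | None = None,
    marker_threshold: float | None = 0.15,
):
    """Render one diagram: grey connected dots, 4CV/3VTV proxy markers."""
    fig, ax = plt.subplots(figsize=(4, 4))
    _draw(ax, diagram, marker_threshold)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_diagram_panel(
    diagrams: dict[str, GraphChartDiagram],
    path: str | Path | None = None,
    marker_threshold: float | None = 0.15,
):
    """Main + sub diagrams of one video side by side."""
    order = [k for k in ("main", "sub_vessels", "sub_heart") if k in diagrams]
    fig, axes = plt.subplots(1, len(order), figsize=(4 * len(order), 4))
    axes = np.atleast_1d(axes)
    for ax, level in zip(axes, order):
        _draw(ax, diagrams[level], marker_threshold if level == "main" else None)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_roc(results: dict[str, "ROCResult"], path: str | Path | None = None):
    """Overlayed ROC curves, AUC in the legend."""
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    for name, res in results.items():
        ax.plot(res.fpr, res.tpr, label=f"{name} (AUC={res.auc:.3f})")
    ax.plot([0, 1], [0, 1], "--", color="0.7", lw=0.8)
    ax.set_xlabel("FPR")
    ax.set_ylabel("TPR")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
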