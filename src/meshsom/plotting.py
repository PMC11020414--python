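"""Convenience plots: cluster scatter with normal ellipses, node densities.

A thin layer over matplotlib for quick visual inspection of projections;
the tabular exports are the canonical outputs.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .projection import ClusterModel, ProjectionResult

__all__ = ["plot_clusters", "plot_density"]


def _ellipse_xy(mean, cov, scale, n=200):
    theta = np.linspace(0, 2 * np.pi, n)
    circle = np.column_stack([np.cos(theta), np.sin(theta)])
    vals, vecs = np.linalg.eigh(cov)
    axes = vecs @ np.diag(np.sqrt(np.maximum(vals, 0.0)))
    return mean + scale * circle @ axes.T


def plot_clusters(
    projection: ProjectionResult,
    model: ClusterModel,
    path: str | Path,
    title: str | None = None,
) -> None:
    """Scatter of projected articles colored by cluster, ellipses overlaid."""
    fig, ax = plt.subplots(figsize=(6, 6))
    pts = projection.points()
    cmap = plt.get_cmap("tab10")
    for c in range(model.k):
        idx = model.labels == c
        ax.scatter(pts[idx, 1], pts[idx, 0], s=8, alpha=0.6,
                   color=cmap(c % 10), label=f"cluster {c}")
    for c, ell in enumerate(model.ellipses):
        mean, cov, scale = ell
        if np.all(np.isfinite(cov)):
            xy = _ellipse_xy(mean, cov, scale)
            ax.plot(xy[:, 1], xy[:, 0], color=cmap(c % 10), lw=1.5)
    ax.set_xlabel("grid column")
    ax.set_ylabel("grid row")
    ax.invert_yaxis()
    ax.legend(fontsize=8)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_density(projection: ProjectionResult, path: str | Path) -> None:
    """Heat map of per-node projected article counts."""
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(projection.density, cmap="viridis")
    fig.colorbar(im, ax=ax, label="articles per node")
    ax.set_xlabel("grid column")
    ax.set_ylabel("grid row")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
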