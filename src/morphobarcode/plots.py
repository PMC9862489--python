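"""Figure helpers for the pipeline reports.

All functions write PNG files and return the path; they use the Agg
backend so they run headless.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from scipy.spatial import ConvexHull

from .gpa import ShapeAlignment
from .shapes import AllometryResult, DiscriminantResult

# wireframe connecting wing landmarks in template order (outline + inner veins)
_WIREFRAME = [list(range(12)) + [0], [12, 13, 14, 15, 16, 17, 12]]


def plot_mean_shapes(alignment: ShapeAlignment, path: str | Path) -> Path:
    """Superimposed per-species mean-shape wireframes."""
    path = Path(path)
    labels = sorted(set(alignment.species_labels))
    fig, ax = plt.subplots(figsize=(7, 4))
    cmap = plt.get_cmap("tab10")
    lab_arr = np.asarray(alignment.species_labels)
    for i, lab in enumerate(labels):
        mean = alignment.aligned[lab_arr == lab].mean(axis=0)
        for chain in _WIREFRAME:
            if max(chain) < mean.shape[0]:
                ax.plot(mean[chain, 0], mean[chain, 1], "-o", ms=2.5, lw=1,
                        color=cmap(i % 10), label=lab if chain is _WIREFRAME[0] else None)
    ax.set_aspect("equal")
    ax.legend(fontsize=8)
    ax.set_title("Superimposed mean shapes")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_discriminant_space(
    disc: DiscriminantResult, labels: list[str], path: str | Path
) -> Path:
    """First two canonical axes with per-group convex-hull polygons."""
    path = Path(path)
    scores = disc.canonical_scores
    fig, ax = plt.subplots(figsize=(6, 5))
    cmap = plt.get_cmap("tab10")
    lab_arr = np.asarray(labels)
    y = scores[:, 1] if scores.shape[1] > 1 else np.zeros(len(scores))
    for i, lab in enumerate(disc.group_labels):
        pts = np.column_stack([scores[lab_arr == lab, 0], y[lab_arr == lab]])
        ax.scatter(pts[:, 0], pts[:, 1], s=12, color=cmap(i % 10), label=lab)
        if len(pts) >= 3 and scores.shape[1] > 1:
            hull = ConvexHull(pts)
            poly = pts[np.append(hull.vertices, hull.vertices[0])]
            ax.plot(poly[:, 0], poly[:, 1], color=cmap(i % 10), lw=1, alpha=0.7)
    ax.set_xlabel("Canonical axis 1")
    ax.set_ylabel("Canonical axis 2")
    ax.legend(fontsize=8)
    ax.set_title("Discriminant space")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_allometry(
    scores_axis1: np.ndarray,
    sizes: np.ndarray,
    result: AllometryResult,
    path: str | Path,
) -> Path:
    """Scatter of the first canonical axis against centroid size."""
    path = Path(path)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(sizes, scores_axis1, s=12, alpha=0.7)
    xs = np.linspace(sizes.min(), sizes.max(), 50)
    b = result.slope
    a = scores_axis1.mean() - b * sizes.mean()
    ax.plot(xs, a + b * xs, "--", color="darkorange")
    ax.set_xlabel("Centroid size")
    ax.set_ylabel("Wing shape (discriminant factor)")
    ax.set_title(f"Allometry: r$^2$ = {result.r_squared:.2f}, p = {result.p_value:.4g}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
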