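"""Clinician-facing figures.

Two renderings are produced, both from exported data products rather than
live model calls, so figures can be regenerated without the predictor:

* an occlusion overlay — the signal trace over per-window background bands
  whose intensity is proportional to the occlusion-induced MAE, with the
  maximal windows marked; and
* the SOM E-matrix heatmap (hexagonal or rectangular layout), optionally
  with a close-up of the sub-signals mapped to the most active neuron.
"""

from __future__ import annotations

from typing import List, Optional, Sequence, Tuple

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.patches import RegularPolygon

from .core import ShapeError, SubSignal, n_windows, segment
from .som import EMatrix, SOMGrid, unit_members

__all__ = ["argmax_markers", "render_occlusion_overlay", "render_som_heatmap"]


def argmax_markers(window_scores: Sequence[float]) -> List[int]:
    """Indices of all windows attaining the maximal score (none if all zero)."""
    scores = np.asarray(window_scores, dtype=float)
    if scores.size == 0:
        return []
    top = scores.max()
    if top <= 0 and np.allclose(scores, 0):
        return []
    return [int(i) for i in np.flatnonzero(scores == top)]


def render_occlusion_overlay(
    series: np.ndarray,
    window_scores: Sequence[float],
    d: int,
    out_path,
    cmap: str = "Reds",
    figsize: Tuple[float, float] = (10, 3),
    title: Optional[str] = None,
) -> List[int]:
    """Signal trace over per-window shaded bands; returns the marked windows.

    Band intensity is min-max scaled over the score vector; the argmax
    windows are marked with triangles above the trace.
    """
    series = np.asarray(series, dtype=float)
    scores = np.asarray(window_scores, dtype=float)
    h = series.size
    if scores.size != n_windows(h, d):
        raise ShapeError(
            f"expected {n_windows(h, d)} window scores for h={h}, d={d}, got {scores.size}"
        )
    windows = segment(h, d)
    lo, hi = scores.min(), scores.max()
    span = hi - lo
    colors = plt.get_cmap(cmap)
    fig, ax = plt.subplots(figsize=figsize)
    for (a, b), sc in zip(windows, scores):
        intensity = 0.0 if span == 0 else (sc - lo) / span
        ax.axvspan(a, b, color=colors(intensity), alpha=0.6, lw=0)
    ax.plot(np.arange(h), series, color="black", lw=0.9)
    markers = argmax_markers(scores)
    y_top = series.max() + 0.05 * (series.max() - series.min() + 1e-12)
    for m in markers:
        a, b = windows[m]
        ax.plot((a + b) / 2, y_top, marker="v", color="red", markersize=9)
    sm = plt.cm.ScalarMappable(cmap=colors, norm=plt.Normalize(lo, hi))
    fig.colorbar(sm, ax=ax, label="window MAE")
    ax.set_xlabel("timestep")
    ax.set_ylabel("signal")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(out_path)
    plt.close(fig)
    return markers


def render_som_heatmap(
    E: EMatrix,
    som: SOMGrid,
    out_path,
    G: Optional[Sequence[SubSignal]] = None,
    with_prototypes: bool = False,
    cmap: str = "viridis",
    figsize: Tuple[float, float] = (10, 6),
) -> None:
    """Heatmap of the E-matrix on the map lattice.

    With ``with_prototypes`` (requires ``G``), adds an inset plotting the
    member sub-signals of the maximal cell.
    """
    import warnings

    rows, cols = E.shape
    if (rows, cols) != (som.config.rows, som.config.cols):
        raise ShapeError(f"E shape {E.shape} != grid ({som.config.rows}, {som.config.cols})")
    if E.counts.sum() == 0:
        warnings.warn("empty E-matrix: rendering a blank grid")

    coords = som.grid_coordinates()
    vals = E.values
    lo, hi = float(vals.min()), float(vals.max())
    norm = plt.Normalize(lo, hi if hi > lo else lo + 1)
    colors = plt.get_cmap(cmap)

    ncols = 2 if with_prototypes else 1
    fig, axes = plt.subplots(1, ncols, figsize=figsize)
    ax = axes[0] if with_prototypes else axes
    hexagonal = som.config.topology == "hexagonal"
    radius = 1 / np.sqrt(3) if hexagonal else 0.5
    for u in range(rows):
        for v in range(cols):
            x, y = coords[u, v]
            if hexagonal:
                patch = RegularPolygon(
                    (x, y), numVertices=6, radius=radius, orientation=0,
                    facecolor=colors(norm(vals[u, v])), edgecolor="white", lw=0.4,
                )
            else:
                patch = plt.Rectangle(
                    (x - 0.5, y - 0.5), 1, 1,
                    facecolor=colors(norm(vals[u, v])), edgecolor="white", lw=0.4,
                )
            ax.add_patch(patch)
    ax.set_xlim(-1, cols + 1)
    ax.set_ylim(-1, rows * (np.sqrt(3) / 2 if hexagonal else 1) + 1)
    ax.set_aspect("equal")
    ax.invert_yaxis()
    ax.set_xticks([])
    ax.set_yticks([])
    sm = plt.cm.ScalarMappable(cmap=colors, norm=norm)
    fig.colorbar(sm, ax=ax, label="mean influence (E)", shrink=0.8)
    ax.set_title("E-matrix")

    if with_prototypes:
        if G is None:
            raise ValueError("with_prototypes requires the sub-signal set G")
        ax2 = axes[1]
        cell = np.unravel_index(int(np.argmax(vals)), vals.shape)
        members = unit_members(som, list(G), (int(cell[0]), int(cell[1])))
        for s in members:
            ax2.plot(s.values, alpha=0.6, lw=0.8)
        ax2.set_title(f"members of most active neuron {tuple(int(c) for c in cell)}")
        ax2.set_xlabel("timestep (within window)")
    fig.tight_layout()
    fig.savefig(out_path)
    plt.close(fig)
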