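"""Figure generation for simulation results.

All functions take results or model objects and return the matplotlib Figure
(also saving to a path when given), so they work headless and in notebooks.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .model import CA1Model
from .protocols import CFResult, LifelongResult

__all__ = [
    "recognition_bars",
    "weight_mosaic",
    "label_map",
    "activation_heatmaps",
    "peak_scatter",
]


def _finish(fig, out: str | Path | None):
    fig.tight_layout()
    if out is not None:
        fig.savefig(out, dpi=120)
    return fig


def recognition_bars(result: CFResult, out: str | Path | None = None, title: str = ""):
    """Per-task recognition bar chart with sd whiskers, one bar per learning
    position (position 1 = first-learned task)."""
    mean, sd = result.per_task_mean, result.per_task_sd
    x = np.arange(1, len(mean) + 1)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(x, mean, yerr=sd, capsize=3, color="tab:blue")
    ax.set_xlabel("task (learning position)")
    ax.set_ylabel("recognition (%)")
    ax.set_ylim(0, 105)
    ax.set_xticks(x)
    if title:
        ax.set_title(title)
    return _finish(fig, out)


def weight_mosaic(model: CA1Model, out: str | Path | None = None):
    """All input-weight vectors as one tile per pyramidal neuron, arranged
    on the neural map: the network's memory content."""
    g = model.params.geometry
    side = g.input_rows
    mosaic = np.zeros((g.p_rows * side, g.p_cols * side))
    w = model.weights.w_inp
    lo, hi = w.min(), w.max()
    span = (hi - lo) or 1.0
    for n in range(g.n_pyramidal):
        r, c = divmod(n, g.p_cols)
        tile = (w[n].reshape(side, g.input_cols) - lo) / span
        mosaic[r * side:(r + 1) * side, c * side:(c + 1) * side] = tile
    fig, ax = plt.subplots(figsize=(8, 8))
    ax.imshow(mosaic, cmap="gray", interpolation="nearest")
    ax.set_title("input weights per pyramidal neuron")
    ax.axis("off")
    return _finish(fig, out)


def label_map(model: CA1Model, out: str | Path | None = None, dominant: bool = False):
    """Task label of each pyramidal neuron on the neural map (-1 = never
    learned, shown black)."""
    g = model.params.geometry
    labels = (
        model.trace.dominant_labels() if dominant else model.trace.labels
    ).reshape(g.p_rows, g.p_cols)
    fig, ax = plt.subplots(figsize=(6, 6))
    cmap = plt.get_cmap("tab10").copy()
    cmap.set_under("black")
    im = ax.imshow(labels, cmap=cmap, vmin=-0.5, vmax=9.5, interpolation="nearest")
    fig.colorbar(im, ax=ax, label="task")
    ax.set_title("neuron task labels")
    return _finish(fig, out)


def activation_heatmaps(
    model: CA1Model, stimulus: np.ndarray, out: str | Path | None = None
):
    """Stimulus, settled pyramidal activation, interneuron activation, and
    the peak neuron's input weights, side by side."""
    g = model.params.geometry
    model.settle(stimulus)
    peak = model.peak_neuron
    panels = [
        (np.asarray(stimulus).reshape(g.input_rows, g.input_cols), "stimulus", "gray"),
        (model.state.a_p.reshape(g.p_rows, g.p_cols), "pyramidal activation", "Reds"),
        (model.state.a_i.reshape(g.i_rows, g.i_cols), "interneuron activation", "Blues"),
        (model.weights.w_inp[peak].reshape(g.input_rows, g.input_cols),
         f"weights of peak neuron {peak}", "gray"),
    ]
    fig, axes = plt.subplots(1, 4, figsize=(14, 3.6))
    for ax, (img, title, cmap) in zip(axes, panels):
        ax.imshow(img, cmap=cmap, interpolation="nearest")
        ax.set_title(title, fontsize=9)
        ax.axis("off")
    return _finish(fig, out)


def peak_scatter(
    result: LifelongResult,
    geometry_cols: int,
    out: str | Path | None = None,
    epochs: list[int] | None = None,
):
    """Peak-neuron positions on the neural map per epoch: squares for
    corridor 1 images, circles for corridor 2; winners shared by two or more
    images drawn red."""
    chosen = epochs if epochs is not None else range(len(result.peak_maps))
    chosen = [e for e in chosen if e < len(result.peak_maps)]
    fig, axes = plt.subplots(1, max(len(chosen), 1), figsize=(4 * max(len(chosen), 1), 4),
                             squeeze=False)
    for ax, e in zip(axes[0], chosen):
        pm = result.peak_maps[e]
        counts: dict[int, int] = {}
        for peak in pm.values():
            counts[peak] = counts.get(peak, 0) + 1
        corridor = result.corridor_per_epoch[e]
        marker = "s" if corridor == 0 else "o"
        for image_id, peak in pm.items():
            r, c = divmod(int(peak), geometry_cols)
            color = "red" if counts[peak] > 1 else "tab:blue"
            ax.scatter(c, r, marker=marker, s=60, facecolors="none", edgecolors=color)
        ax.set_title(f"epoch {e + 1} (corridor {corridor + 1})", fontsize=9)
        ax.set_xlim(-1, geometry_cols)
        ax.set_ylim(geometry_cols, -1)
        ax.set_aspect("equal")
    return _finish(fig, out)
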