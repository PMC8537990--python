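"""Plots: partition-ordered distance heatmaps and activity-timeline rasters."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from matplotlib.colors import ListedColormap
from matplotlib.patches import Rectangle

from .io_preprocess import IDLE, DailyActivityVector
from .metrics import DistanceMatrix

__all__ = ["plot_distance_heatmap", "plot_activity_raster", "activity_colors"]


def _annot(value: float) -> str:
    # values annotated in thousands, round-half-even
    return str(int(round(value / 1000.0)))


def plot_distance_heatmap(D: DistanceMatrix, boundaries: Sequence[int] = (),
                          path: str | Path = "heatmap.png",
                          annotate: bool = True, dpi: int = 120) -> Path:
    """Heatmap of a (reordered) distance matrix, red = low, green = high.

    Cell values are annotated in thousands; *boundaries* (from
    :func:`adlseq.clustering.reorder`) frame the within-partition blocks.
    """
    if D.n == 0:
        raise ValueError("cannot plot an empty distance matrix")
    m = D.n
    fig, ax = plt.subplots(figsize=(max(4.0, 0.33 * m), max(3.5, 0.33 * m)))
    ax.imshow(D.matrix, cmap="RdYlGn", interpolation="nearest")
    ax.set_xticks(range(m), labels=[str(l) for l in D.labels], fontsize=6, rotation=90)
    ax.set_yticks(range(m), labels=[str(l) for l in D.labels], fontsize=6)
    if annotate and m <= 40:
        for i in range(m):
            for j in range(m):
                ax.text(j, i, _annot(D.matrix[i, j]), ha="center", va="center", fontsize=5)
    edges = [0, *boundaries, m]
    for lo, hi in zip(edges[:-1], edges[1:]):
        ax.add_patch(Rectangle((lo - 0.5, lo - 0.5), hi - lo, hi - lo,
                               fill=False, edgecolor="black", linewidth=2.0))
    ax.set_title(f"{D.metric} distance matrix")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=dpi)
    plt.close(fig)
    return path


def activity_colors(alphabet: Sequence[str]) -> dict[str, tuple]:
    """Fixed activity -> RGBA mapping by sorted label order (reproducible)."""
    labels = sorted(set(alphabet))
    cmap = plt.get_cmap("tab20")
    colors = {}
    idx = 0
    for lab in labels:
        if lab == IDLE:
            colors[lab] = (0.85, 0.92, 1.0, 1.0)  # light blue for idle
        else:
            colors[lab] = cmap(idx % 20)
            idx += 1
    return colors


def plot_activity_raster(days: Sequence[DailyActivityVector],
                         path: str | Path = "raster.png",
                         order: str = "consecutive",
                         partitioning=None,
                         alphabet: Sequence[str] | None = None,
                         dpi: int = 120) -> Path:
    """One row per day, colored by activity; concurrency as a split band.

    Each day is drawn as two half-height pixel rows: identical for a
    single activity, differing where a second concurrent activity runs.
    ``order="partitioned"`` requires *partitioning* and groups the rows by
    partition with separator lines.
    """
    if order not in ("consecutive", "partitioned"):
        raise ValueError(f"unknown order {order!r}")
    if order == "partitioned" and partitioning is None:
        raise ValueError("partitioned order requires a partitioning")
    if alphabet is None:
        alphabet = sorted({a for d in days for s in set(d.slots.tolist()) for a in s})
    colors = activity_colors(alphabet)

    if order == "partitioned":
        by_day = {d.day_index: d for d in days}
        ordered, seps = [], []
        for pid in range(partitioning.k):
            ordered.extend(by_day[lab] for lab in by_day
                           if partitioning.assignment[lab] == pid)
            seps.append(len(ordered))
        seps = seps[:-1]
    else:
        ordered, seps = list(days), []

    n = len(ordered[0].slots)
    img = np.zeros((2 * len(ordered), n, 4))
    for r, day in enumerate(ordered):
        slots = day.slots
        start, prev = 0, slots[0]
        for i in range(1, n + 1):  # run-length fill: equal stretches share colors
            if i < n and (slots[i] is prev or slots[i] == prev):
                continue
            members = sorted(prev)
            for a in members:
                if a not in colors:
                    raise ValueError(f"unknown activity label {a!r}")
            img[2 * r, start:i] = colors[members[0]]
            img[2 * r + 1, start:i] = colors[members[-1]]
            if i < n:
                start, prev = i, slots[i]

    fig, ax = plt.subplots(figsize=(10, max(2.0, 0.28 * len(ordered))))
    ax.imshow(img, aspect="auto", interpolation="nearest",
              extent=(0, n, len(ordered), 0))
    for sep in seps:
        ax.axhline(sep, color="black", linewidth=1.5)
    ax.set_yticks(np.arange(len(ordered)) + 0.5,
                  labels=[str(d.day_index) for d in ordered], fontsize=6)
    ax.set_xlabel("seconds since day start (04:00)")
    ax.set_ylabel("day")
    handles = [plt.Line2D([], [], marker="s", linestyle="", color=colors[a], label=a)
               for a in sorted(colors)]
    ax.legend(handles=handles, loc="center left", bbox_to_anchor=(1.01, 0.5), fontsize=6)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=dpi)
    plt.close(fig)
    return path
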