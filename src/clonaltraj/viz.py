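"""Plots: lineage dynamics, diversity profiles, clusters and consensus curves.

Every figure is written together with a tidy companion table holding exactly
the plotted values, so downstream checks assert on data, never on pixels.
Log-scale dynamics plots substitute the detection floor for zero
frequencies; the stored plot data records the floored values actually drawn.
"""

from __future__ import annotations

import os

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .clustering import ClonalClusterSet
from .core import FrequencyMatrix
from .diversity import DiversityProfile

__all__ = ["plot_dynamics", "plot_diversity", "plot_clusters"]


def _companion(path: str | os.PathLike) -> str:
    root, _ = os.path.splitext(os.fspath(path))
    return root + ".csv"


def plot_dynamics(
    fm: FrequencyMatrix,
    path: str | os.PathLike,
    scale: str = "log",
    clusters: ClonalClusterSet | None = None,
    coloring: str = "none",
) -> pd.DataFrame:
    """One line per barcode over time, on log or linear frequency scale.

    ``coloring`` is ``"none"`` or ``"by_cluster"``/``"by_rank"`` (both need
    ``clusters``). Returns the plotted table (also written next to the image).
    """
    if fm.n_barcodes == 0:
        raise ValueError("cannot plot an empty frequency matrix")
    if scale not in ("log", "linear"):
        raise ValueError(f"unknown scale {scale!r}")
    if coloring not in ("none", "by_cluster", "by_rank"):
        raise ValueError(f"unknown coloring {coloring!r}")
    if coloring != "none" and clusters is None:
        raise ValueError(f"coloring {coloring!r} requires computed clusters")

    values = fm.freqs if scale == "linear" else np.maximum(fm.freqs, fm.floor)
    rows = []
    for i, bid in enumerate(fm.barcode_ids):
        cl = clusters.assignment.get(bid) if clusters is not None else None
        for t, v in zip(fm.timepoints, values[i]):
            rows.append({"ID": bid, "Time": t, "frequency": v, "cluster": cl})
    data = pd.DataFrame(rows)

    fig, ax = plt.subplots(figsize=(7, 4))
    if coloring == "none":
        color_of = {bid: None for bid in fm.barcode_ids}
    else:
        order = clusters.rank
        cmap = plt.get_cmap("tab10")
        ccol = {c: cmap(i % 10) for i, c in enumerate(order)}
        color_of = {
            bid: ccol[clusters.assignment[bid]]
            for bid in fm.barcode_ids
            if bid in clusters.assignment
        }
    for i, bid in enumerate(fm.barcode_ids):
        ax.plot(fm.timepoints, values[i], lw=0.6, alpha=0.6,
                color=color_of.get(bid))
    if scale == "log":
        ax.set_yscale("log")
    ax.set_xlabel("Time")
    ax.set_ylabel("Barcode frequency")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    data.to_csv(_companion(path), index=False)
    return data


def plot_diversity(profile: DiversityProfile, path: str | os.PathLike) -> pd.DataFrame:
    """One curve per diversity order q over time."""
    if len(profile.orders) == 0:
        raise ValueError("empty diversity profile")
    data = profile.to_frame()
    fig, ax = plt.subplots(figsize=(7, 4))
    for col in data.columns[1:]:
        ax.plot(data["Time"], data[col], marker="o", ms=3, label=col)
    ax.set_xlabel("Time")
    ax.set_ylabel("Effective diversity $D_q$")
    ax.set_yscale("log")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    data.to_csv(_companion(path), index=False)
    return data


def plot_clusters(
    fm: FrequencyMatrix,
    clusters: ClonalClusterSet,
    path: str | os.PathLike,
    scale: str = "log",
) -> pd.DataFrame:
    """Member trajectories (thin) with the LOESS consensus (thick) per cluster."""
    data = clusters.consensus.copy()
    fig, ax = plt.subplots(figsize=(7, 4))
    cmap = plt.get_cmap("tab10")
    ccol = {c: cmap(i % 10) for i, c in enumerate(clusters.rank)}
    values = np.maximum(fm.freqs, fm.floor) if scale == "log" else fm.freqs
    idx = {b: i for i, b in enumerate(fm.barcode_ids)}
    for cname in clusters.rank:
        for b in clusters.members(cname):
            ax.plot(fm.timepoints, values[idx[b]], lw=0.4, alpha=0.3,
                    color=ccol[cname])
        sub = data[data["cluster"] == cname]
        ax.plot(sub["Time"], sub["frequency"], lw=2.2, color=ccol[cname],
                label=cname)
    if scale == "log":
        ax.set_yscale("log")
    ax.set_xlabel("Time")
    ax.set_ylabel("Frequency")
    ax.legend(ncols=2, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    data.to_csv(_companion(path), index=False)
    return data
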