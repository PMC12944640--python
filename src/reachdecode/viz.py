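"""Plotting: scalp maps, relevance heatmaps, confusion matrices.

All functions take an ``ax`` or create one, and return the figure, so the
pipeline can write PNGs while notebooks can compose panels.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from scipy.interpolate import griddata

from .montage import Montage


def plot_scalp_map(values: np.ndarray, montage: Montage, ax=None,
                   title: str = "", cmap: str = "RdBu_r",
                   vlim: tuple[float, float] | None = None):
    """Interpolated topographic map of one value per channel."""
    if ax is None:
        _, ax = plt.subplots(figsize=(3, 3))
    pos = montage.positions
    grid = np.linspace(-1.1, 1.1, 120)
    gx, gy = np.meshgrid(grid, grid)
    img = griddata(pos, values, (gx, gy), method="cubic")
    img[gx ** 2 + gy ** 2 > 1.1**2] = np.nan
    if vlim is None:
        m = np.nanmax(np.abs(values)) or 1.0
        vlim = (-m, m)
    pc = ax.imshow(img, extent=[-1.1, 1.1, -1.1, 1.1], origin="lower",
                   cmap=cmap, vmin=vlim[0], vmax=vlim[1])
    ax.add_patch(plt.Circle((0, 0), 1.0, fill=False, lw=1))
    ax.scatter(pos[:, 0], pos[:, 1], s=2, c="k")
    ax.set_xticks([])
    ax.set_yticks([])
    ax.set_title(title, fontsize=8)
    plt.colorbar(pc, ax=ax, shrink=0.7)
    return ax.figure


def plot_relevance_heatmap(values: np.ndarray, times: np.ndarray,
                           montage: Montage, ax=None, title: str = ""):
    """Channels × time relevance heatmap with event markers."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    pc = ax.imshow(values, aspect="auto", origin="upper",
                   extent=[times[0], times[-1], values.shape[0], 0],
                   cmap="viridis")
    for t, lbl in ((-2.0, "cue"), (0.0, "go")):
        if times[0] <= t <= times[-1]:
            ax.axvline(t, color="w", ls="--", lw=0.8)
            ax.text(t, -1, lbl, ha="center", fontsize=7)
    step = max(1, values.shape[0] // 15)
    ax.set_yticks(np.arange(0, values.shape[0], step) + 0.5)
    ax.set_yticklabels(montage.channel_names[::step], fontsize=5)
    ax.set_xlabel("time (s)")
    ax.set_title(title, fontsize=9)
    plt.colorbar(pc, ax=ax, shrink=0.8, label="|relevance|")
    return ax.figure


def plot_confusion(cm: np.ndarray, class_names: tuple[str, ...], ax=None,
                   title: str = ""):
    """Row-normalized confusion matrix with cell annotations."""
    if ax is None:
        _, ax = plt.subplots(figsize=(3.2, 3))
    pc = ax.imshow(cm, cmap="Blues", vmin=0, vmax=1)
    n = len(class_names)
    ax.set_xticks(range(n))
    ax.set_yticks(range(n))
    ax.set_xticklabels(class_names, rotation=45, fontsize=7, ha="right")
    ax.set_yticklabels(class_names, fontsize=7)
    for i in range(n):
        for j in range(n):
            ax.text(j, i, f"{cm[i, j]:.2f}", ha="center", va="center",
                    fontsize=7, color="w" if cm[i, j] > 0.5 else "k")
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    ax.set_title(title, fontsize=9)
    plt.colorbar(pc, ax=ax, shrink=0.8)
    return ax.figure
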