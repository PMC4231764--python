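"""Minimal plots: metagene profiles and fold-change heatmaps."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .metagene import BIN_LABELS, MetageneProfile

__all__ = ["plot_metagene", "plot_fold_change_heatmap"]


def plot_metagene(
    profiles: dict[str, MetageneProfile], path: str | Path, title: str = ""
) -> None:
    """Line plot of one or more 12-bin metagene profiles."""
    fig, ax = plt.subplots(figsize=(6, 3.5))
    x = np.arange(len(BIN_LABELS))
    for label, profile in profiles.items():
        ax.plot(x, profile.bins, marker="o", label=label)
    ax.set_xticks(x, BIN_LABELS, rotation=60, fontsize=7)
    mode = next(iter(profiles.values())).mode if profiles else ""
    ax.set_ylabel("% of clusters" if mode == "cluster_percent" else "mean log2 IP/SUP")
    ax.set_xlabel("gene segment (5' to 3')")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_fold_change_heatmap(
    log2_fc, path: str | Path, gene_order: Sequence[str] | None = None
) -> None:
    """Heatmap of a genes x profiles log2 fold-change matrix."""
    data = log2_fc.loc[list(gene_order)] if gene_order is not None else log2_fc
    fig, ax = plt.subplots(figsize=(3 + 0.4 * data.shape[1], 6))
    vmax = float(np.nanmax(np.abs(data.to_numpy()))) or 1.0
    im = ax.imshow(data.to_numpy(), aspect="auto", cmap="RdBu_r", vmin=-vmax, vmax=vmax)
    ax.set_xticks(range(data.shape[1]), data.columns, rotation=45, fontsize=8)
    ax.set_yticks([])
    fig.colorbar(im, ax=ax, label="log2 fold-change")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
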