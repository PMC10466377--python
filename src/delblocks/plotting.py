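"""Minimal plotting helpers (headless-safe)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def joint_heatmap(table: pd.DataFrame, path, title: str = "") -> None:
    """Heatmap of a long-format joint-probability table.

    Unobserved combinations are hatched out so "never observed" is visually
    distinct from "low probability".
    """
    pivot = table.pivot(index="group_i", columns="group_j", values="p")
    observed = table.pivot(index="group_i", columns="group_j", values="observed")
    fig, ax = plt.subplots(figsize=(6, 5))
    masked = np.ma.masked_invalid(pivot.to_numpy(dtype=float))
    im = ax.imshow(masked, origin="lower", cmap="viridis", vmin=0, vmax=max(1e-9, np.nanmax(pivot.to_numpy())))
    for (i, j), obs in np.ndenumerate(observed.to_numpy()):
        if not obs:
            ax.text(j, i, "x", ha="center", va="center", color="grey")
    ax.set_xticks(range(len(pivot.columns)), pivot.columns)
    ax.set_yticks(range(len(pivot.index)), pivot.index)
    ax.set_xlabel("group (position j)")
    ax.set_ylabel("group (position i)")
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, label="P(bind)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def embedding_scatter(coords: np.ndarray, labels: np.ndarray, path, sizes=None) -> None:
    """Scatter of 2D embedding colored by cluster (noise in grey)."""
    fig, ax = plt.subplots(figsize=(6, 5))
    noise = labels < 0
    ax.scatter(coords[noise, 0], coords[noise, 1], c="lightgrey", s=10, label="noise")
    ax.scatter(
        coords[~noise, 0], coords[~noise, 1], c=labels[~noise], cmap="tab20",
        s=sizes if sizes is None else np.asarray(sizes)[~noise],
    )
    ax.set_xlabel("UMAP 1")
    ax.set_ylabel("UMAP 2")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
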