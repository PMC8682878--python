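"""Minimal plotting helpers (Manhattan tracks, heatmaps, networks)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import networkx as nx
import numpy as np
import pandas as pd


def manhattan(
    df: pd.DataFrame,
    value_col: str,
    path: str | Path,
    log10: bool = False,
    hlines: dict[str, float] | None = None,
    ylabel: str | None = None,
) -> None:
    """Scatter a per-position statistic along the genome, one panel."""
    fig, ax = plt.subplots(figsize=(10, 3))
    x = df["pos"] if "pos" in df.columns else (df["start"] + df["end"]) / 2
    y = df[value_col]
    if log10:
        y = -np.log10(y)
    colors = pd.factorize(df["chrom"])[0] % 2
    ax.scatter(x, y, s=4, c=np.where(colors == 0, "#3465a4", "#73879c"))
    for label, yv in (hlines or {}).items():
        ax.axhline(-np.log10(yv) if log10 else yv, ls="--", lw=0.8, label=label)
        ax.legend(fontsize=7)
    ax.set_xlabel("position (bp)")
    ax.set_ylabel(ylabel or (f"-log10 {value_col}" if log10 else value_col))
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def heatmap(matrix: pd.DataFrame, path: str | Path, cmap: str = "viridis") -> None:
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(matrix.to_numpy(), cmap=cmap)
    fig.colorbar(im, ax=ax, shrink=0.8)
    ax.set_xticks([])
    ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def haplotype_network(
    distances: pd.DataFrame,
    edges: list[tuple[str, str, int]],
    sizes: dict[str, int],
    path: str | Path,
) -> None:
    """Draw the minimum-spanning haplotype network; node area scales
    with carrier count and edges are annotated with step counts."""
    g = nx.Graph()
    g.add_nodes_from(distances.index)
    for a, b, w in edges:
        g.add_edge(a, b, weight=w)
    pos = nx.spring_layout(g, seed=0, weight="weight")
    fig, ax = plt.subplots(figsize=(6, 6))
    nx.draw_networkx(
        g,
        pos,
        ax=ax,
        node_size=[60 * sizes.get(n, 1) for n in g.nodes],
        node_color="#73a946",
        font_size=7,
    )
    nx.draw_networkx_edge_labels(
        g, pos, edge_labels={(a, b): w for a, b, w in edges}, ax=ax, font_size=6
    )
    ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
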