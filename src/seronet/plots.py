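"""Static figures: group boxplots, connectivity heatmaps, network layouts.

Rendering conventions: correlations are colored from red (negative) to
blue (positive), circle/cell size scales with |rho|, non-significant
cells are blank, nodes are colored by functional group and sized by
degree, and edges are blue for positive and red for negative
correlations. Purely presentational; none of the statistics depend on
this module.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import networkx as nx
import numpy as np

from .connectivity import ConnectivityMatrix, ToxicityAssociation
from .network import ConnectivityNetwork, node_degrees
from .panel import GROUP_ORDER

_CMAP = "RdBu"  # red = negative, blue = positive

_GROUP_COLORS = {
    "cytokine": "#1f77b4",
    "chemokine": "#ff7f0e",
    "soluble_immune_checkpoint": "#2ca02c",
    "adhesion_molecule": "#d62728",
    "ido_activity": "#9467bd",
}


def boxplot_significant(cohort, differential, path: str | Path) -> Path:
    """Per-significant-analyte boxplots of log abundance by toxicity group."""
    sig = [r for r in differential if r.p_adjusted <= 0.05]
    path = Path(path)
    n = max(len(sig), 1)
    ncols = min(n, 4)
    nrows = int(np.ceil(n / ncols))
    fig, axes = plt.subplots(nrows, ncols, figsize=(3 * ncols, 3 * nrows), squeeze=False)
    for ax in axes.flat:
        ax.set_visible(False)
    for ax, r in zip(axes.flat, sig):
        ax.set_visible(True)
        v0 = cohort.group_frame(0)[r.analyte_id].dropna()
        v1 = cohort.group_frame(1)[r.analyte_id].dropna()
        box = ax.boxplot([v0, v1], tick_labels=["tox 0", "tox 1"], patch_artist=True)
        for patch, color in zip(box["boxes"], ("#9467bd", "#17becf")):
            patch.set_facecolor(color)
        ax.set_title(f"{r.analyte_id} (q={r.p_adjusted:.3g})", fontsize=9)
        ax.set_ylabel("log level")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def association_heatmap(associations: Sequence[ToxicityAssociation], path: str | Path) -> Path:
    """Single-row heatmap of analyte-vs-toxicity Spearman correlations;
    non-significant cells are blank."""
    path = Path(path)
    ids = [a.analyte_id for a in associations]
    rho = np.array([a.rho if a.significant else np.nan for a in associations])
    fig, ax = plt.subplots(figsize=(max(6, 0.32 * len(ids)), 2.2))
    im = ax.imshow(rho[np.newaxis, :], cmap=_CMAP, vmin=-1, vmax=1, aspect="auto")
    ax.set_yticks([0], ["cumulative toxicity"])
    ax.set_xticks(range(len(ids)), ids, rotation=90, fontsize=7)
    fig.colorbar(im, ax=ax, label="Spearman rho", shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def matrix_heatmap(matrix: ConnectivityMatrix, path: str | Path, alpha: float = 0.05) -> Path:
    """Analyte x analyte correlation heatmap masking non-significant pairs."""
    path = Path(path)
    rho = matrix.rho.to_numpy(dtype=float).copy()
    mask = matrix.p_adjusted.to_numpy(dtype=float) > alpha
    rho[mask] = np.nan
    ids = matrix.analytes
    size = max(5.0, 0.3 * len(ids))
    fig, ax = plt.subplots(figsize=(size + 1.5, size))
    im = ax.imshow(rho, cmap=_CMAP, vmin=-1, vmax=1)
    ax.set_xticks(range(len(ids)), ids, rotation=90, fontsize=7)
    ax.set_yticks(range(len(ids)), ids, fontsize=7)
    ax.set_title(f"connectivity ({matrix.group_label})")
    fig.colorbar(im, ax=ax, label="Spearman rho", shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def network_figure(net: ConnectivityNetwork, path: str | Path, seed: int = 7) -> Path:
    """Spring-layout network with functional-group colors, degree-scaled
    nodes and sign-colored edges."""
    path = Path(path)
    g = net.to_networkx()
    degrees = node_degrees(net)
    pos = nx.spring_layout(g, seed=seed)
    node_colors = [
        _GROUP_COLORS.get(net.functional_groups.get(n, ""), "#7f7f7f") for n in g.nodes
    ]
    node_sizes = [80 + 40 * degrees[n] for n in g.nodes]
    edge_colors = ["#2166ac" if d["sign"] > 0 else "#b2182b" for _, _, d in g.edges(data=True)]
    fig, ax = plt.subplots(figsize=(8, 8))
    nx.draw_networkx(
        g,
        pos=pos,
        ax=ax,
        node_color=node_colors,
        node_size=node_sizes,
        edge_color=edge_colors,
        font_size=7,
        width=1.2,
    )
    ax.set_title(f"{net.group_label}: {net.n_edges} edges, |rho| > {net.threshold_used:.3f}")
    ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
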