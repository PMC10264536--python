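"""Connectivity networks and their shared / group-specific decomposition.

A network links two analytes when the absolute Spearman correlation of
their profiles is strictly greater than the edge threshold AND the
BH-adjusted p-value is at or below alpha. The threshold is usually the
85th percentile of the pooled off-diagonal |rho| distribution of both
group matrices, but a fixed manual value can be supplied instead.
Comparing the two group networks yields shared edges and edges specific
to either toxicity group; edge identity is the unordered analyte pair,
so a pair correlated positively in one group and negatively in the other
still counts as shared (sign-sensitive matching is available).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix
from .panel import PanelMetadata
from .stats import ALPHA

DEFAULT_PERCENTILE = 85.0

Pair = frozenset


@dataclass(frozen=True)
class EdgeAttrs:
    rho: float
    p_adjusted: float

    @property
    def sign(self) -> int:
        return 1 if self.rho >= 0 else -1


@dataclass
class ConnectivityNetwork:
    group_label: str
    nodes: list[str]
    functional_groups: dict[str, str]
    edges: dict[Pair, EdgeAttrs]
    threshold_used: float
    alpha: float = ALPHA

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        for pair, attrs in self.edges.items():
            if len(pair) != 2:
                raise ValueError(f"self-loop or malformed edge: {set(pair)}")
            if not pair <= node_set:
                raise ValueError(f"edge endpoints outside node set: {set(pair)}")
            if not (abs(attrs.rho) > self.threshold_used and attrs.p_adjusted <= self.alpha):
                raise ValueError(
                    f"edge {sorted(pair)} violates the threshold/significance rule"
                )

    @property
    def edge_pairs(self) -> set[Pair]:
        return set(self.edges)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph(group_label=self.group_label, threshold=self.threshold_used)
        for node in self.nodes:
            g.add_node(node, functional_group=self.functional_groups.get(node, ""))
        for pair, attrs in self.edges.items():
            a, b = sorted(pair)
            g.add_edge(a, b, rho=attrs.rho, p_adjusted=attrs.p_adjusted, sign=attrs.sign)
        return g


@dataclass
class NetworkComparison:
    shared_edges: set[Pair]
    specific_to_group0: set[Pair]
    specific_to_group1: set[Pair]
    degree0: dict[str, int]
    degree1: dict[str, int]
    net0: ConnectivityNetwork
    net1: ConnectivityNetwork

    def __post_init__(self) -> None:
        e0, e1 = self.net0.edge_pairs, self.net1.edge_pairs
        assert self.shared_edges | self.specific_to_group0 == e0
        assert self.shared_edges | self.specific_to_group1 == e1
        assert not self.shared_edges & self.specific_to_group0
        assert not self.shared_edges & self.specific_to_group1
        # under pair-identity matching the specific sets are disjoint too; a
        # sign-flipped pair may appear in both under sign-sensitive matching
        assert len(e0) == len(self.shared_edges) + len(self.specific_to_group0)
        assert len(e1) == len(self.shared_edges) + len(self.specific_to_group1)

    def counts(self) -> dict[str, int]:
        return dict(
            edges_group0=self.net0.n_edges,
            edges_group1=self.net1.n_edges,
            shared=len(self.shared_edges),
            specific_to_group0=len(self.specific_to_group0),
            specific_to_group1=len(self.specific_to_group1),
        )


def percentile_threshold(
    matrices: Sequence[ConnectivityMatrix], percentile: float = DEFAULT_PERCENTILE
) -> float:
    """Linear-interpolation percentile of the pooled off-diagonal |rho|.

    Each unordered analyte pair contributes once per matrix; both group
    matrices together form the overall distribution.
    """
    if not 0 < percentile < 100:
        raise ValueError(f"percentile must be in (0, 100), got {percentile}")
    if not matrices:
        raise ValueError("at least one connectivity matrix is required")
    pooled = []
    for mat in matrices:
        arr = mat.rho.to_numpy(dtype=float)
        iu = np.triu_indices(arr.shape[0], k=1)
        vals = np.abs(arr[iu])
        pooled.append(vals[~np.isnan(vals)])
    pooled_arr = np.concatenate(pooled)
    if pooled_arr.size == 0:
        raise ValueError("pooled correlation distribution is empty")
    return float(np.percentile(pooled_arr, percentile, method="linear"))


def build_network(
    matrix: ConnectivityMatrix,
    threshold: float,
    alpha: float = ALPHA,
    panel: PanelMetadata | None = None,
) -> ConnectivityNetwork:
    """Threshold a connectivity matrix into a network.

    An edge requires |rho| strictly greater than ``threshold`` and
    adjusted p at most ``alpha``. All panel analytes are kept as nodes,
    including isolated ones.
    """
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    ids = matrix.analytes
    groups = (
        {a: panel.functional_group(a).value for a in ids if a in panel}
        if panel is not None
        else {a: "" for a in ids}
    )
    rho = matrix.rho.to_numpy(dtype=float)
    p_adj = matrix.p_adjusted.to_numpy(dtype=float)
    edges: dict[Pair, EdgeAttrs] = {}
    for i, j in itertools.combinations(range(len(ids)), 2):
        r, q = rho[i, j], p_adj[i, j]
        if np.isnan(r) or np.isnan(q):
            continue
        if abs(r) > threshold and q <= alpha:
            edges[frozenset((ids[i], ids[j]))] = EdgeAttrs(float(r), float(q))
    return ConnectivityNetwork(
        group_label=matrix.group_label,
        nodes=list(ids),
        functional_groups=groups,
        edges=edges,
        threshold_used=threshold,
        alpha=alpha,
    )


def node_degrees(net: ConnectivityNetwork) -> dict[str, int]:
    """Number of incident edges per node; the degree sum is 2x the edge count."""
    degrees = {node: 0 for node in net.nodes}
    for pair in net.edges:
        for node in pair:
            degrees[node] += 1
    assert sum(degrees.values()) == 2 * net.n_edges
    return degrees


def compare_networks(
    net0: ConnectivityNetwork,
    net1: ConnectivityNetwork,
    *,
    sign_sensitive: bool = False,
) -> NetworkComparison:
    """Shared / specific edge decomposition of two group networks.

    Edge identity is the unordered analyte pair; with
    ``sign_sensitive=True`` a pair must also agree in correlation sign to
    count as shared.
    """
    if set(net0.nodes) != set(net1.nodes):
        raise ValueError("networks must be built over the same node set")
    e0, e1 = net0.edge_pairs, net1.edge_pairs
    shared = e0 & e1
    if sign_sensitive:
        shared = {p for p in shared if net0.edges[p].sign == net1.edges[p].sign}
    return NetworkComparison(
        shared_edges=shared,
        specific_to_group0=e0 - shared,
        specific_to_group1=e1 - shared,
        degree0=node_degrees(net0),
        degree1=node_degrees(net1),
        net0=net0,
        net1=net1,
    )


def _edge_frame(pairs: set[Pair], source: ConnectivityNetwork) -> pd.DataFrame:
    rows = [
        dict(
            analyte_a=min(pair),
            analyte_b=max(pair),
            rho=source.edges[pair].rho,
            p_adjusted=source.edges[pair].p_adjusted,
        )
        for pair in pairs
    ]
    frame = pd.DataFrame(rows, columns=["analyte_a", "analyte_b", "rho", "p_adjusted"])
    return frame.sort_values(["analyte_a", "analyte_b"], ignore_index=True)


def edge_list_frames(comparison: NetworkComparison) -> dict[str, pd.DataFrame]:
    """The five canonical edge-list tables (shared edges carry group-0 values)."""
    return {
        "network_toxicity0": _edge_frame(comparison.net0.edge_pairs, comparison.net0),
        "network_toxicity1": _edge_frame(comparison.net1.edge_pairs, comparison.net1),
        "shared": _edge_frame(comparison.shared_edges, comparison.net0),
        "specific_toxicity0": _edge_frame(comparison.specific_to_group0, comparison.net0),
        "specific_toxicity1": _edge_frame(comparison.specific_to_group1, comparison.net1),
    }


def export_edge_lists(comparison: NetworkComparison, outdir: str | Path) -> dict[str, Path]:
    """Write the five edge-list TSVs (alphabetical pair order)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, frame in edge_list_frames(comparison).items():
        path = outdir / f"edges_{name}.tsv"
        frame.to_csv(path, sep="\t", index=False)
        paths[name] = path
    return paths


def export_excel(comparison: NetworkComparison, path: str | Path) -> Path:
    """Write the five edge lists as one spreadsheet, one sheet per set."""
    path = Path(path)
    with pd.ExcelWriter(path) as writer:
        for name, frame in edge_list_frames(comparison).items():
            frame.to_excel(writer, sheet_name=name[:31], index=False)
    return path


def export_graphml(net: ConnectivityNetwork, path: str | Path) -> Path:
    path = Path(path)
    nx.write_graphml(net.to_networkx(), path)
    return path


def load_edge_list(path: str | Path) -> set[Pair]:
    """Read an exported edge-list TSV back into a set of unordered pairs."""
    frame = pd.read_csv(path, sep="\t")
    return {
        frozenset((a, b)) for a, b in zip(frame["analyte_a"], frame["analyte_b"])
    }
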