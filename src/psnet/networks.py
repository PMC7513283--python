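"""Weighted PS-PS similarity networks: assembly, thresholding, topology.

At threshold zero every similarity network is complete — every PS shares at
least the ontology root with every other PS, so all n(n-1)/2 edges exist,
most of them weak. Raising the weight threshold strips the uninformative
edges first, eventually fragmenting the network into *islands* (connected
components) of highly similar PS.

Five networks are built per run: the clinical similarity network (CSN, from
HPO profiles), one biological similarity network per GO sub-ontology
(BSN-BP, BSN-CC, BSN-MF), and the general BSN whose edge weights are the
per-pair maximum over the three sub-ontology networks.

Topology metrics (mean connectivity <k>, mean clustering coefficient <C>,
characteristic path length <l>, density) follow the unweighted conventions
of Cytoscape's NetworkAnalyzer and are computed with networkx.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence, TextIO

import networkx as nx
import numpy as np
import pandas as pd

from .similarity import SimilarityCoefficient

NETWORK_NAMES = ("CSN", "BSN-BP", "BSN-CC", "BSN-MF", "BSN")
_MERGE_PRIORITY = ("BSN-BP", "BSN-CC", "BSN-MF")

Pair = tuple[str, str]


def _key(a: str, b: str) -> Pair:
    if a == b:
        raise ValueError(f"self-loop on {a}")
    return (a, b) if a < b else (b, a)


@dataclass
class SimilarityNetwork:
    """A weighted graph over PS with its applied threshold state."""

    name: str
    nodes: frozenset[str]
    edges: dict[Pair, float]
    threshold: float = 0.0
    #: general BSN only: which sub-ontology network supplied each edge weight
    edge_provenance: dict[Pair, str] = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph(name=self.name)
        g.add_nodes_from(sorted(self.nodes))
        for (a, b), w in self.edges.items():
            g.add_edge(a, b, weight=w, provenance=self.edge_provenance.get((a, b), ""))
        return g


def assemble(
    coefficients: Iterable[SimilarityCoefficient], name: str
) -> SimilarityNetwork:
    """Build the complete (threshold-0) network from all-pair coefficients.

    Completeness is the contract: with n distinct PS there must be exactly
    n(n-1)/2 coefficients, one per unordered pair.
    """
    edges: dict[Pair, float] = {}
    nodes: set[str] = set()
    for c in coefficients:
        key = _key(c.ps_a, c.ps_b)
        if key in edges:
            raise ValueError(f"duplicate coefficient for pair {key}")
        edges[key] = c.w
        nodes.update(key)
    n = len(nodes)
    expected = n * (n - 1) // 2
    if len(edges) != expected:
        raise ValueError(
            f"{name}: incomplete network — {len(edges)} edges for {n} nodes "
            f"(expected {expected})"
        )
    return SimilarityNetwork(name=name, nodes=frozenset(nodes), edges=edges)


def apply_threshold(net: SimilarityNetwork, w_min: float) -> SimilarityNetwork:
    """Keep edges with w strictly greater than ``w_min``; drop isolated nodes."""
    kept = {pair: w for pair, w in net.edges.items() if w > w_min}
    nodes = frozenset(n for pair in kept for n in pair)
    provenance = {p: s for p, s in net.edge_provenance.items() if p in kept}
    return SimilarityNetwork(
        name=net.name,
        nodes=nodes,
        edges=kept,
        threshold=w_min,
        edge_provenance=provenance,
    )


def merge_max(
    bp: SimilarityNetwork, cc: SimilarityNetwork, mf: SimilarityNetwork
) -> SimilarityNetwork:
    """General BSN: per-pair maximum weight over the three sub-ontology BSNs.

    Ties go to BP, then CC, then MF; provenance records the winning
    sub-ontology for every edge.
    """
    inputs = dict(zip(_MERGE_PRIORITY, (bp, cc, mf)))
    edges: dict[Pair, float] = {}
    provenance: dict[Pair, str] = {}
    pairs: set[Pair] = set()
    for net in inputs.values():
        pairs |= net.edges.keys()
    for pair in pairs:
        best_tag, best_w = None, -np.inf
        for tag in _MERGE_PRIORITY:
            w = inputs[tag].edges.get(pair)
            if w is not None and w > best_w:
                best_tag, best_w = tag, w
        edges[pair] = best_w
        provenance[pair] = best_tag  # type: ignore[assignment]
    nodes = bp.nodes | cc.nodes | mf.nodes
    return SimilarityNetwork(
        name="BSN", nodes=frozenset(nodes), edges=edges, edge_provenance=provenance
    )


def contribution_fractions(net: SimilarityNetwork) -> dict[str, float]:
    """Share of edges each sub-ontology contributed to the general BSN."""
    if not net.edge_provenance:
        raise ValueError("network carries no edge provenance")
    counts = {tag: 0 for tag in _MERGE_PRIORITY}
    for tag in net.edge_provenance.values():
        counts[tag] += 1
    total = sum(counts.values())
    return {tag: counts[tag] / total for tag in _MERGE_PRIORITY}


@dataclass(frozen=True)
class NetworkStats:
    n_nodes: int
    n_edges: int
    mean_k: float
    mean_C: float
    mean_l: float
    density: float
    n_components: int
    gcc_size: int


def stats_from_counts(n_nodes: int, n_edges: int) -> tuple[float, float]:
    """(mean degree, density) identities from node and edge counts alone."""
    if n_nodes < 2:
        raise ValueError("need at least two nodes")
    mean_k = 2.0 * n_edges / n_nodes
    density = 2.0 * n_edges / (n_nodes * (n_nodes - 1))
    return mean_k, density


def topology_stats(net: SimilarityNetwork) -> NetworkStats:
    """Unweighted topology metrics of a (possibly thresholded) network.

    <C> counts nodes of degree < 2 as C_i = 0; <l> averages shortest-path
    lengths over connected node pairs only, so it stays defined after
    fragmentation.
    """
    if net.n_nodes < 2:
        raise ValueError("topology stats need at least two nodes")
    g = net.to_networkx()
    mean_k, density = stats_from_counts(net.n_nodes, net.n_edges)
    mean_c = nx.average_clustering(g, count_zeros=True)

    components = [g.subgraph(c) for c in nx.connected_components(g)]
    path_sum = 0.0
    n_pairs = 0
    for sub in components:
        m = len(sub)
        if m < 2:
            continue
        for _, dists in nx.all_pairs_shortest_path_length(sub):
            path_sum += sum(dists.values())  # includes d=0 to self
        n_pairs += m * (m - 1)
    mean_l = path_sum / n_pairs if n_pairs else 0.0

    return NetworkStats(
        n_nodes=net.n_nodes,
        n_edges=net.n_edges,
        mean_k=mean_k,
        mean_C=mean_c,
        mean_l=mean_l,
        density=density,
        n_components=len(components),
        gcc_size=max(len(c) for c in components),
    )


def islands(net: SimilarityNetwork) -> list[set[str]]:
    """Connected components, largest first (ties by smallest member id)."""
    comps = [set(c) for c in nx.connected_components(net.to_networkx())]
    return sorted(comps, key=lambda c: (-len(c), min(c)))


@dataclass(frozen=True)
class FragmentationCurve:
    thresholds: tuple[float, ...]
    node_fraction: tuple[float, ...]
    edge_fraction: tuple[float, ...]


def fragmentation_curve(
    net: SimilarityNetwork, thresholds: Sequence[float]
) -> FragmentationCurve:
    """Retained node/edge fractions (relative to threshold 0) per threshold."""
    if list(thresholds) != sorted(thresholds):
        raise ValueError("thresholds must be ascending")
    n0, e0 = max(net.n_nodes, 1), max(net.n_edges, 1)
    node_f, edge_f = [], []
    for t in thresholds:
        cut = apply_threshold(net, t)
        node_f.append(cut.n_nodes / n0)
        edge_f.append(cut.n_edges / e0)
    return FragmentationCurve(tuple(thresholds), tuple(node_f), tuple(edge_f))


def threshold_for_node_fraction(
    net: SimilarityNetwork, target: float
) -> tuple[float, float]:
    """Smallest weight threshold retaining at most ``target`` of the nodes.

    Walks the sorted distinct edge weights; returns (threshold, achieved
    node fraction). ``target=1.0`` returns threshold 0.
    """
    if not 0.0 < target <= 1.0:
        raise ValueError("target fraction must be in (0, 1]")
    n0 = net.n_nodes
    for t in [0.0] + sorted(set(net.edges.values())):
        frac = apply_threshold(net, t).n_nodes / n0
        if frac <= target:
            return t, frac
    raise AssertionError("unreachable: thresholding above max weight empties the graph")


# ---------------------------------------------------------------------------
# export

def write_edge_tsv(net: SimilarityNetwork, stream: TextIO) -> None:
    """Cytoscape-compatible weighted edge list (source, target, weight)."""
    rows = [
        (a, b, w, net.edge_provenance.get((a, b), ""))
        for (a, b), w in sorted(net.edges.items())
    ]
    pd.DataFrame(rows, columns=["source", "target", "weight", "provenance"]).to_csv(
        stream, sep="\t", index=False, float_format="%.10g"
    )


def read_edge_tsv(stream: TextIO, name: str, threshold: float = 0.0) -> SimilarityNetwork:
    df = pd.read_csv(stream, sep="\t", dtype={"source": str, "target": str})
    edges: dict[Pair, float] = {}
    provenance: dict[Pair, str] = {}
    for r in df.itertuples(index=False):
        key = _key(r.source, r.target)
        edges[key] = float(r.weight)
        if isinstance(r.provenance, str) and r.provenance:
            provenance[key] = r.provenance
    nodes = frozenset(n for pair in edges for n in pair)
    return SimilarityNetwork(name, nodes, edges, threshold, provenance)


def write_graphml(net: SimilarityNetwork, path: str) -> None:
    nx.write_graphml(net.to_networkx(), path)


def stats_table(stats: dict[str, dict[float, NetworkStats]]) -> pd.DataFrame:
    """Long-form stats table (network, threshold, parameter columns)."""
    rows = []
    for name, per_threshold in stats.items():
        for t, s in per_threshold.items():
            rows.append(
                {
                    "network": name,
                    "threshold": t,
                    "nodes": s.n_nodes,
                    "edges": s.n_edges,
                    "mean_k": s.mean_k,
                    "mean_C": s.mean_C,
                    "mean_l": s.mean_l,
                    "density": s.density,
                    "components": s.n_components,
                    "gcc_size": s.gcc_size,
                }
            )
    return pd.DataFrame(rows)
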