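"""Interactome connectivity statistics.

Summarises a protein-protein interaction graph the way comparative
expression studies report module connectivity: per-node and average
clustering coefficients, average number of neighbours within a module
(induced subgraph by default, full-graph degrees optionally), and
pairwise cluster-to-cluster connectivity — the number of edges joining
two clusters divided by their combined node count — with a per-cluster
median over all its pairings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .datamodel import InteractionGraph

__all__ = [
    "NetworkStats",
    "clustering_coefficient",
    "average_neighbours",
    "cluster_pair_connectivity",
    "neighbourhood_degrees",
]


@dataclass
class NetworkStats:
    per_node_clustering: pd.Series = None
    average_clustering: float = None
    average_neighbours: float = None
    pair_connectivity: dict = field(default_factory=dict)  # (a, b) sorted -> ratio
    per_cluster_median_connectivity: dict = field(default_factory=dict)


def _induced(g: InteractionGraph, nodes):
    missing = [v for v in nodes if v not in g.nx]
    if missing:
        raise ValueError(f"nodes not in graph: {missing[:5]}")
    return g.nx.subgraph(nodes)


def clustering_coefficient(g: InteractionGraph, nodes=None) -> NetworkStats:
    """Per-node triangle clustering coefficients and their average.

    With a node subset, coefficients are computed on the induced subgraph.
    Degree-<2 nodes contribute a coefficient of 0 (they stay in the
    average rather than being excluded).
    """
    sub = g.nx if nodes is None else _induced(g, nodes)
    if sub.number_of_nodes() == 0:
        raise ValueError("empty node set")
    cc = nx.clustering(sub)  # networkx returns 0.0 for degree < 2
    per_node = pd.Series(cc, dtype=float).sort_index()
    return NetworkStats(
        per_node_clustering=per_node, average_clustering=float(per_node.mean())
    )


def average_neighbours(g: InteractionGraph, nodes=None, global_degree: bool = False) -> float:
    """Mean degree of the subset.

    By default only edges with both endpoints inside the subset count
    (induced subgraph); ``global_degree`` counts all neighbours in the
    full graph instead.
    """
    if nodes is None:
        nodes = list(g.nx.nodes)
    nodes = list(nodes)
    if not nodes:
        raise ValueError("empty node subset")
    if global_degree:
        missing = [v for v in nodes if v not in g.nx]
        if missing:
            raise ValueError(f"nodes not in graph: {missing[:5]}")
        degs = [g.nx.degree(v) for v in nodes]
    else:
        sub = _induced(g, nodes)
        degs = [d for _, d in sub.degree()]
    return float(np.mean(degs))


def cluster_pair_connectivity(g: InteractionGraph, clusters: dict) -> NetworkStats:
    """Inter-cluster edges per combined node count, for every cluster pair.

    ``clusters`` maps cluster label -> set of node ids; clusters must be
    disjoint. connectivity(A, B) = |edges between A and B| / (|A| + |B|).
    The per-cluster summary is the median over its pairings with every
    other cluster.
    """
    labels = sorted(clusters)
    seen: dict = {}
    for lbl in labels:
        for v in clusters[lbl]:
            if v in seen:
                raise ValueError(f"node {v!r} in clusters {seen[v]!r} and {lbl!r}")
            seen[v] = lbl
    member = {lbl: set(clusters[lbl]) for lbl in labels}
    counts = {tuple(sorted((a, b))): 0 for i, a in enumerate(labels) for b in labels[i + 1 :]}
    for u, v in g.nx.edges:
        cu, cv = seen.get(u), seen.get(v)
        if cu is None or cv is None or cu == cv:
            continue
        counts[tuple(sorted((cu, cv)))] += 1
    pair_conn = {
        pair: counts[pair] / (len(member[pair[0]]) + len(member[pair[1]]))
        for pair in counts
    }
    medians = {}
    for lbl in labels:
        vals = [v for pair, v in pair_conn.items() if lbl in pair]
        medians[lbl] = float(np.median(vals)) if vals else float("nan")
    return NetworkStats(pair_connectivity=pair_conn, per_cluster_median_connectivity=medians)


def neighbourhood_degrees(g: InteractionGraph, seeds, targets=None) -> dict:
    """First- and second-degree interactors of a seed set.

    First degree: nodes at shortest-path distance 1 from any seed;
    second degree: distance exactly 2 (excluding seeds and first-degree
    nodes). With ``targets``, both sets are intersected with it.
    """
    seeds = {s for s in seeds if s in g.nx}
    first = set()
    for s in seeds:
        first.update(g.nx.neighbors(s))
    first -= seeds
    second = set()
    for v in first:
        second.update(g.nx.neighbors(v))
    second -= seeds | first
    if targets is not None:
        targets = set(targets)
        first &= targets
        second &= targets
    return {"first_degree": first, "second_degree": second}
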