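"""Connectivity statistics on a protein-interaction edge list.

Works on any STRING-like edge list (gene_a, gene_b, combined score in
[0, 1]). Edge enrichment of a gene subset uses a permutation null (random
equal-size node subsets) rather than any service-specific analytical
model; for an Erdős–Rényi background the permutation expectation converges
to the density closed form E*k*(k-1)/(N*(N-1)).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np


@dataclass
class ConnectivityStats:
    observed_edges: int
    avg_node_degree: float
    avg_clustering_coeff: float  # mean local clustering (degree < 2 contributes 0)
    transitivity: float  # global definition, emitted alongside


class InteractionNetwork:
    """Undirected PPI graph with per-edge confidence scores in [0, 1]."""

    def __init__(self, edges: Iterable[tuple[str, str, float]] = (), nodes: Iterable[str] = ()) -> None:
        self.graph = nx.Graph()
        self.graph.add_nodes_from(str(n) for n in nodes)
        for a, b, score in edges:
            a, b = str(a), str(b)
            if a == b:
                raise ValueError(f"self-loop on {a!r}")
            if not (0.0 <= score <= 1.0):
                raise ValueError(f"edge score {score} outside [0, 1] for {a}-{b}")
            if self.graph.has_edge(a, b):
                raise ValueError(f"duplicate edge {a}-{b}")
            self.graph.add_edge(a, b, score=float(score))

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str, float]]:
        return [(a, b, d["score"]) for a, b, d in self.graph.edges(data=True)]

    def __len__(self) -> int:
        return self.graph.number_of_nodes()


def filter_edges(network: InteractionNetwork, min_score: float = 0.4) -> InteractionNetwork:
    """Keep edges with score >= min_score (inclusive); isolated nodes are kept."""
    kept = InteractionNetwork(nodes=network.nodes)
    for a, b, s in network.edges:
        if s >= min_score:
            kept.graph.add_edge(a, b, score=s)
    return kept


def connectivity_stats(network: InteractionNetwork, node_subset: Iterable[str]) -> ConnectivityStats:
    """Induced-subgraph edge count, average degree 2E/N, and clustering."""
    nodes = [n for n in dict.fromkeys(node_subset) if n in network.graph]
    sub = network.graph.subgraph(nodes)
    n = sub.number_of_nodes()
    e = sub.number_of_edges()
    return ConnectivityStats(
        observed_edges=e,
        avg_node_degree=(2 * e / n) if n else 0.0,
        avg_clustering_coeff=nx.average_clustering(sub) if n else 0.0,
        transitivity=nx.transitivity(sub) if n else 0.0,
    )


def edge_enrichment(
    background: InteractionNetwork,
    node_subset: Iterable[str],
    n_permutations: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Permutation test of induced-edge excess for a node subset.

    Draws random subsets of the background node set of the same size,
    counts induced edges, and returns (expected_edges, p) with the
    add-one estimator p = (1 + #{perm >= observed}) / (n_permutations + 1)
    so p is never zero.
    """
    requested = list(dict.fromkeys(node_subset))
    all_nodes = background.nodes
    if len(requested) > len(all_nodes):
        raise ValueError("subset larger than the background node set")
    subset = [n for n in requested if n in background.graph]
    if not subset:
        raise ValueError("empty node subset")
    observed = background.graph.subgraph(subset).number_of_edges()
    rng = np.random.default_rng(seed)
    perm_counts = np.empty(n_permutations, dtype=np.int64)
    for i in range(n_permutations):
        draw = rng.choice(len(all_nodes), size=len(subset), replace=False)
        perm_counts[i] = background.graph.subgraph([all_nodes[j] for j in draw]).number_of_edges()
    expected = float(perm_counts.mean())
    p = float((1 + int((perm_counts >= observed).sum())) / (n_permutations + 1))
    return expected, p


def intra_region_connectivity(
    region_genes: dict[str, Sequence[str]],
    network: InteractionNetwork,
) -> dict[str, tuple[int, int]]:
    """Per region: gene pairs at graph distance exactly 1 and exactly 2.

    Distance is the shortest path in the full background network (so two
    region genes may be linked through a gene outside the region). Pairs
    with either gene absent from the network, or farther than 2, count in
    neither bucket.
    """
    out: dict[str, tuple[int, int]] = {}
    for region, genes in region_genes.items():
        genes = [g for g in dict.fromkeys(genes) if g in network.graph]
        d1 = d2 = 0
        for i, g1 in enumerate(genes):
            neigh = set(network.graph[g1])
            two_away: set[str] = set()
            for nb in neigh:
                two_away.update(network.graph[nb])
            for g2 in genes[i + 1:]:
                if g2 in neigh:
                    d1 += 1
                elif g2 in two_away:
                    d2 += 1
        out[region] = (d1, d2)
    return out
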