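"""Disease-specific PPI subnetwork construction and degree-based gene weights.

The subnetwork is built from seed genes by nearest-neighbor expansion:
the node set is the seeds found in the interaction universe plus every
gene within ``hops`` edges of any seed, and the edge set is the full
induced subgraph on those nodes.  Gene weights are node degrees
normalized by the maximum degree (degree mode) or all ones (uniform
mode); they later scale each gene's contribution to the integrated
expression profile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx

from .io_formats import InteractionRecord, SeedGeneSet, canonical_symbol

log = logging.getLogger(__name__)

__all__ = [
    "PPINetwork",
    "GeneWeights",
    "build_network",
    "expand_from_seeds",
    "largest_connected_component",
    "compute_gene_weights",
]


@dataclass
class PPINetwork:
    """Undirected gene graph with per-edge confidence in [0, 1].

    ``genes`` is the sorted node list (size N); ``graph`` the backing
    networkx Graph.  No self-loops; downstream reordering requires N >= 2
    and connectivity.
    """

    graph: nx.Graph

    def __post_init__(self) -> None:
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            raise ValueError(f"self-loops not allowed: {loops[:5]}")

    @property
    def genes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def n_genes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degree(self, gene: str) -> int:
        return self.graph.degree[gene]

    def is_connected(self) -> bool:
        return self.n_genes > 0 and nx.is_connected(self.graph)

    def edge_records(self) -> list[InteractionRecord]:
        return sorted(
            InteractionRecord(u, v, float(d.get("confidence", 1.0)))
            for u, v, d in self.graph.edges(data=True)
        )


@dataclass
class GeneWeights:
    """Per-gene weights in (0, 1] used by the IXP transform."""

    w: dict[str, float]
    mode: str

    def __post_init__(self) -> None:
        if self.mode not in ("degree", "uniform"):
            raise ValueError(f"unknown weight mode {self.mode!r}")
        if any(v <= 0 for v in self.w.values()):
            raise ValueError("all gene weights must be > 0")


def build_network(records: Iterable[InteractionRecord]) -> PPINetwork:
    """Assemble a PPINetwork from interaction records."""
    g = nx.Graph()
    for rec in records:
        g.add_edge(rec.gene_a, rec.gene_b, confidence=rec.confidence)
    return PPINetwork(graph=g)


def expand_from_seeds(records: Sequence[InteractionRecord], seeds: SeedGeneSet,
                      hops: int = 1) -> PPINetwork:
    """Nearest-neighbor expansion: seeds plus all genes within ``hops`` edges.

    Returns the induced subgraph — every record whose both endpoints
    fall inside the expanded node set becomes an edge.  Seeds absent
    from the interaction universe are logged, not silently dropped.
    """
    if hops < 0:
        raise ValueError("hops must be >= 0")
    universe = build_network(records).graph
    found = sorted(s for s in seeds.genes if s in universe)
    missing = sorted(seeds.genes - set(found))
    if missing:
        log.warning("%d seed gene(s) absent from the interaction records: %s",
                    len(missing), missing)
    if not found:
        raise ValueError("none of the seed genes appear in the interaction records")
    nodes: set[str] = set(found)
    frontier = set(found)
    for _ in range(hops):
        frontier = {nb for u in frontier for nb in universe.neighbors(u)} - nodes
        if not frontier:
            break
        nodes |= frontier
    sub = nx.Graph()
    sub.add_nodes_from(nodes)
    sub.add_edges_from(
        (u, v, d) for u, v, d in universe.edges(nodes, data=True)
        if u in nodes and v in nodes
    )
    net = PPINetwork(graph=sub)
    log.info("expanded %d/%d seeds by %d hop(s): %d genes, %d edges",
             len(found), len(seeds.genes), hops, net.n_genes, net.n_edges)
    return net


def largest_connected_component(net: PPINetwork) -> PPINetwork:
    """Induced subgraph on the largest component.

    Size ties are broken by the lexicographically smallest member gene.
    """
    if net.n_genes == 0:
        raise ValueError("empty network")
    comps = [sorted(c) for c in nx.connected_components(net.graph)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    best = comps[0]
    if len(comps) > 1:
        log.info("keeping largest component (%d of %d genes); %d smaller "
                 "component(s) dropped", len(best), net.n_genes, len(comps) - 1)
    return PPINetwork(graph=net.graph.subgraph(best).copy())


def compute_gene_weights(net: PPINetwork, mode: str = "degree") -> GeneWeights:
    """Degree mode: w(g) = deg(g)/max_degree; uniform mode: w(g) = 1.

    Degree is the unweighted edge count — confidences filter edges at
    read time but do not enter the weight formula.
    """
    if mode == "uniform":
        return GeneWeights(w={g: 1.0 for g in net.genes}, mode=mode)
    if mode != "degree":
        raise ValueError(f"unknown weight mode {mode!r}")
    degrees = {g: net.degree(g) for g in net.genes}
    isolated = [g for g, d in degrees.items() if d == 0]
    if isolated:
        raise ValueError(
            f"isolated node(s) {isolated[:5]} have no degree weight; run "
            "largest_connected_component first"
        )
    dmax = max(degrees.values())
    return GeneWeights(w={g: d / dmax for g, d in degrees.items()}, mode=mode)
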