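"""Node orderings: ACOR ant-colony reordering plus comparison methods.

The goal of every method here is seriation of the interaction network:
a bijection from genes to positions 1..N that places interacting genes
at nearby positions, quantified by the linear arrangement cost
``sum over edges |pos(u) - pos(v)|``.

ACOR (ant colony optimization reordering) evolves an ant-visit density
over nodes: each iteration, ants perform pheromone-biased random walks
(transition weight = pheromone^alpha * degree^beta), deposit pheromone
on traversed edges under evaporation, and accumulate visit counts into
a node density.  Genes are first ranked by final density, then the
ordering is refined by adjacent-transposition local search that accepts
swaps which strictly decrease the arrangement cost.  In populated mode
ants launch from every node each iteration; in single mode all ants
launch from the highest-degree node.

Comparison orderings: damped random-walk ranking (PageRank-style),
average-linkage hierarchical clustering of node neighborhoods, and a
uniform random permutation.  A brute-force exhaustive minimizer over
all N! orderings serves as an oracle for tiny graphs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .network import PPINetwork

__all__ = [
    "NodeOrdering",
    "ColonyState",
    "AcorParams",
    "acor_reorder",
    "random_walk_rank",
    "hclust_order",
    "random_order",
    "linear_arrangement_cost",
    "brute_force_min_arrangement",
]


@dataclass(frozen=True)
class NodeOrdering:
    """Bijection gene -> position in 1..N, tagged with the producing method."""

    position: dict[str, int]
    method: str

    def __post_init__(self) -> None:
        n = len(self.position)
        if sorted(self.position.values()) != list(range(1, n + 1)):
            raise ValueError("positions must be a bijection onto 1..N")

    @property
    def n(self) -> int:
        return len(self.position)

    def genes_by_position(self) -> list[str]:
        return [g for g, _ in sorted(self.position.items(), key=lambda kv: kv[1])]


@dataclass
class ColonyState:
    """Final pheromone/density state of an ACOR run (diagnostic output)."""

    pheromone: dict[tuple[str, str], float]
    density: dict[str, float]
    iteration: int

    def __post_init__(self) -> None:
        if self.density:
            total = sum(self.density.values())
            if not np.isclose(total, 1.0):
                raise ValueError(f"density must sum to 1, got {total}")
        if any(t <= 0 for t in self.pheromone.values()):
            raise ValueError("pheromone must stay above the positive floor")


@dataclass(frozen=True)
class AcorParams:
    """ACOR tuning knobs.

    n_ants defaults to N (one ant per node, populated mode); walk_length
    is the number of steps per ant; alpha/beta weight pheromone vs the
    degree heuristic in transition probabilities; rho is the evaporation
    rate; refine_passes bounds the local-search sweeps.
    """

    n_ants: int | None = None
    walk_length: int = 10
    alpha: float = 1.0
    beta: float = 1.0
    rho: float = 0.1
    n_iterations: int = 50
    mode: str = "populated"
    refine_passes: int = 5
    seed: int = 0
    pheromone_floor: float = 1e-6

    def __post_init__(self) -> None:
        if self.n_ants is not None and self.n_ants < 1:
            raise ValueError("n_ants must be positive")
        if self.walk_length < 1 or self.n_iterations < 1:
            raise ValueError("walk_length and n_iterations must be positive")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be >= 0")
        if not 0.0 < self.rho < 1.0:
            raise ValueError("rho must lie in (0, 1)")
        if self.mode not in ("populated", "single"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.refine_passes < 0:
            raise ValueError("refine_passes must be >= 0")
        if self.pheromone_floor <= 0:
            raise ValueError("pheromone floor must be > 0")


def _require_connected(net: PPINetwork) -> None:
    if net.n_genes < 2:
        raise ValueError("reordering requires at least 2 genes")
    if not net.is_connected():
        raise ValueError(
            "network is disconnected; extract the largest component first "
            "(network.largest_connected_component)"
        )


def linear_arrangement_cost(net: PPINetwork, ordering: NodeOrdering) -> float:
    """Sum over edges of the positional distance between endpoints."""
    if set(ordering.position) != set(net.graph.nodes):
        raise ValueError("ordering genes do not match network genes")
    pos = ordering.position
    return float(sum(abs(pos[u] - pos[v]) for u, v in net.graph.edges))


def _refine(order: list[int], nbrs: list[np.ndarray], passes: int) -> list[int]:
    """Insertion local search built from chained adjacent transpositions.

    Each pass tries, for every index, to slide the node there left or
    right through successive adjacent swaps, accumulating the exact cost
    delta, and commits the best strictly improving stop point.  Single
    adjacent swaps are the one-step special case; longer slides let the
    search escape the shallow local optima that one-step swaps cannot,
    which is what block contiguity requires.  Only strictly decreasing
    moves are accepted, so the final cost never exceeds the initial one.
    """
    order = list(order)
    n = len(order)
    pos = np.empty(n, dtype=np.int64)
    for i, node in enumerate(order):
        pos[node] = i

    def swap_delta(i: int) -> float:
        # cost change of transposing positions i and i+1
        u, v = order[i], order[i + 1]
        du = pos[nbrs[u]]
        dv = pos[nbrs[v]]
        du = du[du != i + 1]
        dv = dv[dv != i]
        return float(
            np.abs(i + 1 - du).sum() - np.abs(i - du).sum()
            + np.abs(i - dv).sum() - np.abs(i + 1 - dv).sum()
        )

    def apply_swap(i: int) -> None:
        u, v = order[i], order[i + 1]
        order[i], order[i + 1] = v, u
        pos[u], pos[v] = i + 1, i

    def slide(i: int, rightward: bool) -> float:
        """Slide the node at index i as far as profitable; return best delta."""
        best_delta, best_k, cum = 0.0, 0, 0.0
        j = i
        if rightward:
            while j < n - 1:
                cum += swap_delta(j)
                apply_swap(j)
                j += 1
                if cum < best_delta:
                    best_delta, best_k = cum, j - i
            while j - i > best_k:  # roll back past the best stop point
                j -= 1
                apply_swap(j)
        else:
            while j > 0:
                cum += swap_delta(j - 1)
                apply_swap(j - 1)
                j -= 1
                if cum < best_delta:
                    best_delta, best_k = cum, i - j
            while i - j > best_k:
                apply_swap(j)
                j += 1
        return best_delta

    for _ in range(passes):
        improved = False
        for i in range(n):
            if slide(i, rightward=True) < 0:
                improved = True
            elif slide(i, rightward=False) < 0:
                improved = True
        if not improved:
            break
    return order


def acor_reorder(net: PPINetwork, params: AcorParams | None = None,
                 return_state: bool = False):
    """ACOR ordering of a connected network; deterministic given the seed.

    Returns a NodeOrdering (and the final ColonyState when
    ``return_state`` is set).  The refined ordering's arrangement cost
    never exceeds the density-ranked initial ordering's cost.
    """
    params = params or AcorParams()
    _require_connected(net)
    genes = net.genes
    n = len(genes)
    index = {g: i for i, g in enumerate(genes)}
    edges = [(index[u], index[v]) for u, v in sorted(net.graph.edges())]
    edge_id = {}
    for eid, (u, v) in enumerate(edges):
        edge_id[(u, v)] = edge_id[(v, u)] = eid
    nbrs = [np.array(sorted(index[w] for w in net.graph.neighbors(g)), dtype=np.int64)
            for g in genes]
    eids = [np.array([edge_id[(i, j)] for j in nbrs[i]], dtype=np.int64)
            for i in range(n)]
    deg = np.array([len(a) for a in nbrs], dtype=float)

    n_ants = params.n_ants if params.n_ants is not None else n
    if params.mode == "populated":
        starts = np.arange(n, dtype=np.int64)
        starts = np.resize(starts, n_ants)
    else:
        hub = int(np.lexsort((np.arange(n), -deg))[0])  # max degree, lexicographic tie
        starts = np.full(n_ants, hub, dtype=np.int64)

    rng = np.random.default_rng(params.seed)
    tau = np.ones(len(edges))
    visits = np.zeros(n)
    heur = [deg[nbrs[i]] ** params.beta for i in range(n)]

    for _ in range(params.n_iterations):
        cum = [np.cumsum((tau[eids[i]] ** params.alpha) * heur[i]) for i in range(n)]
        deposit = np.zeros(len(edges))
        draws = rng.random((len(starts), params.walk_length))
        for a, start in enumerate(starts):
            cur = int(start)
            visits[cur] += 1
            for step in range(params.walk_length):
                c = cum[cur]
                k = int(np.searchsorted(c, draws[a, step] * c[-1], side="right"))
                k = min(k, len(c) - 1)
                deposit[eids[cur][k]] += 1
                cur = int(nbrs[cur][k])
                visits[cur] += 1
        tau = (1.0 - params.rho) * tau + deposit / (len(starts) * params.walk_length)
        np.maximum(tau, params.pheromone_floor, out=tau)

    density = visits / visits.sum()
    # density descending, lexicographic gene symbol tie-break
    initial = sorted(range(n), key=lambda i: (-density[i], genes[i]))
    refined = _refine(initial, nbrs, params.refine_passes)

    ordering = NodeOrdering(
        position={genes[node]: p + 1 for p, node in enumerate(refined)},
        method="acor",
    )
    if return_state:
        state = ColonyState(
            pheromone={(genes[u], genes[v]): float(tau[edge_id[(u, v)]])
                       for u, v in edges},
            density={genes[i]: float(density[i]) for i in range(n)},
            iteration=params.n_iterations,
        )
        return ordering, state
    return ordering


def random_walk_rank(net: PPINetwork, damping: float = 0.85,
                     tol: float = 1e-10, max_iter: int = 10_000) -> NodeOrdering:
    """Damped random-walk (PageRank-style) stationary scores, ranked descending.

    Power iteration runs until the L1 change drops below ``tol``; ties in
    score are broken lexicographically by gene symbol.
    """
    _require_connected(net)
    if not 0.0 < damping < 1.0:
        raise ValueError("damping must lie in (0, 1)")
    genes = net.genes
    n = len(genes)
    index = {g: i for i, g in enumerate(genes)}
    deg = np.array([net.degree(g) for g in genes], dtype=float)
    rows, cols = [], []
    for u, v in net.graph.edges:
        rows += [index[u], index[v]]
        cols += [index[v], index[u]]
    x = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        contrib = x / deg
        x_new = np.zeros(n)
        np.add.at(x_new, cols, contrib[rows])
        x_new = (1.0 - damping) / n + damping * x_new
        if np.abs(x_new - x).sum() < tol:
            x = x_new
            break
        x = x_new
    else:
        raise RuntimeError(f"random-walk ranking did not converge in {max_iter} iterations")
    order = sorted(range(n), key=lambda i: (-x[i], genes[i]))
    return NodeOrdering(
        position={genes[i]: p + 1 for p, i in enumerate(order)}, method="rank"
    )


def _closed_neighborhood_jaccard_dissim(net: PPINetwork) -> np.ndarray:
    genes = net.genes
    n = len(genes)
    sets = [set(net.graph.neighbors(g)) | {g} for g in genes]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            inter = len(sets[i] & sets[j])
            union = len(sets[i] | sets[j])
            d[i, j] = d[j, i] = 1.0 - inter / union
    return d


def hclust_order(net: PPINetwork) -> NodeOrdering:
    """Dendrogram leaf order from average-linkage clustering of neighborhoods.

    Dissimilarity d(u, v) = 1 - Jaccard(closed neighborhoods).  Child
    clusters are ordered deterministically: smaller cluster first, ties
    by lexicographically smallest member gene.
    """
    if net.n_genes < 2:
        raise ValueError("hierarchical ordering requires at least 2 genes")
    genes = net.genes
    n = len(genes)
    d = _closed_neighborhood_jaccard_dissim(net)
    z = linkage(squareform(d, checks=False), method="average")
    # iterative post-order with deterministic child ordering
    members: dict[int, tuple[int, str]] = {}  # cluster -> (size, min gene)
    for i, g in enumerate(genes):
        members[i] = (1, g)
    for k, (a, b, _, size) in enumerate(z):
        ca, cb = members[int(a)], members[int(b)]
        members[n + k] = (int(size), min(ca[1], cb[1]))

    leaves: list[int] = []
    stack: list[int] = [n + len(z) - 1] if len(z) else [0]
    while stack:
        node = stack.pop()
        if node < n:
            leaves.append(node)
            continue
        a, b = int(z[node - n, 0]), int(z[node - n, 1])
        first, second = sorted((a, b), key=lambda c: members[c])
        stack.append(second)  # LIFO: push second so first is visited first
        stack.append(first)
    return NodeOrdering(
        position={genes[i]: p + 1 for p, i in enumerate(leaves)}, method="hclust"
    )


def random_order(net: PPINetwork, seed: int) -> NodeOrdering:
    """Uniform random permutation of the genes, deterministic given seed."""
    genes = net.genes
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(genes))
    return NodeOrdering(
        position={genes[i]: int(p) + 1 for i, p in enumerate(perm)}, method="random"
    )


def brute_force_min_arrangement(net: PPINetwork) -> tuple[NodeOrdering, float]:
    """Exhaustive minimum linear arrangement; oracle for graphs with N <= 9.

    Returns the first minimizer in lexicographic order of gene sequences.
    """
    genes = net.genes
    n = len(genes)
    if n > 9:
        raise ValueError(f"brute force refused for N={n} > 9")
    index = {g: i for i, g in enumerate(genes)}
    edges = [(index[u], index[v]) for u, v in net.graph.edges]
    best_cost = np.inf
    best_perm: tuple[int, ...] | None = None
    pos = [0] * n
    for perm in itertools.permutations(range(n)):
        for p, node in enumerate(perm):
            pos[node] = p
        cost = sum(abs(pos[u] - pos[v]) for u, v in edges)
        if cost < best_cost:
            best_cost = cost
            best_perm = perm
    assert best_perm is not None
    ordering = NodeOrdering(
        position={genes[node]: p + 1 for p, node in enumerate(best_perm)},
        method="brute",
    )
    return ordering, float(best_cost)
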