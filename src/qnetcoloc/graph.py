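"""Undirected molecular-interaction network: container, I/O and degree machinery.

The network is the substrate for random-walk propagation: an undirected simple
graph over gene identifiers. This module provides the edge-list reader/writer,
the column-normalized adjacency matrix used by the random walk, degree binning
(the sampling strata for degree-matched nulls), and degree-preserving edge
swapping used to produce progressively randomized ("diluted") networks.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import scipy.sparse as sp

logger = logging.getLogger("qnetcoloc")

__all__ = [
    "Network",
    "DegreeBins",
    "load_edge_list",
    "write_edge_list",
    "largest_connected_component",
    "column_normalized_adjacency",
    "make_degree_bins",
    "shuffle_network",
    "edge_jaccard_dilution",
]


def _canonical(u: str, v: str) -> tuple[str, str]:
    """Canonical unordered-pair representation: (min, max)."""
    return (u, v) if u <= v else (v, u)


class Network:
    """Simple undirected graph over gene identifiers with a fixed node order.

    Nodes are sorted lexicographically once at construction; every vector and
    matrix produced downstream (seed vectors, heat vectors, NPS) is aligned to
    this order. Self-loops are dropped and duplicate edges collapse.

    Parameters
    ----------
    graph
        Any :class:`networkx.Graph`-like object (nodes coerced to ``str``).
    """

    def __init__(self, graph: nx.Graph):
        g = nx.Graph()
        g.add_nodes_from(str(n) for n in graph.nodes)
        n_loops = 0
        for u, v in graph.edges:
            u, v = str(u), str(v)
            if u == v:
                n_loops += 1
                continue
            g.add_edge(*_canonical(u, v))
        if n_loops:
            logger.info("dropped %d self-loop(s)", n_loops)
        self.graph = g
        self.nodes: tuple[str, ...] = tuple(sorted(g.nodes))
        self.node_index: dict[str, int] = {n: i for i, n in enumerate(self.nodes)}
        self._kernels: dict[float, np.ndarray] = {}

    # -- basic accessors ---------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def degree(self) -> dict[str, int]:
        return {n: self.graph.degree[n] for n in self.nodes}

    def degree_array(self) -> np.ndarray:
        return np.array([self.graph.degree[n] for n in self.nodes], dtype=int)

    def edge_set(self) -> frozenset[tuple[str, str]]:
        return frozenset(_canonical(u, v) for u, v in self.graph.edges)

    def has_node(self, g: str) -> bool:
        return g in self.node_index

    def __contains__(self, g: str) -> bool:
        return g in self.node_index

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Network(n_nodes={self.n_nodes}, n_edges={self.n_edges})"

    # -- propagation support ----------------------------------------------

    def rwr_kernel(self, alpha: float) -> np.ndarray:
        """Dense random-walk-with-restart kernel ``(1−α)(I−αW)⁻¹``.

        Computed once per dissipation constant and cached on the instance:
        propagating any seed (or matrix of seeds) is then a single mat-vec
        (mat-mat) product, which is what makes the permutation-null ensembles
        affordable.
        """
        key = float(alpha)
        if key not in self._kernels:
            if not 0 < alpha < 1:
                raise ValueError(f"alpha must be in (0, 1), got {alpha}")
            W = column_normalized_adjacency(self).toarray()
            n = self.n_nodes
            A = np.eye(n) - alpha * W
            self._kernels[key] = np.linalg.solve(A, (1.0 - alpha) * np.eye(n))
        return self._kernels[key]


@dataclass(frozen=True)
class DegreeBins:
    """Degree-contiguous node strata, each holding at least ``min_size`` nodes.

    ``bins`` partition the node set; nodes are sorted by (degree, identifier)
    and grouped greedily, with an undersized trailing remainder merged into its
    predecessor. ``bin_of`` maps each node to its bin index.
    """

    bins: tuple[tuple[str, ...], ...]
    min_size: int
    bin_of: dict[str, int] = field(repr=False)

    def members(self, gene: str) -> tuple[str, ...]:
        return self.bins[self.bin_of[gene]]


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------


def load_edge_list(
    path,
    delimiter: str = "\t",
    restrict_to_lcc: bool = False,
) -> Network:
    """Read an undirected network from a two-column edge-list text file.

    Lines starting with ``#`` are ignored; extra columns beyond the first two
    are ignored; duplicate edges collapse and self-loops are dropped (counted
    in the log). With ``restrict_to_lcc`` the result is the largest connected
    component, which guarantees every node has degree ≥ 1 as propagation
    requires.

    Raises
    ------
    ValueError
        If a non-comment, non-blank line has fewer than two fields (the error
        names the line number).
    """
    g = nx.Graph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split(delimiter) if delimiter else line.split()
            fields = [f for f in fields if f != ""]
            if len(fields) < 2:
                raise ValueError(
                    f"{path}: line {lineno}: expected at least 2 fields, "
                    f"got {len(fields)}"
                )
            g.add_edge(fields[0], fields[1])
    net = Network(g)
    if restrict_to_lcc:
        net = largest_connected_component(net)
    return net


def write_edge_list(net: Network, path, delimiter: str = "\t") -> None:
    """Write canonicalized (min, max) edges in sorted order, one per line."""
    with open(path, "w") as fh:
        for u, v in sorted(net.edge_set()):
            fh.write(f"{u}{delimiter}{v}\n")


def largest_connected_component(net: Network) -> Network:
    """Restrict to the largest connected component (ties broken by node order).

    Logs the number of dropped nodes so callers can surface it.
    """
    if net.n_nodes == 0:
        return net
    comps = sorted(nx.connected_components(net.graph), key=lambda c: (-len(c), min(c)))
    keep = comps[0]
    dropped = net.n_nodes - len(keep)
    if dropped:
        logger.info("LCC restriction dropped %d of %d nodes", dropped, net.n_nodes)
    return Network(net.graph.subgraph(keep))


# ---------------------------------------------------------------------------
# Column-normalized adjacency
# ---------------------------------------------------------------------------


def column_normalized_adjacency(net: Network) -> sp.csc_matrix:
    """Column-stochastic adjacency W: w(i,j) = 1/degree(j) for each edge {i,j}.

    Every column sums to one, so the random walk conserves total heat. An
    isolated node makes its column all-zero and breaks conservation, so it is
    rejected with a pointer to LCC restriction.
    """
    if net.n_nodes == 0:
        raise ValueError("network is empty")
    deg = net.degree_array()
    if (deg == 0).any():
        bad = [net.nodes[i] for i in np.flatnonzero(deg == 0)[:5]]
        raise ValueError(
            "network contains isolated node(s) "
            f"(e.g. {bad}); restrict to the largest connected component first"
        )
    A = nx.to_scipy_sparse_array(net.graph, nodelist=list(net.nodes), format="csc")
    A = A.astype(float)
    W = A @ sp.diags(1.0 / deg)
    return sp.csc_matrix(W)


# ---------------------------------------------------------------------------
# Degree binning
# ---------------------------------------------------------------------------


def make_degree_bins(net: Network, beta: int = 20) -> DegreeBins:
    """Group nodes into degree-contiguous bins of at least ``beta`` members.

    Nodes are sorted by (degree, identifier) — the identifier tie-break makes
    the stratification deterministic. Bins fill greedily until they reach
    ``beta`` nodes; a trailing remainder smaller than ``beta`` merges into the
    previous bin. ``beta`` larger than the node count yields a single bin.
    """
    if beta < 1:
        raise ValueError(f"beta must be >= 1, got {beta}")
    order = sorted(net.nodes, key=lambda n: (net.graph.degree[n], n))
    bins: list[list[str]] = []
    current: list[str] = []
    for node in order:
        current.append(node)
        if len(current) >= beta:
            bins.append(current)
            current = []
    if current:
        if bins:
            bins[-1].extend(current)
        else:
            bins.append(current)
    bin_of = {n: i for i, b in enumerate(bins) for n in b}
    return DegreeBins(
        bins=tuple(tuple(b) for b in bins), min_size=beta, bin_of=bin_of
    )


# ---------------------------------------------------------------------------
# Degree-preserving randomization
# ---------------------------------------------------------------------------


def shuffle_network(
    net: Network, n_swap_multiplier: float, rng_seed: int | np.random.Generator = 0
) -> Network:
    """Randomize edges by degree-preserving double-edge swaps.

    Attempts ``n_swap_multiplier × |E|`` swaps: each attempt picks two distinct
    edges {a,b}, {c,d} and a random orientation, and rewires to {a,c}, {b,d}
    unless that would create a self-loop or a duplicate edge (rejected
    attempts are simply discarded). The degree sequence is preserved exactly.
    Dilution is *measured* afterwards with :func:`edge_jaccard_dilution`, not
    targeted.
    """
    if n_swap_multiplier < 0:
        raise ValueError("n_swap_multiplier must be >= 0")
    if net.n_edges < 2:
        warnings.warn("network has fewer than 2 edges; returning unchanged copy")
        return Network(net.graph)
    rng = np.random.default_rng(rng_seed)
    edges = [list(e) for e in sorted(net.edge_set())]
    edge_lookup = {tuple(e) for e in net.edge_set()}
    m = len(edges)
    n_attempts = int(round(n_swap_multiplier * m))
    for _ in range(n_attempts):
        i, j = rng.integers(0, m, size=2)
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if rng.random() < 0.5:
            c, d = d, c
        # proposed rewiring: {a,c}, {b,d}
        if a == c or b == d:
            continue
        e1, e2 = _canonical(a, c), _canonical(b, d)
        if e1 in edge_lookup or e2 in edge_lookup or e1 == e2:
            continue
        edge_lookup.discard(_canonical(a, b))
        edge_lookup.discard(_canonical(c, d))
        edge_lookup.add(e1)
        edge_lookup.add(e2)
        edges[i] = list(e1)
        edges[j] = list(e2)
    g = nx.Graph()
    g.add_nodes_from(net.nodes)
    g.add_edges_from(edge_lookup)
    return Network(g)


def edge_jaccard_dilution(original: Network, shuffled: Network) -> float:
    """Network dilution 1 − J, with J the Jaccard similarity of edge sets."""
    if set(original.nodes) != set(shuffled.nodes):
        raise ValueError("networks must share the same node set")
    e1, e2 = original.edge_set(), shuffled.edge_set()
    union = len(e1 | e2)
    if union == 0:
        return 0.0
    return 1.0 - len(e1 & e2) / union
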