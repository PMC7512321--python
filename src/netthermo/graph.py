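"""Graph containers, degrees, normalized Laplacian and its spectrum.

Graphs are simple (no self-loops, no multi-edges) with nodes identified by
contiguous integer indices ``0..n_nodes-1``. Undirected edges are stored as
canonical ``(u, v)`` tuples with ``u < v``; directed arcs as ordered pairs.
Isolated nodes are permitted — correlation networks routinely produce them —
but note that the degree-form entropy approximations assume
``Tr[L~] = |V|`` and therefore warn when isolated nodes are present.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence, Union

import numpy as np

__all__ = [
    "UndirectedGraph",
    "DirectedGraph",
    "LaplacianSpectrum",
    "SnapshotSequence",
    "build_undirected_graph",
    "build_directed_graph",
    "degree_vector",
    "in_out_degrees",
    "adjacency_matrix",
    "normalized_laplacian",
    "laplacian_spectrum",
]


class GraphValidationError(ValueError):
    """Raised when a graph, arc set or snapshot sequence violates an invariant."""


@dataclass(frozen=True)
class UndirectedGraph:
    """A simple undirected graph on ``n_nodes`` integer-labelled nodes."""

    n_nodes: int
    edges: frozenset  # frozenset of (u, v) tuples with u < v

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degrees(self) -> np.ndarray:
        return degree_vector(self)

    def has_isolated_nodes(self) -> bool:
        return bool(np.any(self.degrees() == 0))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"UndirectedGraph(n_nodes={self.n_nodes}, n_edges={self.n_edges})"


@dataclass(frozen=True)
class DirectedGraph:
    """A simple directed graph; arcs are ordered ``(u, v)`` pairs, u != v."""

    n_nodes: int
    arcs: frozenset  # frozenset of ordered (u, v) tuples

    @property
    def n_arcs(self) -> int:
        return len(self.arcs)

    def has_bidirectional_pair(self):
        """Return one ``(u, v)`` with both orientations present, or None."""
        for (u, v) in self.arcs:
            if (v, u) in self.arcs and u < v:
                return (u, v)
        return None

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"DirectedGraph(n_nodes={self.n_nodes}, n_arcs={self.n_arcs})"


AnyGraph = Union[UndirectedGraph, DirectedGraph]


@dataclass(frozen=True)
class LaplacianSpectrum:
    """Eigenvalues of the normalized Laplacian and their occupations.

    ``occupations[s] = eigenvalues[s] / n_nodes`` are the microstate
    occupation probabilities p_s of the graph density matrix ``L~ / |V|``.
    Eigenvalues are sorted ascending and lie in [0, 2]; their sum equals the
    number of non-isolated nodes.
    """

    eigenvalues: np.ndarray
    n_nodes: int

    @property
    def occupations(self) -> np.ndarray:
        return self.eigenvalues / self.n_nodes


@dataclass
class SnapshotSequence:
    """An ordered sequence of graphs on one fixed node set.

    All graphs must share ``n_nodes`` (the framework applies to evolving
    networks that do not change size). ``labels`` carry timestamps or
    filename stems; ``node_names`` optionally maps indices to external
    string identifiers.
    """

    graphs: list
    labels: list
    node_names: list | None = field(default=None)

    def __post_init__(self):
        if len(self.graphs) < 1:
            raise GraphValidationError("a snapshot sequence needs at least one graph")
        if len(self.labels) != len(self.graphs):
            raise GraphValidationError(
                f"{len(self.labels)} labels for {len(self.graphs)} graphs"
            )
        n0 = self.graphs[0].n_nodes
        for i, g in enumerate(self.graphs):
            if g.n_nodes != n0:
                raise GraphValidationError(
                    f"snapshot {self.labels[i]!r} has {g.n_nodes} nodes, expected {n0}"
                )
        directed = isinstance(self.graphs[0], DirectedGraph)
        for g in self.graphs:
            if isinstance(g, DirectedGraph) != directed:
                raise GraphValidationError("mixed directed/undirected snapshot sequence")
        if self.node_names is not None and len(self.node_names) != n0:
            raise GraphValidationError("node_names length does not match n_nodes")

    @property
    def n_nodes(self) -> int:
        return self.graphs[0].n_nodes

    @property
    def directed(self) -> bool:
        return isinstance(self.graphs[0], DirectedGraph)

    def __len__(self) -> int:
        return len(self.graphs)

    def __iter__(self):
        return iter(self.graphs)


def _canonical_pair(u, v) -> tuple:
    return (u, v) if u < v else (v, u)


def build_undirected_graph(n: int, pairs: Iterable[Sequence[int]]) -> UndirectedGraph:
    """Build a simple undirected graph from node pairs.

    Duplicate pairs (in either orientation) collapse to a single edge;
    self-loops and out-of-range indices raise ``GraphValidationError``.
    """
    if n < 1:
        raise GraphValidationError(f"n_nodes must be positive, got {n}")
    edges = set()
    for pair in pairs:
        u, v = int(pair[0]), int(pair[1])
        if u == v:
            raise GraphValidationError(f"self-loop ({u}, {v}) is not allowed")
        if not (0 <= u < n and 0 <= v < n):
            raise GraphValidationError(
                f"pair ({u}, {v}) out of range for n_nodes={n}"
            )
        edges.add(_canonical_pair(u, v))
    return UndirectedGraph(n_nodes=n, edges=frozenset(edges))


def build_directed_graph(n: int, arcs: Iterable[Sequence[int]]) -> DirectedGraph:
    """Build a simple directed graph from ordered node pairs."""
    if n < 1:
        raise GraphValidationError(f"n_nodes must be positive, got {n}")
    arc_set = set()
    for pair in arcs:
        u, v = int(pair[0]), int(pair[1])
        if u == v:
            raise GraphValidationError(f"self-loop ({u}, {v}) is not allowed")
        if not (0 <= u < n and 0 <= v < n):
            raise GraphValidationError(f"arc ({u}, {v}) out of range for n_nodes={n}")
        arc_set.add((u, v))
    return DirectedGraph(n_nodes=n, arcs=frozenset(arc_set))


def degree_vector(g: UndirectedGraph) -> np.ndarray:
    """Node degrees d_u = sum_v A_vu; sums to 2|E|."""
    d = np.zeros(g.n_nodes, dtype=np.int64)
    for (u, v) in g.edges:
        d[u] += 1
        d[v] += 1
    return d


def in_out_degrees(g: DirectedGraph) -> tuple:
    """Return ``(in_degrees, out_degrees)``; each sums to the arc count."""
    din = np.zeros(g.n_nodes, dtype=np.int64)
    dout = np.zeros(g.n_nodes, dtype=np.int64)
    for (u, v) in g.arcs:
        dout[u] += 1
        din[v] += 1
    return din, dout


def adjacency_matrix(g: AnyGraph) -> np.ndarray:
    """Dense 0/1 adjacency matrix (symmetric for undirected graphs)."""
    a = np.zeros((g.n_nodes, g.n_nodes), dtype=float)
    if isinstance(g, DirectedGraph):
        for (u, v) in g.arcs:
            a[u, v] = 1.0
    else:
        for (u, v) in g.edges:
            a[u, v] = 1.0
            a[v, u] = 1.0
    return a


def normalized_laplacian(g: UndirectedGraph) -> np.ndarray:
    """Normalized Laplacian L~ = D^{-1/2} (D - A) D^{-1/2}.

    Element-wise: 1 on the diagonal for non-isolated nodes,
    ``-1/sqrt(d_u d_v)`` where (u, v) is an edge, 0 elsewhere. Rows and
    columns of isolated nodes are all zero.
    """
    d = degree_vector(g)
    lap = np.zeros((g.n_nodes, g.n_nodes), dtype=float)
    for u in range(g.n_nodes):
        if d[u] > 0:
            lap[u, u] = 1.0
    for (u, v) in g.edges:
        w = -1.0 / np.sqrt(d[u] * d[v])
        lap[u, v] = w
        lap[v, u] = w
    return lap


def laplacian_spectrum(g: UndirectedGraph) -> LaplacianSpectrum:
    """Eigendecompose the normalized Laplacian.

    Eigenvalues are clipped at -1e-12 against round-off before forming the
    occupation probabilities, then floored at zero.
    """
    lap = normalized_laplacian(g)
    try:
        eig = np.linalg.eigvalsh(lap)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - numerical escape hatch
        raise RuntimeError(f"eigensolver failed to converge: {exc}") from exc
    if eig.size and eig[0] < -1e-12:
        warnings.warn(
            f"normalized-Laplacian eigenvalue {eig[0]:.3e} below zero; clipping",
            RuntimeWarning,
            stacklevel=2,
        )
    eig = np.clip(eig, 0.0, None)
    return LaplacianSpectrum(eigenvalues=np.sort(eig), n_nodes=g.n_nodes)
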