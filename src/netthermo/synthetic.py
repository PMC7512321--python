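"""Seeded generators: named graphs, random graphs, perturbation sequences
and correlated time-series panels.

Every stochastic operation takes an explicit integer seed and draws from
its own ``numpy.random.default_rng``; there is no global random state, so
identical seeds reproduce byte-identical outputs.

The two scheduled-event generators emulate, at desk scale, the dynamics the
thermodynamic framework is meant to expose:

* ``gen_event_sequence`` evolves a graph by independent edge flips (each
  absent pair appears, and each present edge disappears, with the scheduled
  flip probability) and applies a much larger flip rate at one scheduled
  step — an abrupt structural event against a background of gradual drift.
* ``gen_correlated_panel`` draws an equicorrelated Gaussian factor panel
  x_i(t) = sqrt(rho_t) f(t) + sqrt(1 - rho_t) eps_i(t) whose common
  correlation jumps from ``base_rho`` to ``event_rho`` inside the event
  interval — a correlation-regime shift of the kind financial crises
  produce in return panels.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .construction import TimeSeriesPanel
from .graph import (
    GraphValidationError,
    SnapshotSequence,
    UndirectedGraph,
    build_undirected_graph,
)

__all__ = [
    "EventSchedule",
    "PanelModel",
    "gen_named_graph",
    "gen_er_graph",
    "perturb_graph",
    "gen_event_sequence",
    "gen_correlated_panel",
    "enumerate_connected_graphs",
]


@dataclass
class EventSchedule:
    """A perturbation schedule with one implanted high-activity step.

    Snapshot ``t`` is obtained from snapshot ``t - 1`` by flipping each node
    pair independently with ``base_edge_flip_rate``, except at
    ``event_step`` where ``event_flip_rate`` applies. The event transition
    is therefore ``(event_step - 1) -> event_step`` (transition row index
    ``event_step - 1``).
    """

    length: int = 50
    base_edge_flip_rate: float = 0.005
    event_step: int = 25
    event_flip_rate: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.length < 2:
            raise GraphValidationError("schedule length must be >= 2")
        if not (1 <= self.event_step < self.length):
            raise GraphValidationError(
                f"event_step must lie in [1, length), got {self.event_step}"
            )
        for name in ("base_edge_flip_rate", "event_flip_rate"):
            r = getattr(self, name)
            if not (0.0 <= r <= 1.0):
                raise GraphValidationError(f"{name} must be in [0, 1], got {r}")
        if self.event_flip_rate <= self.base_edge_flip_rate:
            raise GraphValidationError(
                "event_flip_rate must exceed base_edge_flip_rate"
            )


@dataclass
class PanelModel:
    """An equicorrelated Gaussian factor panel with a correlation-regime shift."""

    n_series: int = 25
    length: int = 200
    base_rho: float = 0.1
    event_rho: float = 0.6
    event_interval: tuple = (100, 150)
    seed: int = 0

    def __post_init__(self):
        if self.n_series < 2 or self.length < 2:
            raise GraphValidationError("panel needs >= 2 series and >= 2 steps")
        for name in ("base_rho", "event_rho"):
            r = getattr(self, name)
            if not (0.0 <= r <= 1.0):
                raise GraphValidationError(f"{name} must be in [0, 1], got {r}")
        lo, hi = self.event_interval
        if not (0 <= lo < hi <= self.length):
            raise GraphValidationError(
                f"event_interval {self.event_interval} must satisfy "
                f"0 <= lo < hi <= length ({self.length})"
            )


def gen_named_graph(kind: str, n: int) -> UndirectedGraph:
    """Canonical labeled complete, path, star or cycle graph on n nodes."""
    if kind == "complete":
        if n < 2:
            raise GraphValidationError("complete graph needs n >= 2")
        pairs = combinations(range(n), 2)
    elif kind == "path":
        if n < 2:
            raise GraphValidationError("path graph needs n >= 2")
        pairs = ((i, i + 1) for i in range(n - 1))
    elif kind == "star":
        if n < 2:
            raise GraphValidationError("star graph needs n >= 2")
        pairs = ((0, i) for i in range(1, n))
    elif kind == "cycle":
        if n < 3:
            raise GraphValidationError("cycle graph needs n >= 3")
        pairs = [(i, i + 1) for i in range(n - 1)] + [(0, n - 1)]
    else:
        raise GraphValidationError(
            f"unknown graph kind {kind!r}; choose complete/path/star/cycle"
        )
    return build_undirected_graph(n, pairs)


def _pair_index_arrays(n: int):
    return np.triu_indices(n, k=1)


def _edges_to_mask(g: UndirectedGraph, iu, ju) -> np.ndarray:
    mask = np.zeros(iu.size, dtype=bool)
    if g.n_edges:
        edge_arr = np.array(sorted(g.edges), dtype=np.int64)
        # position of pair (u, v) among upper-triangle pairs, row-major
        n = g.n_nodes
        u, v = edge_arr[:, 0], edge_arr[:, 1]
        pos = (u * (2 * n - u - 1)) // 2 + (v - u - 1)
        mask[pos] = True
    return mask


def _mask_to_graph(n: int, mask: np.ndarray, iu, ju) -> UndirectedGraph:
    return UndirectedGraph(
        n_nodes=n,
        edges=frozenset(zip(iu[mask].tolist(), ju[mask].tolist())),
    )


def gen_er_graph(n: int, p: float, seed: int) -> UndirectedGraph:
    """Erdos-Renyi G(n, p): each pair is an edge independently with prob p."""
    if not (0.0 <= p <= 1.0):
        raise GraphValidationError(f"edge probability must be in [0, 1], got {p}")
    if n < 1:
        raise GraphValidationError(f"n must be positive, got {n}")
    rng = np.random.default_rng(seed)
    iu, ju = _pair_index_arrays(n)
    mask = rng.random(iu.size) < p
    return _mask_to_graph(n, mask, iu, ju)


def perturb_graph(g: UndirectedGraph, add_rate: float, remove_rate: float,
                  seed: int) -> UndirectedGraph:
    """Independently add absent pairs (add_rate) and drop edges (remove_rate)."""
    for name, r in (("add_rate", add_rate), ("remove_rate", remove_rate)):
        if not (0.0 <= r <= 1.0):
            raise GraphValidationError(f"{name} must be in [0, 1], got {r}")
    rng = np.random.default_rng(seed)
    iu, ju = _pair_index_arrays(g.n_nodes)
    mask = _edges_to_mask(g, iu, ju)
    u = rng.random(iu.size)
    new_mask = np.where(mask, u >= remove_rate, u < add_rate)
    return _mask_to_graph(g.n_nodes, new_mask, iu, ju)


def gen_event_sequence(schedule: EventSchedule,
                       base: UndirectedGraph | None = None) -> SnapshotSequence:
    """Evolve a base graph by scheduled edge flips (see :class:`EventSchedule`).

    The default base graph is Erdos-Renyi G(100, 0.1): sparse enough that
    background flips produce a steady, strictly positive edge-count drift,
    against which the event step's burst of flips stands out.
    """
    rng = np.random.default_rng(schedule.seed)
    if base is None:
        base = gen_er_graph(100, 0.1, seed=int(rng.integers(2**31)))
    graphs = [base]
    for t in range(1, schedule.length):
        rate = (schedule.event_flip_rate if t == schedule.event_step
                else schedule.base_edge_flip_rate)
        step_seed = int(rng.integers(2**31))
        graphs.append(perturb_graph(graphs[-1], add_rate=rate,
                                    remove_rate=rate, seed=step_seed))
    labels = [f"t{t:03d}" for t in range(schedule.length)]
    return SnapshotSequence(graphs=graphs, labels=labels)


def gen_correlated_panel(model: PanelModel) -> TimeSeriesPanel:
    """Draw the factor panel x_i(t) = sqrt(rho_t) f(t) + sqrt(1-rho_t) eps_i(t).

    f and eps are i.i.d. standard normal, so the population correlation
    between any two series at step t is exactly rho_t.
    """
    rng = np.random.default_rng(model.seed)
    f = rng.standard_normal(model.length)
    eps = rng.standard_normal((model.length, model.n_series))
    rho = np.full(model.length, model.base_rho)
    lo, hi = model.event_interval
    rho[lo:hi] = model.event_rho
    values = (np.sqrt(rho)[:, None] * f[:, None]
              + np.sqrt(1.0 - rho)[:, None] * eps)
    names = [f"s{i:02d}" for i in range(model.n_series)]
    return TimeSeriesPanel(values=values, names=names)


def enumerate_connected_graphs(n: int):
    """Yield every labeled connected graph on n nodes (exhaustive, n <= 6)."""
    if n < 2:
        raise GraphValidationError("enumeration needs n >= 2")
    if n > 6:
        raise GraphValidationError(
            f"exhaustive enumeration of 2^C({n},2) graphs is impractical; "
            "sample instead"
        )
    pairs = list(combinations(range(n), 2))
    m = len(pairs)
    for mask in range(1 << m):
        edges = [pairs[i] for i in range(m) if mask >> i & 1]
        # union-find connectivity over all n nodes
        parent = list(range(n))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for u, v in edges:
            ru, rv = find(u), find(v)
            if ru != rv:
                parent[ru] = rv
        if len({find(x) for x in range(n)}) == 1:
            yield UndirectedGraph(n_nodes=n, edges=frozenset(edges))
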