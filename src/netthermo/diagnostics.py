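"""Thermodynamic trajectories and degree-change diagnostics.

``thermo_trajectory`` evaluates entropy H, internal energy U and the
inter-snapshot temperature along a snapshot sequence and returns tidy
per-snapshot / per-transition tables. ``degree_change_table`` and
``degree_change_variance_profile`` expose the (d_u, delta_v) correlation
structure that drives the temperature: strongly correlated degree changes
mean low temperature, disrupted correlations mean high temperature.
``assortativity_coefficient`` and ``estrada_index`` are the two classical
baseline indices the thermodynamic variables are compared against.

No automated change-point rule is imposed: ``rank_transitions`` orders
transitions by |1/T| (then |dH|) and leaves thresholds to the user.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

from . import directed as thdir
from . import entropy as th
from .graph import (
    DirectedGraph,
    GraphValidationError,
    SnapshotSequence,
    UndirectedGraph,
    adjacency_matrix,
    degree_vector,
)

__all__ = [
    "TrajectoryTable",
    "thermo_trajectory",
    "rank_transitions",
    "degree_change_table",
    "degree_change_variance_profile",
    "assortativity_coefficient",
    "estrada_index",
]

_STATE_COLUMNS = ["label", "H", "U"]
_TRANSITION_COLUMNS = ["label_from", "label_to", "dH", "dU", "invT", "T",
                       "mode", "degenerate"]


class TrajectoryTable:
    """Per-snapshot states and per-transition measures as DataFrames."""

    def __init__(self, states: pd.DataFrame, transitions: pd.DataFrame,
                 directed: bool):
        self.states = states
        self.transitions = transitions
        self.directed = directed

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"TrajectoryTable({len(self.states)} snapshots, "
                f"{len(self.transitions)} transitions, directed={self.directed})")


def _directed_mode(mode: str) -> str:
    return "exact" if mode == "exact" else "printed_first_order"


def thermo_trajectory(seq: SnapshotSequence, mode: str = "printed",
                      variant: str = "printed") -> TrajectoryTable:
    """Entropy/energy per snapshot and temperature per transition.

    Undirected sequences use ``entropy_degree_form(variant)`` and
    ``inverse_temperature(mode)``; directed sequences dispatch to the
    directed entropy (``mode`` maps onto {printed_first_order, exact}).
    """
    if seq.directed:
        h = [thdir.directed_entropy(g) for g in seq.graphs]
        u = [g.n_arcs for g in seq.graphs]
        dmode = _directed_mode(mode)
        trans = [
            thdir.directed_inverse_temperature(a, b, mode=dmode)
            for a, b in zip(seq.graphs[:-1], seq.graphs[1:])
        ]
    else:
        h = [th.entropy_degree_form(g, variant=variant) for g in seq.graphs]
        u = [th.internal_energy(g) for g in seq.graphs]
        trans = [
            th.inverse_temperature(a, b, mode=mode)
            for a, b in zip(seq.graphs[:-1], seq.graphs[1:])
        ]

    states = pd.DataFrame({"label": seq.labels, "H": h, "U": u},
                          columns=_STATE_COLUMNS)
    transitions = pd.DataFrame(
        [
            {
                "label_from": seq.labels[i],
                "label_to": seq.labels[i + 1],
                "dH": t.dH,
                "dU": t.dU,
                "invT": t.inverse_temperature,
                "T": t.temperature,
                "mode": t.mode,
                "degenerate": t.degenerate,
            }
            for i, t in enumerate(trans)
        ],
        columns=_TRANSITION_COLUMNS,
    )
    return TrajectoryTable(states=states, transitions=transitions,
                           directed=seq.directed)


def rank_transitions(table: TrajectoryTable) -> pd.DataFrame:
    """Transitions ordered by |1/T| descending, ties by |dH| descending."""
    t = table.transitions.copy()
    t["abs_invT"] = t["invT"].abs()
    t["abs_dH"] = t["dH"].abs()
    return t.sort_values(["abs_invT", "abs_dH"], ascending=False,
                         kind="stable").reset_index(drop=True)


def degree_change_table(g: UndirectedGraph, g2: UndirectedGraph) -> pd.DataFrame:
    """Rows (u, v, d_u, delta_v) for both orientations of each surviving edge.

    Degrees come from the earlier snapshot; deltas are later - earlier.
    """
    if g.n_nodes != g2.n_nodes:
        raise GraphValidationError(
            f"snapshots have different node counts ({g.n_nodes} vs {g2.n_nodes})"
        )
    d = degree_vector(g)
    delta = degree_vector(g2) - d
    rows = []
    for (u, v) in sorted(g.edges & g2.edges):
        rows.append((u, v, int(d[u]), int(delta[v])))
        rows.append((v, u, int(d[v]), int(delta[u])))
    return pd.DataFrame(rows, columns=["u", "v", "d_u", "delta_v"])


def degree_change_variance_profile(table: pd.DataFrame,
                                   bin_width: int | None = None) -> dict:
    """Population variance of delta_v grouped by d_u.

    By default the grouping is by exact degree value; ``bin_width`` groups
    degrees into [0, w), [w, 2w), ... bins keyed by the bin's lower edge
    (useful on large graphs). Degrees seen once report variance 0.
    """
    if table.empty:
        return {}
    key = table["d_u"] if bin_width is None else (table["d_u"] // bin_width) * bin_width
    grouped = table.groupby(key)["delta_v"].var(ddof=0)
    return {int(k): float(v) for k, v in grouped.items()}


def assortativity_coefficient(g: UndirectedGraph) -> float:
    """Degree assortativity: Pearson correlation of endpoint degrees.

    Computed over the 2|E| ordered edge stubs. Regular graphs have zero
    stub-degree variance and return NaN with a warning; a graph with no
    edges raises.
    """
    if g.n_edges == 0:
        raise GraphValidationError("assortativity is undefined for an empty graph")
    d = degree_vector(g)
    x = np.empty(2 * g.n_edges, dtype=float)
    y = np.empty(2 * g.n_edges, dtype=float)
    for i, (u, v) in enumerate(g.edges):
        x[2 * i], y[2 * i] = d[u], d[v]
        x[2 * i + 1], y[2 * i + 1] = d[v], d[u]
    if x.std() == 0.0:
        warnings.warn(
            "all edge endpoints have equal degree (regular graph); "
            "assortativity is undefined (NaN)",
            RuntimeWarning,
            stacklevel=2,
        )
        return math.nan
    xm = x - x.mean()
    ym = y - y.mean()
    return float((xm @ ym) / (np.sqrt(xm @ xm) * np.sqrt(ym @ ym)))


def estrada_index(g: UndirectedGraph) -> float:
    """Estrada index: sum of exp(mu) over adjacency eigenvalues mu."""
    mu = np.linalg.eigvalsh(adjacency_matrix(g))
    return float(np.sum(np.exp(mu)))
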