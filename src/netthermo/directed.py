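"""Entropy and temperature for graphs made entirely of unidirectional arcs.

The directed von Neumann entropy approximation applies to graphs with no
bidirectional node pairs:

    H_D = 1 - 1/n - (1/n^2) * sum_{(u,v) in E_D} d_u^in / ((d_u^out)^2 d_v^in)

Arcs leaving a node with zero in-degree contribute nothing; the out-degree
of the terminal node never appears (the term is determined by the causal
past, not the future, of the arc's head). Internal energy for directed
snapshots is taken as the arc count U = |E_D|, by analogy with the
undirected case (the published framework does not define it explicitly).

The first-order entropy change between two such snapshots is emitted
verbatim as published. Note the convention: the exact differential of H_D
is -(1/n^2) times the published per-arc terms, so ``printed_first_order``
values differ from ``exact`` differences by the overall sign and the 1/n^2
prefactor; both modes are provided.
"""

from __future__ import annotations

import math
import warnings

from .graph import DirectedGraph, GraphValidationError, in_out_degrees
from .entropy import TransitionMeasures

__all__ = [
    "directed_entropy",
    "directed_entropy_change",
    "directed_inverse_temperature",
]

_MODES = ("printed_first_order", "exact")


def _validate_unidirectional(g: DirectedGraph) -> None:
    pair = g.has_bidirectional_pair()
    if pair is not None:
        raise GraphValidationError(
            f"arcs {pair} and {(pair[1], pair[0])} are both present; the "
            "directed entropy applies only to graphs with no bidirectional edges"
        )


def directed_entropy(g: DirectedGraph) -> float:
    """Approximate von Neumann entropy of a unidirectional directed graph."""
    _validate_unidirectional(g)
    din, dout = in_out_degrees(g)
    n = g.n_nodes
    total = 0.0
    for (u, v) in g.arcs:
        # d_u^out >= 1 and d_v^in >= 1 are guaranteed by the arc itself.
        if din[u] == 0:
            continue
        total += din[u] / (dout[u] ** 2 * din[v])
    return 1.0 - 1.0 / n - total / (n * n)


def _check_pair(g: DirectedGraph, g2: DirectedGraph) -> None:
    if g.n_nodes != g2.n_nodes:
        raise GraphValidationError(
            f"snapshots have different node counts ({g.n_nodes} vs {g2.n_nodes})"
        )
    _validate_unidirectional(g)
    _validate_unidirectional(g2)


def directed_entropy_change(
    g: DirectedGraph, g2: DirectedGraph, mode: str = "printed_first_order"
) -> float:
    """Entropy change between directed snapshots g -> g2.

    ``printed_first_order`` sums, over arcs surviving in both snapshots,

        (d_u^out d_v^in D_u^in - 2 d_u^in d_v^in D_u^out - d_u^in d_u^out D_v^in)
        / ((d_u^out)^3 (d_v^in)^2)

    exactly as published (no sign flip, no 1/n^2 prefactor). ``exact``
    returns directed_entropy(g2) - directed_entropy(g).
    """
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {_MODES}, got {mode!r}")
    _check_pair(g, g2)
    if mode == "exact":
        return directed_entropy(g2) - directed_entropy(g)

    din, dout = in_out_degrees(g)
    din2, dout2 = in_out_degrees(g2)
    d_in = din2 - din
    d_out = dout2 - dout
    total = 0.0
    for (u, v) in g.arcs & g2.arcs:
        # surviving arcs guarantee dout[u] >= 1 and din[v] >= 1 in g
        num = (
            dout[u] * din[v] * d_in[u]
            - 2 * din[u] * din[v] * d_out[u]
            - din[u] * dout[u] * d_in[v]
        )
        total += num / (dout[u] ** 3 * din[v] ** 2)
    return float(total)


def directed_inverse_temperature(
    g: DirectedGraph, g2: DirectedGraph, mode: str = "printed_first_order"
) -> TransitionMeasures:
    """1/T = dH_D / d|E_D|, with the same degeneracy handling as undirected."""
    dh = directed_entropy_change(g, g2, mode=mode)
    du = g2.n_arcs - g.n_arcs
    if du == 0:
        if dh == 0.0:
            warnings.warn(
                "transition changes neither entropy nor arc count; "
                "temperature is undefined (NaN)",
                RuntimeWarning,
                stacklevel=2,
            )
            inv_t = math.nan
            temp = math.nan
        else:
            inv_t = math.copysign(math.inf, dh)
            temp = 0.0
        return TransitionMeasures(dH=dh, dU=0, inverse_temperature=inv_t,
                                  temperature=temp, mode=mode, degenerate=True)
    inv_t = dh / du
    temp = math.inf if dh == 0.0 else du / dh
    return TransitionMeasures(dH=dh, dU=int(du), inverse_temperature=inv_t,
                              temperature=temp, mode=mode, degenerate=False)
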