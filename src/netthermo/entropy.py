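"""Entropy, internal energy and temperature for undirected snapshots.

The von Neumann entropy of a graph is the Shannon entropy of the scaled
normalized-Laplacian eigenvalues p_s = lambda_s / |V| (Boltzmann constant
k = 1, so entropies are in nats). Three computable forms are provided:

``entropy_spectral_exact``
    -sum p_s ln p_s over the spectrum (0 ln 0 = 0).
``entropy_spectral_quadratic``
    the quadratic approximation sum p_s (1 - p_s), equal to
    Tr[L~]/|V| - Tr[L~^2]/|V|^2.
``entropy_degree_form``
    the degree-statistics form 1 - 1/|V| - c/|V|^2 * sum_{(u,v) in E}
    1/(d_u d_v). Two variants are exposed because the literature's printed
    coefficient is c = 1 over unordered edges while the exact expansion of
    the quadratic form gives c = 2. The ``printed`` variant (default) keeps
    every downstream closed form, bound and temperature formula internally
    consistent; ``spectral_consistent`` reproduces the quadratic spectral
    entropy exactly on graphs without isolated nodes.

Internal energy is the edge count U = |E|. The reciprocal temperature of a
transition between consecutive snapshots is 1/T = dH/dU, with dH computed
either from the printed degree-fluctuation formula, its first-order
simplification, or as the exact difference of degree-form entropies.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .graph import (
    GraphValidationError,
    LaplacianSpectrum,
    UndirectedGraph,
    degree_vector,
)

__all__ = [
    "ThermoState",
    "TransitionMeasures",
    "entropy_spectral_exact",
    "entropy_spectral_quadratic",
    "entropy_degree_form",
    "entropy_bounds",
    "internal_energy",
    "entropy_change",
    "inverse_temperature",
]

_VARIANTS = ("printed", "spectral_consistent")
_MODES = ("printed", "first_order", "exact")


@dataclass(frozen=True)
class ThermoState:
    """Per-snapshot entropy H (nats) and internal energy U = |E|."""

    entropy: float
    internal_energy: int
    method: str


@dataclass(frozen=True)
class TransitionMeasures:
    """Entropy/energy changes and temperature between consecutive snapshots.

    ``degenerate`` marks edge-count-preserving transitions (dU = 0), where
    the ratio dH/dU is a signed infinity (dH != 0) or undefined (dH = 0).
    """

    dH: float
    dU: int
    inverse_temperature: float
    temperature: float
    mode: str
    degenerate: bool


def _warn_isolated(g: UndirectedGraph, context: str) -> None:
    if g.has_isolated_nodes():
        warnings.warn(
            f"{context}: graph has isolated nodes, so Tr[L~] < |V| and the "
            "degree-form entropy approximation degrades",
            RuntimeWarning,
            stacklevel=3,
        )


def entropy_spectral_exact(s: LaplacianSpectrum) -> float:
    """Exact von Neumann entropy -sum p ln p with 0 ln 0 = 0."""
    p = s.occupations
    p = p[p > 0.0]
    if p.size == 0:
        return 0.0
    return float(-np.sum(p * np.log(p)))


def entropy_spectral_quadratic(s: LaplacianSpectrum) -> float:
    """Quadratic approximation sum p (1 - p) of the spectral entropy."""
    p = s.occupations
    return float(np.sum(p * (1.0 - p)))


def entropy_degree_form(g: UndirectedGraph, variant: str = "printed") -> float:
    """Degree-statistics entropy 1 - 1/n - c/n^2 * sum_E 1/(d_u d_v).

    ``variant='printed'`` uses c = 1 (the published coefficient, consistent
    with the K_n/P_n closed forms and the temperature formulas);
    ``variant='spectral_consistent'`` uses c = 2, matching
    :func:`entropy_spectral_quadratic` on graphs without isolated nodes.
    """
    if variant not in _VARIANTS:
        raise ValueError(f"variant must be one of {_VARIANTS}, got {variant!r}")
    _warn_isolated(g, "entropy_degree_form")
    n = g.n_nodes
    d = degree_vector(g)
    total = 0.0
    for (u, v) in g.edges:
        total += 1.0 / (d[u] * d[v])
    coeff = 1.0 if variant == "printed" else 2.0
    return 1.0 - 1.0 / n - coeff * total / (n * n)


def entropy_bounds(n: int) -> tuple:
    """(lower, upper) degree-form entropy bounds for connected graphs on n nodes.

    The lower bound 1 - (5n+1)/(4n^2) is attained by the path P_n, the upper
    bound 1 - (2n-1)/(2n(n-1)) by the complete graph K_n. Requires n >= 3
    (the path closed form assumes two degree-1 ends and a degree-2 interior).
    """
    if n < 3:
        raise GraphValidationError(f"entropy bounds require n >= 3, got {n}")
    lower = 1.0 - (5.0 * n + 1.0) / (4.0 * n * n)
    upper = 1.0 - (2.0 * n - 1.0) / (2.0 * n * (n - 1.0))
    return lower, upper


def internal_energy(g: UndirectedGraph) -> int:
    """Internal energy U = |E| (total number of edges)."""
    return g.n_edges


def thermo_state(g: UndirectedGraph, variant: str = "printed") -> ThermoState:
    """Entropy and internal energy of a single snapshot."""
    return ThermoState(
        entropy=entropy_degree_form(g, variant=variant),
        internal_energy=internal_energy(g),
        method=f"degree_form_{variant}",
    )


def _check_same_n(g: UndirectedGraph, g2: UndirectedGraph) -> None:
    if g.n_nodes != g2.n_nodes:
        raise GraphValidationError(
            f"snapshots have different node counts ({g.n_nodes} vs {g2.n_nodes}); "
            "the framework assumes a fixed node set"
        )


def entropy_change(g: UndirectedGraph, g2: UndirectedGraph, mode: str = "printed") -> float:
    """Entropy change dH between consecutive snapshots g -> g2.

    ``printed``
        sum over surviving edges (u,v) in E & E' of
        (d_u D_v + d_v D_u + D_u D_v) / (d_u (d_u+D_u) d_v (d_v+D_v))
        with D_u = d'_u - d_u, exactly as published (no 1/n^2 prefactor).
    ``first_order``
        sum over E & E' of (d_u D_v + d_v D_u) / (d_u^2 d_v^2), valid when
        degree changes are small against the degrees.
    ``exact``
        entropy_degree_form(g2) - entropy_degree_form(g) (printed variant).

    The fluctuation sums run over the surviving edges E & E' — the only
    domain where both d and d + D denominators are guaranteed positive;
    edges present in a single snapshot are accounted for exactly only in
    ``exact`` mode.
    """
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {_MODES}, got {mode!r}")
    _check_same_n(g, g2)

    if mode == "exact":
        return entropy_degree_form(g2, "printed") - entropy_degree_form(g, "printed")

    d = degree_vector(g)
    d2 = degree_vector(g2)
    delta = d2 - d
    common = g.edges & g2.edges
    total = 0.0
    if mode == "printed":
        for (u, v) in common:
            du, dv, au, av = d[u], d[v], delta[u], delta[v]
            total += (du * av + dv * au + au * av) / (
                du * (du + au) * dv * (dv + av)
            )
    else:  # first_order
        for (u, v) in common:
            du, dv, au, av = d[u], d[v], delta[u], delta[v]
            total += (du * av + dv * au) / (du * du * dv * dv)
    return float(total)


def inverse_temperature(
    g: UndirectedGraph, g2: UndirectedGraph, mode: str = "printed"
) -> TransitionMeasures:
    """Reciprocal temperature 1/T = dH / d|E| for the transition g -> g2.

    Edge-count-preserving transitions (dU = 0) are reported as degenerate
    rather than raising: 1/T is a signed infinity and T = 0 when dH != 0,
    and both are NaN (with a warning) when dH = 0 as well.
    """
    dh = entropy_change(g, g2, mode=mode)
    du = internal_energy(g2) - internal_energy(g)
    if du == 0:
        if dh == 0.0:
            warnings.warn(
                "transition changes neither entropy nor edge count; "
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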