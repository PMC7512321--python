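"""Sliding-window correlation networks from multivariate time-series panels.

The recipe mirrors the standard stock-market construction: slide a trailing
window (default 28 steps) along the panel, compute pairwise absolute
cross-correlations inside each window, and connect the top fraction
(default 5%) of node pairs. Every snapshot therefore has the same node set
and exactly ``floor(retain_fraction * C(N, 2))`` edges.

Window convention: the window labelled ``t`` (1-based step numbering)
covers steps ``t - window .. t - 1``, so a panel of T steps with step 1
yields ``T - window`` snapshots labelled ``window + 1 .. T`` — e.g. 6004
daily returns with a 28-day window give 5976 networks labelled Day 29
through Day 6004.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .graph import GraphValidationError, SnapshotSequence, UndirectedGraph

__all__ = [
    "TimeSeriesPanel",
    "CorrNetConfig",
    "sliding_windows",
    "window_correlations",
    "threshold_top_fraction",
    "build_dynamic_network",
    "log_returns",
]


@dataclass
class TimeSeriesPanel:
    """A T x N panel of real-valued series (rows = time steps)."""

    values: np.ndarray
    names: list

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise GraphValidationError("panel values must be a 2-D matrix")
        if self.values.shape[0] < 2:
            raise GraphValidationError("panel needs at least two time steps")
        if np.isnan(self.values).any():
            raise GraphValidationError(
                "panel contains missing values; resolve them upstream"
            )
        if len(self.names) != self.values.shape[1]:
            raise GraphValidationError(
                f"{len(self.names)} names for {self.values.shape[1]} series"
            )

    @property
    def n_steps(self) -> int:
        return self.values.shape[0]

    @property
    def n_series(self) -> int:
        return self.values.shape[1]


@dataclass
class CorrNetConfig:
    """Parameters of the correlation-network construction."""

    window: int = 28
    step: int = 1
    retain_fraction: float = 0.05
    lag_range: int = 0
    tie_policy: str = "rank_stable"
    use_log_returns: bool = False

    def __post_init__(self):
        if self.window < 2:
            raise GraphValidationError(f"window must be >= 2, got {self.window}")
        if self.step < 1:
            raise GraphValidationError(f"step must be positive, got {self.step}")
        if not (0.0 < self.retain_fraction <= 1.0):
            raise GraphValidationError(
                f"retain_fraction must be in (0, 1], got {self.retain_fraction}"
            )
        if self.lag_range < 0:
            raise GraphValidationError(f"lag_range must be >= 0, got {self.lag_range}")
        if self.tie_policy != "rank_stable":
            raise GraphValidationError(f"unknown tie policy {self.tie_policy!r}")


def log_returns(panel: TimeSeriesPanel) -> TimeSeriesPanel:
    """Log-returns ln(x_t / x_{t-1}) of a strictly positive panel."""
    if np.any(panel.values <= 0):
        raise GraphValidationError("log returns require strictly positive values")
    return TimeSeriesPanel(values=np.diff(np.log(panel.values), axis=0),
                           names=list(panel.names))


def sliding_windows(panel: TimeSeriesPanel, window: int, step: int = 1):
    """Split a panel into trailing windows.

    Returns a list of ``(label, sub_matrix)`` pairs where ``label`` is the
    1-based step the window trails (covering steps label-window..label-1)
    and ``sub_matrix`` is the window x N value slice.
    """
    t_total = panel.n_steps
    if window >= t_total:
        raise GraphValidationError(
            f"window ({window}) must be shorter than the panel ({t_total} steps)"
        )
    out = []
    for label in range(window + 1, t_total + 1, step):
        start = label - window - 1  # 0-based row of step label-window
        out.append((label, panel.values[start:start + window, :]))
    return out


def window_correlations(sub_panel: np.ndarray, lag_range: int = 0) -> np.ndarray:
    """N x N matrix of maximum absolute Pearson correlation over lags.

    Entry (i, j) is max over lags in [-lag_range, lag_range] of
    |r(x_i shifted by the lag, x_j)|. The diagonal is 1. Pairs involving a
    constant series are set to 0 with a warning.
    """
    sub_panel = np.asarray(sub_panel, dtype=float)
    w, n = sub_panel.shape
    if w < 3:
        raise GraphValidationError(f"window length must be >= 3, got {w}")
    if lag_range >= w - 2:
        raise GraphValidationError(
            f"lag_range {lag_range} leaves fewer than 3 overlapping steps"
        )

    constant = sub_panel.std(axis=0) == 0.0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant series in window; their "
            "correlations are set to 0",
            RuntimeWarning,
            stacklevel=2,
        )

    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.abs(np.corrcoef(sub_panel, rowvar=False))
    corr = np.nan_to_num(corr, nan=0.0)

    for lag in range(1, lag_range + 1):
        a = sub_panel[lag:, :]
        b = sub_panel[:-lag, :]
        # r(x_i lagged, x_j) for all pairs; both lag signs via the transpose
        am = a - a.mean(axis=0)
        bm = b - b.mean(axis=0)
        sa = am.std(axis=0)
        sb = bm.std(axis=0)
        denom = np.outer(sa, sb) * a.shape[0]
        with np.errstate(invalid="ignore", divide="ignore"):
            cross = np.abs(am.T @ bm) / denom
        cross = np.nan_to_num(cross, nan=0.0)
        corr = np.maximum(corr, np.maximum(cross, cross.T))

    np.fill_diagonal(corr, 1.0)
    corr[constant, :] = 0.0
    corr[:, constant] = 0.0
    np.fill_diagonal(corr, 1.0)
    return corr


def threshold_top_fraction(corr: np.ndarray, retain_fraction: float) -> UndirectedGraph:
    """Keep exactly floor(retain_fraction * C(N,2)) strongest node pairs.

    Ties are broken by descending |r| then ascending lexicographic pair
    index, so the selection is deterministic.
    """
    corr = np.asarray(corr, dtype=float)
    n = corr.shape[0]
    if corr.shape != (n, n) or not np.allclose(corr, corr.T, atol=1e-12):
        raise GraphValidationError("correlation matrix must be square and symmetric")
    n_pairs = n * (n - 1) // 2
    k = math.floor(retain_fraction * n_pairs)
    if k < 1:
        raise GraphValidationError(
            f"retain_fraction {retain_fraction} keeps zero of {n_pairs} pairs"
        )
    iu, ju = np.triu_indices(n, k=1)
    strength = np.abs(corr[iu, ju])
    # stable sort on (-|r|, u, v): lexsort with last key most significant
    order = np.lexsort((ju, iu, -strength))[:k]
    return UndirectedGraph(
        n_nodes=n,
        edges=frozenset((int(iu[o]), int(ju[o])) for o in order),
    )


def build_dynamic_network(panel: TimeSeriesPanel, cfg: CorrNetConfig | None = None
                          ) -> SnapshotSequence:
    """Panel -> snapshot sequence of thresholded correlation networks."""
    if cfg is None:
        cfg = CorrNetConfig()
    if cfg.use_log_returns:
        panel = log_returns(panel)
    windows = sliding_windows(panel, cfg.window, cfg.step)
    graphs = []
    labels = []
    for label, sub in windows:
        corr = window_correlations(sub, lag_range=cfg.lag_range)
        graphs.append(threshold_top_fraction(corr, cfg.retain_fraction))
        labels.append(str(label))
    return SnapshotSequence(graphs=graphs, labels=labels,
                            node_names=list(panel.names))
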