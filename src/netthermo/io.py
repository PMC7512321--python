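"""Edge-list, snapshot-directory, temporal edge-list and panel I/O.

Edge-list dialect (TSV / whitespace-separated):

* ``#`` starts a comment (whole line),
* an optional ``%n <count>`` header declares the node count, which lets
  empty snapshots and trailing isolated nodes round-trip,
* data rows are ``u v`` (order significant for directed graphs).

A snapshot directory holds one edge-list file per snapshot; lexicographic
filename order is time order. An optional ``nodes.txt`` (one label per line)
persists the mapping from external string labels to integer indices.

A temporal edge list has rows ``t u v``; snapshots are the distinct ``t``
values in ascending order.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .graph import (
    DirectedGraph,
    GraphValidationError,
    SnapshotSequence,
    UndirectedGraph,
    build_directed_graph,
    build_undirected_graph,
)

__all__ = [
    "read_edgelist",
    "write_edgelist",
    "read_snapshots",
    "write_snapshots",
    "read_panel",
    "write_panel",
]

_NODES_FILE = "nodes.txt"
_MANIFEST_FILE = "manifest.json"


def _parse_edgelist_lines(lines, path):
    """Return (declared_n or None, list of token rows)."""
    declared_n = None
    rows = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("%n"):
            try:
                declared_n = int(line.split()[1])
            except (IndexError, ValueError):
                raise GraphValidationError(
                    f"{path}:{lineno}: malformed %n header {raw.strip()!r}"
                )
            continue
        tokens = line.split()
        rows.append((lineno, tokens))
    return declared_n, rows


def read_edgelist(path, directed: bool = False, n_nodes: int | None = None,
                  label_map: dict | None = None):
    """Read one edge-list file into a graph.

    ``n_nodes`` overrides the ``%n`` header; with neither, the node count is
    ``max index + 1``. ``label_map`` maps string node labels to indices (for
    files that use names instead of integers).
    """
    path = Path(path)
    declared_n, rows = _parse_edgelist_lines(path.read_text().splitlines(), path)
    if n_nodes is not None and declared_n is not None and n_nodes != declared_n:
        raise GraphValidationError(
            f"{path}: declared %n {declared_n} conflicts with expected {n_nodes}"
        )
    n = n_nodes if n_nodes is not None else declared_n

    pairs = []
    for lineno, tokens in rows:
        if len(tokens) != 2:
            raise GraphValidationError(
                f"{path}:{lineno}: expected 'u v', got {' '.join(tokens)!r}"
            )
        try:
            if label_map is not None:
                u, v = label_map[tokens[0]], label_map[tokens[1]]
            else:
                u, v = int(tokens[0]), int(tokens[1])
        except (KeyError, ValueError) as exc:
            raise GraphValidationError(f"{path}:{lineno}: unknown node {exc}") from exc
        pairs.append((u, v))

    if n is None:
        n = max((max(u, v) for u, v in pairs), default=-1) + 1
        if n == 0:
            raise GraphValidationError(
                f"{path}: empty edge list with no %n header; node count unknown"
            )
    builder = build_directed_graph if directed else build_undirected_graph
    return builder(n, pairs)


def write_edgelist(g, path, node_names=None) -> None:
    """Write a graph as an edge list with a ``%n`` header."""
    path = Path(path)
    pairs = sorted(g.arcs) if isinstance(g, DirectedGraph) else sorted(g.edges)
    with path.open("w") as fh:
        fh.write(f"%n {g.n_nodes}\n")
        for u, v in pairs:
            if node_names is not None:
                fh.write(f"{node_names[u]}\t{node_names[v]}\n")
            else:
                fh.write(f"{u}\t{v}\n")


def _read_snapshot_dir(source: Path, directed: bool) -> SnapshotSequence:
    files = sorted(
        p for p in source.iterdir()
        if p.is_file() and p.name not in (_NODES_FILE, _MANIFEST_FILE)
        and p.suffix not in (".json", ".csv", ".png", ".svg")
        and not p.name.startswith(".")
    )
    if not files:
        raise GraphValidationError(f"{source}: no snapshot files found")

    node_names = None
    label_map = None
    nodes_path = source / _NODES_FILE
    if nodes_path.exists():
        node_names = [ln.strip() for ln in nodes_path.read_text().splitlines() if ln.strip()]
        label_map = {name: i for i, name in enumerate(node_names)}

    # First pass: establish one shared node universe.
    declared = []
    parsed = []
    for p in files:
        declared_n, rows = _parse_edgelist_lines(p.read_text().splitlines(), p)
        declared.append(declared_n)
        parsed.append(rows)

    if label_map is not None:
        n = len(node_names)
        for p, dn in zip(files, declared):
            if dn is not None and dn != n:
                raise GraphValidationError(
                    f"{p}: declared %n {dn} conflicts with {_NODES_FILE} ({n} nodes)"
                )
    else:
        stated = {dn for dn in declared if dn is not None}
        if len(stated) > 1:
            raise GraphValidationError(
                f"{source}: snapshot files declare inconsistent node counts {sorted(stated)}"
            )
        if stated:
            n = stated.pop()
        else:
            n = 0
            for rows in parsed:
                for _, tokens in rows:
                    n = max(n, int(tokens[0]) + 1, int(tokens[1]) + 1)
            if n == 0:
                raise GraphValidationError(
                    f"{source}: cannot infer a node universe (no %n headers, no edges)"
                )

    graphs = [
        read_edgelist(p, directed=directed, n_nodes=n, label_map=label_map)
        for p in files
    ]
    return SnapshotSequence(graphs=graphs, labels=[p.stem for p in files],
                            node_names=node_names)


def _read_temporal_file(source: Path, directed: bool) -> SnapshotSequence:
    declared_n, rows = _parse_edgelist_lines(source.read_text().splitlines(), source)
    by_t: dict = {}
    for lineno, tokens in rows:
        if len(tokens) != 3:
            raise GraphValidationError(
                f"{source}:{lineno}: expected 't u v', got {' '.join(tokens)!r}"
            )
        try:
            t, u, v = int(tokens[0]), int(tokens[1]), int(tokens[2])
        except ValueError:
            raise GraphValidationError(f"{source}:{lineno}: non-integer row")
        by_t.setdefault(t, []).append((u, v))
    if not by_t:
        raise GraphValidationError(f"{source}: temporal edge list holds no rows")
    n = declared_n
    if n is None:
        n = 1 + max(max(u, v) for pairs in by_t.values() for u, v in pairs)
    builder = build_directed_graph if directed else build_undirected_graph
    ts = sorted(by_t)
    graphs = [builder(n, by_t[t]) for t in ts]
    return SnapshotSequence(graphs=graphs, labels=[str(t) for t in ts])


def read_snapshots(source, directed: bool = False) -> SnapshotSequence:
    """Read a snapshot sequence from a directory or a temporal edge list."""
    source = Path(source)
    if not source.exists():
        raise GraphValidationError(f"{source}: no such file or directory")
    if source.is_dir():
        return _read_snapshot_dir(source, directed)
    return _read_temporal_file(source, directed)


def write_snapshots(seq: SnapshotSequence, outdir, manifest: dict | None = None) -> None:
    """Write one edge-list file per snapshot plus optional manifest JSON.

    Filenames are zero-padded so that lexicographic order preserves the
    sequence order regardless of label content.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    width = max(4, len(str(len(seq) - 1)))
    for i, (g, label) in enumerate(zip(seq.graphs, seq.labels)):
        write_edgelist(g, outdir / f"s{i:0{width}d}_{label}.tsv",
                       node_names=seq.node_names)
    if seq.node_names is not None:
        (outdir / _NODES_FILE).write_text("\n".join(seq.node_names) + "\n")
    if manifest is not None:
        (outdir / _MANIFEST_FILE).write_text(json.dumps(manifest, indent=2, sort_keys=True))


def read_panel(path):
    """Read a multivariate time-series panel from CSV.

    First row: series names. Subsequent rows: time steps. If the first
    column is non-numeric it is treated as a timestamp index and dropped
    from the value matrix.
    """
    from .construction import TimeSeriesPanel

    df = pd.read_csv(path)
    if df.shape[1] >= 2 and not np.issubdtype(df.dtypes.iloc[0], np.number):
        df = df.set_index(df.columns[0])
    values = df.to_numpy(dtype=float)
    return TimeSeriesPanel(values=values, names=list(df.columns))


def write_panel(panel, path, timestamps=None) -> None:
    """Write a panel to CSV (optionally with a leading timestamp column)."""
    df = pd.DataFrame(panel.values, columns=panel.names)
    if timestamps is not None:
        df.insert(0, "t", timestamps)
        df.to_csv(path, index=False)
    else:
        df.to_csv(path, index=False)
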