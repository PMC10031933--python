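"""Undirected, unweighted interaction networks.

A :class:`Network` is an immutable view over an ordered list of string node
identifiers and a set of undirected edges between them.  The adjacency matrix
is symmetric and has no self-loops; the public API speaks in node identifiers,
index bookkeeping is internal.

Three edge-list dialects are readable: plain two-column lists, STRING-style
tables with per-channel confidence scores, and BioGRID TAB3-style tables
(official symbol columns).
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp

from .errors import EmptyNetworkError, InputError, MalformedRowError, NetwarpWarning

__all__ = [
    "Network",
    "read_edge_list",
    "write_edge_list",
    "restrict_to_nodes",
    "largest_connected_component",
]

#: Default column names for the STRING dialect; override via ``column_map``.
STRING_COLUMNS = {
    "node1": "protein1",
    "node2": "protein2",
    "experimental": "experimental",
    "combined": "combined_score",
}

#: Column names used by the BioGRID TAB3 dialect.
BIOGRID_COLUMNS = {
    "node1": "Official Symbol Interactor A",
    "node2": "Official Symbol Interactor B",
}


class Network:
    """An undirected unweighted graph over opaque string node identifiers.

    Parameters
    ----------
    node_ids:
        Unique node identifiers; their order defines the index used by all
        matrix/vector representations produced from this network.
    edges:
        Iterable of ``(u, v)`` identifier pairs.  Orientation is ignored,
        duplicates are merged, and self-loops are dropped silently.
    """

    def __init__(self, node_ids: Sequence[str], edges: Iterable[tuple[str, str]]):
        ids = list(node_ids)
        if len(set(ids)) != len(ids):
            raise InputError("duplicate node identifiers")
        self._ids: list[str] = ids
        self._index: dict[str, int] = {g: i for i, g in enumerate(ids)}

        pairs: set[tuple[int, int]] = set()
        for u, v in edges:
            try:
                iu, iv = self._index[u], self._index[v]
            except KeyError as exc:
                raise InputError(f"edge endpoint {exc.args[0]!r} not in node_ids") from exc
            if iu == iv:
                continue
            pairs.add((min(iu, iv), max(iu, iv)))
        self._edge_idx: list[tuple[int, int]] = sorted(pairs)

        n = len(ids)
        if self._edge_idx:
            rows = np.fromiter((i for i, _ in self._edge_idx), dtype=np.int64)
            cols = np.fromiter((j for _, j in self._edge_idx), dtype=np.int64)
            data = np.ones(len(self._edge_idx), dtype=np.int8)
            upper = sp.coo_array((data, (rows, cols)), shape=(n, n))
            adj = (upper + upper.T).tocsr()
        else:
            adj = sp.csr_array((n, n), dtype=np.int8)
        self._adj = adj

    # -- basic accessors ---------------------------------------------------

    @property
    def node_ids(self) -> list[str]:
        return list(self._ids)

    @property
    def n_nodes(self) -> int:
        return len(self._ids)

    @property
    def n_edges(self) -> int:
        return len(self._edge_idx)

    @property
    def adjacency(self) -> sp.csr_array:
        """Symmetric binary adjacency matrix (CSR)."""
        return self._adj

    @property
    def degrees(self) -> np.ndarray:
        """Per-node degree, i.e. the column sums of the adjacency matrix."""
        return np.asarray(self._adj.sum(axis=0)).ravel().astype(np.int64)

    @property
    def edges(self) -> set[tuple[str, str]]:
        """Undirected edges as identifier pairs, each sorted lexicographically."""
        out = set()
        for i, j in self._edge_idx:
            u, v = self._ids[i], self._ids[j]
            out.add((u, v) if u <= v else (v, u))
        return out

    def index_of(self, node_id: str) -> int:
        return self._index[node_id]

    def __contains__(self, node_id: str) -> bool:
        return node_id in self._index

    def neighbor_indices(self, i: int) -> np.ndarray:
        return self._adj.indices[self._adj.indptr[i] : self._adj.indptr[i + 1]]

    def neighbors(self, node_id: str) -> set[str]:
        return {self._ids[k] for k in self.neighbor_indices(self._index[node_id])}

    def neighbor_sets(self) -> list[set[int]]:
        """Neighbor index sets for every node (degree-0 nodes give empty sets)."""
        return [set(self.neighbor_indices(i).tolist()) for i in range(self.n_nodes)]

    def edge_indices(self) -> list[tuple[int, int]]:
        """Unordered edges as sorted index pairs, in deterministic order."""
        return list(self._edge_idx)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Network(n_nodes={self.n_nodes}, n_edges={self.n_edges})"

    def __eq__(self, other) -> bool:
        if not isinstance(other, Network):
            return NotImplemented
        return self._ids == other._ids and self._edge_idx == other._edge_idx


# -- readers ---------------------------------------------------------------


def _parse_plain(path) -> tuple[list[str], list[tuple[str, str]]]:
    nodes: dict[str, None] = {}
    edges: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) < 2:
                raise MalformedRowError(path, lineno, f"expected 2 columns, got {len(fields)}")
            u, v = fields[0], fields[1]
            nodes.setdefault(u)
            nodes.setdefault(v)
            edges.append((u, v))
    return list(nodes), edges


def _parse_table(
    path,
    dialect: str,
    min_confidence: float | None,
    require_experimental: bool,
    column_map: dict[str, str] | None,
) -> tuple[list[str], list[tuple[str, str]]]:
    import pandas as pd

    cols = dict(STRING_COLUMNS if dialect == "string_db" else BIOGRID_COLUMNS)
    if column_map:
        cols.update(column_map)
    sep = r"\s+" if dialect == "string_db" else "\t"
    try:
        df = pd.read_csv(path, sep=sep, comment=None, dtype=str)
    except Exception as exc:
        raise InputError(f"cannot parse {path}: {exc}") from exc

    for key in ("node1", "node2"):
        if cols[key] not in df.columns:
            raise InputError(f"{path}: missing required column {cols[key]!r} for dialect {dialect!r}")

    if dialect == "string_db":
        for key in ("experimental", "combined"):
            if cols[key] not in df.columns:
                raise InputError(f"{path}: missing required column {cols[key]!r} for dialect 'string_db'")
        conf = pd.to_numeric(df[cols["combined"]], errors="coerce")
        expe = pd.to_numeric(df[cols["experimental"]], errors="coerce")
        bad = conf.isna() | expe.isna()
        if bad.any():
            lineno = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise MalformedRowError(path, lineno, "non-numeric confidence value")
        # STRING ships scores both as 0-1000 integers and 0-1 reals.
        if conf.max() > 1:
            conf = conf / 1000.0
        keep = np.ones(len(df), dtype=bool)
        if require_experimental:
            keep &= expe.to_numpy() > 0
        if min_confidence is not None:
            keep &= conf.to_numpy() > min_confidence  # strictly greater
        df = df[keep]

    nodes: dict[str, None] = {}
    edges: list[tuple[str, str]] = []
    for u, v in zip(df[cols["node1"]], df[cols["node2"]]):
        if not isinstance(u, str) or not isinstance(v, str):
            raise InputError(f"{path}: missing node identifier in a row")
        nodes.setdefault(u)
        nodes.setdefault(v)
        edges.append((u, v))
    return list(nodes), edges


def read_edge_list(
    path,
    dialect: str = "plain",
    min_confidence: float | None = None,
    require_experimental: bool = False,
    column_map: dict[str, str] | None = None,
) -> Network:
    """Read an undirected network from an edge-list file.

    Parameters
    ----------
    path:
        Input file.
    dialect:
        ``"plain"`` (two whitespace-separated identifier columns, ``#``
        comments), ``"string_db"`` (header with per-channel confidence
        columns), or ``"biogrid"`` (TAB3 official-symbol columns).
    min_confidence:
        For ``string_db`` only: keep rows whose combined confidence is
        *strictly greater* than this threshold.  Scores on the 0-1000
        integer scale are auto-detected and rescaled to [0, 1].
    require_experimental:
        For ``string_db`` only: keep rows with a nonzero experimental
        evidence channel.
    column_map:
        Optional overrides for the dialect's column names.

    Raises
    ------
    MalformedRowError
        On an unparseable row (carries the line number).
    EmptyNetworkError
        If no edges survive parsing and filtering.
    """
    if dialect not in ("plain", "string_db", "biogrid"):
        raise InputError(f"unknown dialect {dialect!r}")
    if dialect == "plain":
        nodes, edges = _parse_plain(path)
    else:
        nodes, edges = _parse_table(path, dialect, min_confidence, require_experimental, column_map)
    net = Network(nodes, edges)
    if net.n_edges == 0:
        raise EmptyNetworkError(f"empty network: no edges after reading {path}")
    return net


def write_edge_list(net: Network, path) -> None:
    """Serialize as a plain two-column edge list (one undirected edge per row)."""
    with open(path, "w") as fh:
        for i, j in net.edge_indices():
            fh.write(f"{net.node_ids[i]}\t{net.node_ids[j]}\n")


# -- transformations -------------------------------------------------------


def restrict_to_nodes(net: Network, keep: Iterable[str]) -> Network:
    """Induced subgraph on ``keep`` ∩ ``net.node_ids`` (order preserved)."""
    keep_set = set(keep)
    ids = [g for g in net.node_ids if g in keep_set]
    if not ids:
        warnings.warn("restriction produced an empty network", NetwarpWarning, stacklevel=2)
        return Network([], [])
    surviving = set(ids)
    edges = [(u, v) for u, v in net.edges if u in surviving and v in surviving]
    return Network(ids, edges)


def largest_connected_component(net: Network) -> Network:
    """Induced subgraph on the largest undirected component.

    Ties between equal-sized components are broken in favor of the component
    containing the lexicographically smallest node identifier.
    """
    if net.n_nodes == 0:
        raise EmptyNetworkError("cannot take the largest component of an empty network")
    n_comp, labels = sp.csgraph.connected_components(net.adjacency, directed=False)
    if n_comp <= 1:
        return net
    sizes = np.bincount(labels, minlength=n_comp)
    candidates = [c for c in range(n_comp) if sizes[c] == sizes.max()]
    best = min(
        candidates,
        key=lambda c: min(net.node_ids[i] for i in np.flatnonzero(labels == c)),
    )
    keep = {net.node_ids[i] for i in np.flatnonzero(labels == best)}
    return restrict_to_nodes(net, keep)
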