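"""Augmented Forman-Ricci edge curvature and the curvature-warped weights.

For an edge e = (u, v) of an unweighted graph the augmented Forman-Ricci
curvature is

    kappa_e = 4 - |N_u| - |N_v| + 3 * |N_u ∩ N_v|,

an integer that is large and positive inside cliques and strongly negative on
hub spokes.  The warped weight matrix standardizes kappa over the edge set and
squashes it through a sigmoid scaled by ``beta``:

    K_ji = sigmoid(beta * (kappa_(i,j) - mean(kappa)) / sd(kappa))   on edges,
    K_ji = 0                                                         otherwise.

``beta = 0`` gives uniform weights 1/2, i.e. the original unweighted network
after column normalization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .errors import InputError, NetwarpWarning
from .network import Network

__all__ = [
    "EdgeCurvatures",
    "WarpedWeights",
    "forman_ricci",
    "node_average_curvature",
    "warp_with_curvature",
    "write_curvature_table",
]


@dataclass(frozen=True)
class EdgeCurvatures:
    """Per-edge curvature values plus their edge-set mean and sample sd.

    ``values`` is keyed by lexicographically sorted identifier pairs; mean and
    sd are taken over the unordered edge set (each edge counted once), sd with
    the unbiased n-1 denominator.  A single-edge network has sd 0.
    """

    values: dict[tuple[str, str], float]
    mean: float
    sd: float

    def __getitem__(self, edge: tuple[str, str]) -> float:
        u, v = edge
        return self.values[(u, v) if u <= v else (v, u)]


@dataclass(frozen=True)
class WarpedWeights:
    """Symmetric nonnegative weight matrix K with its ``beta`` hyperparameter.

    Entries lie in (0, 1) exactly on the edge set and are 0 elsewhere.
    """

    K: sp.csr_array
    beta: float
    node_ids: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.K.shape[0]


def _edge_kappas(net: Network) -> np.ndarray:
    """Curvature per unordered edge, aligned with ``net.edge_indices()``."""
    A = net.adjacency.astype(np.int64)
    common = A @ A  # (i, j) entry counts common neighbors of i and j
    deg = net.degrees
    edges = net.edge_indices()
    if not edges:
        return np.empty(0, dtype=np.int64)
    rows = np.fromiter((i for i, _ in edges), dtype=np.int64)
    cols = np.fromiter((j for _, j in edges), dtype=np.int64)
    common_csr = common.tocsr()
    shared = np.asarray(common_csr[rows, cols]).ravel()
    return 4 - deg[rows] - deg[cols] + 3 * shared


def forman_ricci(net: Network) -> EdgeCurvatures:
    """Compute the augmented Forman-Ricci curvature for every edge.

    Raises :class:`InputError` on an edgeless network (the sd over edges is
    undefined there).
    """
    if net.n_edges == 0:
        raise InputError("curvature undefined on a network without edges")
    kappas = _edge_kappas(net)
    values = {}
    ids = net.node_ids
    for (i, j), k in zip(net.edge_indices(), kappas):
        u, v = ids[i], ids[j]
        values[(u, v) if u <= v else (v, u)] = float(k)
    mean = float(np.mean(kappas))
    sd = float(np.std(kappas, ddof=1)) if len(kappas) > 1 else 0.0
    return EdgeCurvatures(values=values, mean=mean, sd=sd)


def node_average_curvature(net: Network, curv: EdgeCurvatures) -> dict[str, float]:
    """Mean curvature of each node's incident edges; degree-0 nodes are absent."""
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for edge, k in curv.values.items():
        for node in edge:
            sums[node] = sums.get(node, 0.0) + k
            counts[node] = counts.get(node, 0) + 1
    return {node: sums[node] / counts[node] for node in sums}


def warp_with_curvature(net: Network, curv: EdgeCurvatures, beta: float) -> WarpedWeights:
    """Build the sigmoid-normalized weight matrix K from edge curvatures.

    When sd(kappa) = 0 (all curvatures identical, e.g. a single edge or a
    lone clique) the standardization is undefined; every edge then gets
    weight sigmoid(0) = 1/2, which reproduces the ``beta = 0`` semantics, and
    a warning is emitted.
    """
    edges = net.edge_indices()
    kappas = np.array([curv[(net.node_ids[i], net.node_ids[j])] for i, j in edges])
    if curv.sd == 0.0:
        if beta != 0.0:
            warnings.warn(
                "sd of curvatures is 0; falling back to uniform edge weight 1/2",
                NetwarpWarning,
                stacklevel=2,
            )
        x = np.zeros(len(edges))
    else:
        x = beta * (kappas - curv.mean) / curv.sd
    w = 1.0 / (1.0 + np.exp(-x))

    n = net.n_nodes
    if edges:
        rows = np.fromiter((i for i, _ in edges), dtype=np.int64)
        cols = np.fromiter((j for _, j in edges), dtype=np.int64)
        upper = sp.coo_array((w, (rows, cols)), shape=(n, n))
        K = (upper + upper.T).tocsr()
    else:
        K = sp.csr_array((n, n), dtype=float)
    return WarpedWeights(K=K, beta=float(beta), node_ids=net.node_ids)


def write_curvature_table(net: Network, curv: EdgeCurvatures, weights: WarpedWeights, path) -> None:
    """TSV export (node1, node2, curvature, weight) for inspection/plotting."""
    idx = {g: i for i, g in enumerate(net.node_ids)}
    K = weights.K
    with open(path, "w") as fh:
        fh.write("node1\tnode2\tcurvature\tweight\n")
        for (u, v), k in sorted(curv.values.items()):
            fh.write(f"{u}\t{v}\t{k:g}\t{K[idx[u], idx[v]]:.10g}\n")
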