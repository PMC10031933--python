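"""Prior-knowledge smoothing and the final asymmetric warped adjacency.

A prior gene set is turned into a uniform restart vector phi, diffused to the
stationary distribution pi of the column-stochastic kernel

    P_ji = (1 - gamma) * K_ji / sum_k K_ki + gamma * phi_j,

and finally multiplied back onto the curvature-warped weights:

    A*_ji = K_ji * pi_j   on edges,   0 otherwise.

A* is generally asymmetric (A*_ji / A*_ij = pi_j / pi_i on edges), which is
what makes the downstream walk implicitly directed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import InputError, NetwarpWarning, NumericalError
from .curvature import WarpedWeights
from .network import Network

__all__ = [
    "PriorVector",
    "PriorKernel",
    "SmoothedPrior",
    "WarpedAdjacency",
    "read_prior_set",
    "make_prior_vector",
    "make_prior_kernel",
    "stationary_distribution",
    "warp_with_prior",
]


@dataclass(frozen=True)
class PriorVector:
    """Uniform probability mass over the prior nodes present in the network."""

    phi: np.ndarray
    members: frozenset[str]
    node_ids: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class PriorKernel:
    """Column-stochastic restart kernel, stored factored as W, phi, gamma.

    ``W`` is the column-normalized weight matrix; the full kernel is the dense
    rank-1 update ``(1 - gamma) W + gamma phi 1^T`` and is never materialized
    except through :meth:`to_dense`.  Columns of ``W`` that were all-zero
    (isolated nodes) are replaced by pure restart.
    """

    W: sp.csr_array
    phi: np.ndarray
    gamma: float
    zero_columns: np.ndarray  # bool mask of columns replaced by pure restart

    @property
    def n(self) -> int:
        return self.W.shape[0]

    def apply(self, v: np.ndarray) -> np.ndarray:
        """Kernel-vector product P @ v without forming the dense kernel."""
        v = np.asarray(v, dtype=float)
        out = (1.0 - self.gamma) * (self.W @ v) + self.gamma * self.phi * v.sum()
        if self.zero_columns.any():
            # those columns contribute restart mass only, already included via
            # phi * v.sum() if gamma covered them fully:
            out += (1.0 - self.gamma) * self.phi * v[self.zero_columns].sum()
        return out

    def column_sums(self) -> np.ndarray:
        sums = (1.0 - self.gamma) * np.asarray(self.W.sum(axis=0)).ravel() + self.gamma
        if self.zero_columns.any():
            sums[self.zero_columns] = float(self.phi.sum())  # pure-restart columns
        return sums

    def to_dense(self) -> np.ndarray:
        """Materialize the kernel as a dense array (small networks only)."""
        P = (1.0 - self.gamma) * self.W.toarray() + self.gamma * np.outer(
            self.phi, np.ones(self.n)
        )
        if self.zero_columns.any():
            P[:, self.zero_columns] = self.phi[:, None]
        return P


@dataclass(frozen=True)
class SmoothedPrior:
    """Stationary distribution pi of the restart kernel (sums to 1)."""

    pi: np.ndarray
    node_ids: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class WarpedAdjacency:
    """The final nonnegative warped adjacency A* (rows scaled by pi)."""

    a_star: sp.csr_array
    node_ids: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.a_star.shape[0]


def read_prior_set(path) -> set[str]:
    """One gene identifier per line; ``#`` comments and blank lines ignored."""
    members = set()
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if line:
                members.add(line)
    return members


def make_prior_vector(net: Network, priors: set[str]) -> PriorVector:
    """Uniform vector phi over the prior nodes found in the network.

    Priors absent from the network are dropped with a warning naming them;
    an empty intersection raises :class:`InputError`.
    """
    present = [g for g in priors if g in net]
    missing = sorted(set(priors) - set(present))
    if missing:
        warnings.warn(
            f"{len(missing)} prior gene(s) not in the network, dropped: "
            + ", ".join(missing[:10]) + ("..." if len(missing) > 10 else ""),
            NetwarpWarning,
            stacklevel=2,
        )
    if not present:
        raise InputError("prior set disjoint from network")
    phi = np.zeros(net.n_nodes)
    for g in present:
        phi[net.index_of(g)] = 1.0 / len(present)
    return PriorVector(phi=phi, members=frozenset(present), node_ids=net.node_ids)


def _column_normalize(K: sp.csr_array) -> tuple[sp.csr_array, np.ndarray]:
    """K D^-1 with zero columns left zero; returns (W, zero-column mask)."""
    colsum = np.asarray(K.sum(axis=0)).ravel().astype(float)
    zero = colsum == 0
    inv = np.zeros_like(colsum)
    inv[~zero] = 1.0 / colsum[~zero]
    W = (K.tocsc() @ sp.diags_array(inv)).tocsr()
    return W, zero


def make_prior_kernel(K: WarpedWeights, phi: PriorVector, gamma: float) -> PriorKernel:
    """Assemble the restart kernel from warped weights and the prior vector.

    Columns of K that sum to zero (isolated nodes) are replaced by pure
    restart (the column becomes phi) and logged via a warning; with
    ``gamma = 0`` such a node is a dead end and an error is raised.
    """
    if not 0.0 <= gamma <= 1.0:
        raise InputError(f"gamma must lie in [0, 1], got {gamma}")
    W, zero = _column_normalize(K.K)
    if zero.any():
        if gamma == 0.0:
            raise InputError("dangling node with no restart (zero column and gamma=0)")
        names = [K.node_ids[i] for i in np.flatnonzero(zero)[:10]]
        warnings.warn(
            f"{int(zero.sum())} isolated node(s) get pure-restart columns: {names}",
            NetwarpWarning,
            stacklevel=2,
        )
    return PriorKernel(W=W, phi=phi.phi.copy(), gamma=float(gamma), zero_columns=zero)


def _is_bipartite(W: sp.csr_array) -> bool:
    """2-colorability of the support graph (symmetric support assumed)."""
    n = W.shape[0]
    pattern = (abs(W) + abs(W.T)).tocsr()
    color = np.full(n, -1, dtype=np.int8)
    for start in range(n):
        if color[start] != -1:
            continue
        color[start] = 0
        stack = [start]
        while stack:
            i = stack.pop()
            for j in pattern.indices[pattern.indptr[i] : pattern.indptr[i + 1]]:
                if color[j] == -1:
                    color[j] = 1 - color[i]
                    stack.append(j)
                elif color[j] == color[i]:
                    return False
    return True


def stationary_distribution(
    kernel: PriorKernel,
    tol: float = 1e-12,
    max_iter: int = 100_000,
    method: str = "auto",
) -> SmoothedPrior:
    """Solve P pi = pi for the restart kernel.

    ``method="direct"`` uses the closed form
    pi = gamma (I - (1 - gamma) W)^-1 phi (requires gamma > 0);
    ``method="power"`` iterates the kernel until the L1 residual drops below
    ``tol``.  ``"auto"`` picks direct for gamma > 0, power otherwise.

    With ``gamma = 0`` the chain is the bare walk on W; a unique convergent
    stationary distribution then needs a connected, non-bipartite support,
    otherwise an error is raised.
    """
    gamma = kernel.gamma
    if method == "auto":
        method = "direct" if gamma > 0 else "power"
    if method == "direct":
        if gamma == 0.0:
            raise InputError("closed-form solve requires gamma > 0")
        n = kernel.n
        W = kernel.W.copy().tolil()
        if kernel.zero_columns.any():
            # pure-restart columns have walk part phi, not W's zero column
            for j in np.flatnonzero(kernel.zero_columns):
                W[:, j] = kernel.phi[:, None]
        A = sp.eye_array(n, format="csc") - (1.0 - gamma) * W.tocsc()
        pi = spla.spsolve(A, gamma * kernel.phi)
        pi = np.asarray(pi, dtype=float)
        s = pi.sum()
        if not np.isfinite(s) or s <= 0:
            raise NumericalError("direct stationary solve failed (singular system)")
        pi = pi / s
        return SmoothedPrior(pi=pi, node_ids=[])
    if method != "power":
        raise InputError(f"unknown method {method!r}")

    if gamma == 0.0:
        n_comp, _ = sp.csgraph.connected_components(kernel.W, directed=False)
        if n_comp > 1:
            raise InputError("gamma=0 stationary distribution undefined: network is disconnected")
        if _is_bipartite(kernel.W):
            raise InputError("gamma=0 stationary distribution undefined: network is bipartite")

    n = kernel.n
    pi = np.full(n, 1.0 / n)
    residual = np.inf
    for _ in range(max_iter):
        new = kernel.apply(pi)
        s = new.sum()
        if s <= 0 or not np.isfinite(s):
            raise NumericalError("power iteration diverged")
        new /= s
        residual = float(np.abs(new - pi).sum())
        pi = new
        if residual <= tol:
            return SmoothedPrior(pi=pi, node_ids=[])
    raise NumericalError("power iteration did not converge", residual=residual)


def warp_with_prior(K: WarpedWeights, pi: SmoothedPrior) -> WarpedAdjacency:
    """A* = diag(pi) K: row j of K scaled by pi_j."""
    p = np.asarray(pi.pi, dtype=float)
    if p.shape[0] != K.n:
        raise InputError("pi and K have mismatched dimensions")
    a_star = (sp.diags_array(p) @ K.K).tocsr()
    return WarpedAdjacency(a_star=a_star, node_ids=K.node_ids)


def write_prior_table(pi: SmoothedPrior, node_ids: list[str], path) -> None:
    """TSV export (gene, pi) for inspection."""
    with open(path, "w") as fh:
        fh.write("gene\tpi\n")
        for g, v in zip(node_ids, pi.pi):
            fh.write(f"{g}\t{v:.12g}\n")
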