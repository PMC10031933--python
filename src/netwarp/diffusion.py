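"""Random walk with restart of gene scores over a (possibly warped) network.

The iteration

    v^(m+1) = (1 - q) * M D^-1 v^(m) + q * v^(0)

is run to its fixed point v* = q (I - (1 - q) M D^-1)^-1 v^(0), where M is
any nonnegative adjacency-like matrix (plain adjacency, curvature weights K,
or the fully warped A*) and D is the diagonal of M's column sums.
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
from .prior import WarpedAdjacency

__all__ = ["GeneScoreVector", "diffuse", "read_score_table", "write_score_table"]


@dataclass(frozen=True)
class GeneScoreVector:
    """Per-gene real scores aligned with a node ordering."""

    scores: np.ndarray
    node_ids: list[str] = field(default_factory=list)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.node_ids, self.scores.tolist()))


def _extract_matrix(adj) -> sp.csr_array:
    if isinstance(adj, Network):
        return adj.adjacency.astype(float).tocsr()
    if isinstance(adj, WarpedWeights):
        return adj.K.tocsr()
    if isinstance(adj, WarpedAdjacency):
        return adj.a_star.tocsr()
    if sp.issparse(adj):
        return sp.csr_array(adj, dtype=float)
    return sp.csr_array(np.asarray(adj, dtype=float))


def diffuse(
    adj,
    v0,
    q: float,
    tol: float = 1e-12,
    max_iter: int = 100_000,
    method: str = "auto",
) -> np.ndarray:
    """Propagate initial scores ``v0`` over ``adj`` with restart probability ``q``.

    Parameters
    ----------
    adj:
        :class:`~netwarp.network.Network`, :class:`~netwarp.curvature.WarpedWeights`,
        :class:`~netwarp.prior.WarpedAdjacency`, or any matrix-like.
    v0:
        Initial score vector (used as given, no normalization).
    q:
        Restart probability in [0, 1].  ``q = 1`` returns ``v0`` unchanged;
        ``q = 0`` is allowed with a warning (the fixed point may not be
        unique) and always uses power iteration.
    method:
        ``"direct"`` (sparse linear solve), ``"power"``, or ``"auto"``
        (direct for q >= 0.05, power below).

    Columns of ``adj`` that sum to zero stay all-zero after normalization:
    score mass entering such a node leaks to the restart term only (logged).
    """
    if not 0.0 <= q <= 1.0:
        raise InputError(f"q must lie in [0, 1], got {q}")
    M = _extract_matrix(adj)
    v0 = np.asarray(v0, dtype=float)
    if v0.shape[0] != M.shape[0]:
        raise InputError(f"score vector length {v0.shape[0]} != matrix size {M.shape[0]}")
    if q == 1.0:
        return v0.copy()
    if q == 0.0:
        warnings.warn(
            "q=0 diffusion has no restart; the fixed point may not be unique",
            NetwarpWarning,
            stacklevel=2,
        )
        method = "power"

    colsum = np.asarray(M.sum(axis=0)).ravel()
    zero = colsum == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} zero-sum column(s); their score mass restarts only",
            NetwarpWarning,
            stacklevel=2,
        )
    inv = np.zeros_like(colsum, dtype=float)
    inv[~zero] = 1.0 / colsum[~zero]
    W = (M.tocsc() @ sp.diags_array(inv)).tocsr()

    if method == "auto":
        method = "direct" if q >= 0.05 else "power"
    if method == "direct":
        n = M.shape[0]
        A = sp.eye_array(n, format="csc") - (1.0 - q) * W.tocsc()
        v = spla.spsolve(A, q * v0)
        v = np.asarray(v, dtype=float)
        if not np.all(np.isfinite(v)):
            raise NumericalError("direct diffusion solve produced non-finite values")
        return v
    if method != "power":
        raise InputError(f"unknown method {method!r}")

    v = v0.copy()
    residual = np.inf
    for _ in range(max_iter):
        new = (1.0 - q) * (W @ v) + q * v0
        residual = float(np.abs(new - v).sum())
        v = new
        if residual <= tol:
            return v
    raise NumericalError("diffusion power iteration did not converge", residual=residual)


def read_score_table(path) -> dict[str, float]:
    """Two-column TSV (gene, score); a header row is detected and skipped."""
    scores: dict[str, float] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 2:
                raise InputError(f"{path}:{lineno}: expected 2 columns")
            gene, value = fields[0], fields[1]
            try:
                scores[gene] = float(value)
            except ValueError:
                if lineno == 1:
                    continue  # header
                raise InputError(f"{path}:{lineno}: non-numeric score {value!r}") from None
    return scores


def write_score_table(scores: GeneScoreVector, path, ranked: bool = True) -> None:
    """Write (gene, score[, rank]) TSV; ranking is score-descending, id-ascending."""
    order = sorted(
        range(len(scores.node_ids)),
        key=lambda i: (-scores.scores[i], scores.node_ids[i]),
    )
    with open(path, "w") as fh:
        if ranked:
            fh.write("gene\tscore\trank\n")
            for rank, i in enumerate(order, start=1):
                fh.write(f"{scores.node_ids[i]}\t{scores.scores[i]:.12g}\t{rank}\n")
        else:
            fh.write("gene\tscore\n")
            for g, s in zip(scores.node_ids, scores.scores):
                fh.write(f"{g}\t{s:.12g}\n")
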