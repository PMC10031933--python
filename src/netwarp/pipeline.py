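"""End-to-end run configuration and stage chaining.

Method variants are configuration, not separate code paths:

* ``warped``           — curvature weights K(beta), prior smoothing pi(gamma),
                         diffusion over A* = diag(pi) K  (the full method)
* ``warped_nocurv``    — same chain with beta forced to 0 (uniform K)
* ``rwr``              — plain random walk with restart over the adjacency
* ``rwr_curvature``    — random walk with restart over K(beta), no prior
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .curvature import forman_ricci, warp_with_curvature
from .diffusion import GeneScoreVector, diffuse, read_score_table, write_score_table
from .errors import InputError, NetwarpWarning
from .network import Network, largest_connected_component, read_edge_list
from .prior import make_prior_kernel, make_prior_vector, read_prior_set, stationary_distribution, warp_with_prior

logger = logging.getLogger("netwarp")

METHODS = ("warped", "warped_nocurv", "rwr", "rwr_curvature")
PRIOR_METHODS = ("warped", "warped_nocurv")


@dataclass
class RunConfig:
    """Everything one prioritization run depends on.

    Defaults beta=0.5, gamma=0.5, q=0.3 are the method's recommended
    settings.  ``warped_nocurv`` forces beta to 0; the rwr variants ignore
    the priors path (with a warning if one is given).
    """

    method: str = "warped"
    beta: float = 0.5
    gamma: float = 0.5
    q: float = 0.3
    network: str | None = None
    priors: str | None = None
    scores: str | None = None
    output: str | None = None
    dialect: str = "plain"
    min_confidence: float | None = None
    require_experimental: bool = False
    lcc: bool = False
    tol: float = 1e-12
    max_iter: int = 100_000
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.method not in METHODS:
            raise InputError(f"unknown method {self.method!r}; choose from {METHODS}")
        if not 0.0 <= self.gamma <= 1.0:
            raise InputError(f"gamma must be in [0, 1], got {self.gamma}")
        if not 0.0 <= self.q <= 1.0:
            raise InputError(f"q must be in [0, 1], got {self.q}")
        if self.method in PRIOR_METHODS and not self.priors:
            raise InputError(f"method {self.method!r} requires a priors path")
        if self.network is None:
            raise InputError("a network path is required")
        if self.scores is None:
            raise InputError("a scores path is required")
        if self.method == "warped_nocurv":
            self.beta = 0.0

    @classmethod
    def from_file(cls, path, **overrides) -> "RunConfig":
        """Load a flat YAML/JSON key-value config; keyword overrides win."""
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise InputError(f"{path}: config must be a flat mapping")
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise InputError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)


def _file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def scores_for_network(net: Network, table: dict[str, float]) -> GeneScoreVector:
    """Align a gene->score table with the network's node order.

    Genes missing from the table get score 0; table genes outside the network
    are dropped.  Both situations are logged.
    """
    v0 = np.zeros(net.n_nodes)
    n_used = 0
    for gene, value in table.items():
        if gene in net:
            v0[net.index_of(gene)] = value
            n_used += 1
    missing = net.n_nodes - n_used
    if missing:
        logger.info("scores: %d network gene(s) without a score (set to 0)", missing)
    dropped = len(table) - n_used
    if dropped:
        logger.info("scores: %d scored gene(s) not in the network (dropped)", dropped)
    return GeneScoreVector(scores=v0, node_ids=net.node_ids)


def run_method(
    net: Network,
    v0: GeneScoreVector,
    method: str,
    prior_set: set[str] | None = None,
    beta: float = 0.5,
    gamma: float = 0.5,
    q: float = 0.3,
    tol: float = 1e-12,
    max_iter: int = 100_000,
) -> GeneScoreVector:
    """Execute one method variant on in-memory inputs and return final scores."""
    if method not in METHODS:
        raise InputError(f"unknown method {method!r}")
    if method == "warped_nocurv":
        beta = 0.0
        method = "warped"
    if method == "rwr":
        final = diffuse(net, v0.scores, q=q, tol=tol, max_iter=max_iter)
        return GeneScoreVector(scores=final, node_ids=net.node_ids)

    logger.info("stage curvature: beta=%g", beta)
    curv = forman_ricci(net)
    K = warp_with_curvature(net, curv, beta)
    if method == "rwr_curvature":
        final = diffuse(K, v0.scores, q=q, tol=tol, max_iter=max_iter)
        return GeneScoreVector(scores=final, node_ids=net.node_ids)

    if not prior_set:
        raise InputError("warped methods require a prior set")
    logger.info("stage prior smoothing: gamma=%g, |priors|=%d", gamma, len(prior_set))
    phi = make_prior_vector(net, prior_set)
    kernel = make_prior_kernel(K, phi, gamma)
    pi = stationary_distribution(kernel, tol=tol, max_iter=max_iter)
    a_star = warp_with_prior(K, pi)
    logger.info("stage diffusion: q=%g", q)
    final = diffuse(a_star, v0.scores, q=q, tol=tol, max_iter=max_iter)
    return GeneScoreVector(scores=final, node_ids=net.node_ids)


def run(config: RunConfig) -> dict:
    """Execute the configured stage chain; write ranked TSV plus a manifest.

    Returns the manifest dictionary (also written as JSON next to the ranked
    output when an output path is configured).
    """
    config.validate()

    logger.info("stage load: network=%s dialect=%s", config.network, config.dialect)
    net = read_edge_list(
        config.network,
        dialect=config.dialect,
        min_confidence=config.min_confidence,
        require_experimental=config.require_experimental,
    )
    if config.lcc:
        net = largest_connected_component(net)

    prior_set = None
    if config.priors:
        if config.method in PRIOR_METHODS:
            prior_set = read_prior_set(config.priors)
        else:
            warnings.warn(
                f"method {config.method!r} ignores the supplied priors file",
                NetwarpWarning,
                stacklevel=2,
            )

    table = read_score_table(config.scores)
    v0 = scores_for_network(net, table)

    final = run_method(
        net,
        v0,
        config.method,
        prior_set=prior_set,
        beta=config.beta,
        gamma=config.gamma,
        q=config.q,
        tol=config.tol,
        max_iter=config.max_iter,
    )

    manifest = {
        "netwarp_version": __version__,
        "config": {k: v for k, v in asdict(config).items() if k != "extra"},
        "inputs": {
            "network_sha256": _file_sha256(config.network),
            "scores_sha256": _file_sha256(config.scores),
            "priors_sha256": _file_sha256(config.priors) if prior_set is not None else None,
        },
        "n_nodes": net.n_nodes,
        "n_edges": net.n_edges,
        "library_versions": _library_versions(),
    }

    if config.output:
        out = Path(config.output)
        out.mkdir(parents=True, exist_ok=True)
        write_score_table(final, out / "ranked_scores.tsv", ranked=True)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        logger.info("wrote %s", out / "ranked_scores.tsv")
    manifest["scores"] = final
    return manifest


def _library_versions() -> dict[str, str]:
    import numpy
    import pandas
    import scipy

    return {"numpy": numpy.__version__, "scipy": scipy.__version__, "pandas": pandas.__version__}
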