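"""Synthetic fixtures: the 11-node toy graph and planted-module benchmarks.

The planted-module generator produces networks with the structure the warping
method exploits — dense cliques ("complexes", high positive edge curvature)
and star hubs (strongly negative spoke curvature) on an Erdős–Rényi
background — together with a ground-truth gene set concentrated in the
cliques and noisy initial scores correlated with truth proximity.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np

from .diffusion import GeneScoreVector
from .errors import InputError, NetwarpWarning
from .network import Network

__all__ = ["SyntheticSpec", "fig2_graph", "planted_module_network"]


def fig2_graph() -> Network:
    """The canonical 11-node toy graph.

    A central node ``center`` is adjacent to ten others: ``l1``..``l5`` are
    additionally pairwise interconnected (the clique side) while ``r1``..``r5``
    have no other edges (the star side).  Center-to-clique edges have
    curvature 1, center-to-leaf edges -7, clique-internal edges 6.
    """
    left = [f"l{i}" for i in range(1, 6)]
    right = [f"r{i}" for i in range(1, 6)]
    nodes = ["center"] + left + right
    edges = [("center", x) for x in left + right]
    edges += list(itertools.combinations(left, 2))
    return Network(nodes, edges)


@dataclass
class SyntheticSpec:
    """Parameters of the planted-module generator (all randomness from ``seed``)."""

    n_modules: int = 6
    clique_size: int = 8
    n_hubs: int = 4
    hub_degree: int = 12
    background_nodes: int = 150
    background_edge_prob: float = 0.02
    truth_fraction_in_modules: float = 0.8
    prior_fraction: float = 0.2
    score_signal: float = 0.3
    score_noise_sd: float = 1.0
    score_baseline: float = 4.0
    n_truth: int = 60
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_modules": self.n_modules,
            "clique_size": self.clique_size,
            "n_hubs": self.n_hubs,
            "hub_degree": self.hub_degree,
            "background_nodes": self.background_nodes,
            "n_truth": self.n_truth,
        }
        for name, value in counts.items():
            if value <= 0:
                raise InputError(f"{name} must be positive, got {value}")
        for name, value in (
            ("background_edge_prob", self.background_edge_prob),
            ("truth_fraction_in_modules", self.truth_fraction_in_modules),
            ("prior_fraction", self.prior_fraction),
        ):
            if not 0.0 <= value <= 1.0:
                raise InputError(f"{name} must be in [0, 1], got {value}")
        if self.clique_size < 2:
            raise InputError("clique_size must be >= 2")
        if self.n_truth > self.n_modules * self.clique_size + self.background_nodes:
            raise InputError("n_truth exceeds the number of available nodes")


def planted_module_network(spec: SyntheticSpec) -> tuple[Network, set[str], GeneScoreVector]:
    """Generate (network, ground-truth set, noisy initial scores).

    Layout: ``n_modules`` cliques of ``clique_size`` nodes, ``n_hubs`` stars
    with ``hub_degree`` fresh leaves each, and an Erdős–Rényi background.
    Components are joined with single bridge edges (logged) so the result is
    connected.  A ``truth_fraction_in_modules`` share of the ``n_truth``
    ground-truth genes is drawn from clique nodes, the rest from the
    background.  Scores are ``score_baseline`` plus Gaussian noise, plus
    ``score_signal`` on truth genes and their neighbors; the positive baseline
    mimics the predominantly positive Z-scores that highly powered
    case/control differential-expression tests yield genome-wide.
    """
    spec.validate()
    root = np.random.default_rng(spec.seed)
    rng_graph, rng_truth, rng_scores = root.spawn(3)

    clique_nodes: list[str] = []
    edges: list[tuple[str, str]] = []
    for m in range(spec.n_modules):
        members = [f"m{m}_{i}" for i in range(spec.clique_size)]
        clique_nodes.extend(members)
        edges.extend(itertools.combinations(members, 2))

    hub_nodes: list[str] = []
    for h in range(spec.n_hubs):
        hub = f"h{h}"
        leaves = [f"h{h}_leaf{i}" for i in range(spec.hub_degree)]
        hub_nodes.extend([hub] + leaves)
        edges.extend((hub, leaf) for leaf in leaves)

    background = [f"b{i}" for i in range(spec.background_nodes)]
    n_bg = len(background)
    if spec.background_edge_prob > 0 and n_bg > 1:
        iu, ju = np.triu_indices(n_bg, k=1)
        mask = rng_graph.random(len(iu)) < spec.background_edge_prob
        edges.extend((background[a], background[b]) for a, b in zip(iu[mask], ju[mask]))

    nodes = clique_nodes + hub_nodes + background
    net = Network(nodes, edges)

    # join components with single bridge edges into the component of nodes[0]
    import scipy.sparse as sp_mod

    n_comp, labels = sp_mod.csgraph.connected_components(net.adjacency, directed=False)
    if n_comp > 1:
        anchor_label = labels[0]
        anchors = [i for i, lab in enumerate(labels) if lab == anchor_label]
        bridges = []
        for comp in range(n_comp):
            if comp == anchor_label:
                continue
            members = np.flatnonzero(labels == comp)
            a = nodes[int(rng_graph.choice(members))]
            b = nodes[int(rng_graph.choice(anchors))]
            bridges.append((a, b))
        edges.extend(bridges)
        net = Network(nodes, edges)
        warnings.warn(
            f"added {len(bridges)} bridge edge(s) to connect components",
            NetwarpWarning,
            stacklevel=2,
        )

    n_in_modules = min(round(spec.truth_fraction_in_modules * spec.n_truth), len(clique_nodes))
    n_outside = spec.n_truth - n_in_modules
    truth = set(rng_truth.choice(clique_nodes, size=n_in_modules, replace=False).tolist())
    if n_outside > 0:
        truth |= set(rng_truth.choice(background, size=min(n_outside, n_bg), replace=False).tolist())

    scores = spec.score_baseline + rng_scores.normal(0.0, spec.score_noise_sd, size=net.n_nodes)
    if spec.score_signal != 0.0:
        boosted = set(truth)
        for g in truth:
            boosted |= net.neighbors(g)
        for g in boosted:
            scores[net.index_of(g)] += spec.score_signal
    return net, truth, GeneScoreVector(scores=scores, node_ids=net.node_ids)
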