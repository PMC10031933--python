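"""Benchmark harness: ground-truth splits, ranking metrics, method comparison.

The protocol: the known relevant genes are split into a small train set (used
as prior knowledge) and a large test set (to be recovered), repeated over
independent trials.  Rankings are scored with average precision and
precision-at-k; methods are compared with one-sided paired t-tests and
Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError

__all__ = [
    "TrialSplit",
    "MetricReport",
    "split_ground_truth",
    "average_precision",
    "precision_at_k",
    "rank_genes",
    "evaluate_ranking",
    "compare_methods",
]


@dataclass(frozen=True)
class TrialSplit:
    """One train/test partition of the ground-truth genes."""

    train: frozenset[str]
    test: frozenset[str]
    seed: int
    ratio: float


@dataclass
class MetricReport:
    """Long-format per-trial metric values: columns (trial, method, metric, value)."""

    table: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["trial", "method", "metric", "value"])
    )

    def add(self, trial: int, method: str, metric: str, value: float) -> None:
        self.table.loc[len(self.table)] = [trial, method, metric, value]

    def aggregate(self) -> pd.DataFrame:
        """Mean and sample sd per (method, metric)."""
        return (
            self.table.groupby(["method", "metric"])["value"]
            .agg(["mean", "std"])
            .reset_index()
        )

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def aggregate_json(self, path) -> None:
        records = self.aggregate().to_dict(orient="records")
        with open(path, "w") as fh:
            json.dump(records, fh, indent=2)


def split_ground_truth(
    truth: set[str],
    network_nodes: set[str],
    train_fraction: float = 0.2,
    n_trials: int = 30,
    seed: int = 0,
) -> list[TrialSplit]:
    """Repeated uniform train/test splits of the ground truth.

    Genes absent from the network are removed first.  The train size is
    ``round(train_fraction * m)`` with Python's round-half-to-even rule.
    Fully reproducible from ``seed``.
    """
    if not 0.0 < train_fraction < 1.0:
        raise InputError(f"train_fraction must be in (0, 1), got {train_fraction}")
    usable = sorted(truth & network_nodes)
    if not usable:
        raise InputError("ground truth disjoint from network")
    m = len(usable)
    n_train = round(train_fraction * m)
    rng = np.random.default_rng(seed)
    splits = []
    for t in range(n_trials):
        perm = rng.permutation(m)
        train = frozenset(usable[i] for i in perm[:n_train])
        test = frozenset(usable[i] for i in perm[n_train:])
        splits.append(TrialSplit(train=train, test=test, seed=seed, ratio=train_fraction))
    return splits


def average_precision(ranking: list[str], relevant: set[str]) -> float:
    """AveP = sum_k Prec@k * [k-th item relevant] / |relevant|.

    The denominator counts *all* relevant items, including those never ranked,
    so an incomplete ranking is penalized.
    """
    if not relevant:
        raise InputError("relevant set is empty")
    if len(set(ranking)) != len(ranking):
        raise InputError("ranking contains duplicates")
    hits = 0
    total = 0.0
    for k, gene in enumerate(ranking, start=1):
        if gene in relevant:
            hits += 1
            total += hits / k
    return total / len(relevant)


def precision_at_k(ranking: list[str], relevant: set[str], k: int) -> float:
    """Fraction of the top-k ranked items that are relevant."""
    if k < 1:
        raise InputError(f"k must be >= 1, got {k}")
    if len(ranking) < k:
        raise InputError(f"ranking has {len(ranking)} items, fewer than k={k}")
    return sum(1 for gene in ranking[:k] if gene in relevant) / k


def rank_genes(scores: dict[str, float], exclude: set[str] | None = None) -> list[str]:
    """Genes sorted by score descending, excluded genes removed first.

    Ties are broken by lexicographic gene identifier, so rankings are
    deterministic.
    """
    exclude = exclude or set()
    return sorted(
        (g for g in scores if g not in exclude),
        key=lambda g: (-scores[g], g),
    )


def evaluate_ranking(
    ranking: list[str],
    relevant: set[str],
    ks: tuple[int, ...] = (100, 200),
) -> dict[str, float]:
    """AveP plus Prec@k for each requested k (skipping k beyond the ranking)."""
    out = {"AveP": average_precision(ranking, relevant)}
    for k in ks:
        if len(ranking) >= k:
            out[f"Prec@{k}"] = precision_at_k(ranking, relevant, k)
    return out


def _bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adjusted = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m - 1, -1, -1):
        idx = order[rank_from_top]
        value = p[idx] * m / (rank_from_top + 1)
        running_min = min(running_min, value)
        adjusted[idx] = running_min
    return np.clip(adjusted, 0.0, 1.0)


def compare_methods(
    report: MetricReport,
    baseline: str,
    alternative: str | list[str],
) -> pd.DataFrame:
    """One-sided paired t-tests (alternative > baseline) per metric, BH-adjusted.

    Both methods must have been evaluated on the identical trial set; a
    mismatch raises.  Zero-variance differences (identical results) are
    guarded to p = 1.
    """
    alternatives = [alternative] if isinstance(alternative, str) else list(alternative)
    table = report.table
    rows = []
    for alt in alternatives:
        for metric in sorted(table["metric"].unique()):
            base = table[(table["method"] == baseline) & (table["metric"] == metric)]
            other = table[(table["method"] == alt) & (table["metric"] == metric)]
            base = base.set_index("trial")["value"].sort_index()
            other = other.set_index("trial")["value"].sort_index()
            if not base.index.equals(other.index):
                raise InputError(
                    f"trial sets differ between {baseline!r} and {alt!r} on {metric!r}"
                )
            diff = other.to_numpy() - base.to_numpy()
            if np.allclose(diff, 0.0):
                p = 1.0
            else:
                p = float(
                    stats.ttest_rel(other.to_numpy(), base.to_numpy(), alternative="greater").pvalue
                )
                if not np.isfinite(p):
                    p = 1.0
            rows.append({"baseline": baseline, "method": alt, "metric": metric, "p": p})
    result = pd.DataFrame(rows)
    result["p_adjusted"] = _bh_adjust(result["p"].to_numpy())
    return result
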