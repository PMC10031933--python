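"""Initial gene scores from case/control expression matrices.

Per stratum (e.g. cancer type) each gene gets a two-sided t-test p-value
comparing case vs. control samples.  P-values are combined across strata with
Fisher's method, S = -2 sum(ln p) ~ chi-square with 2k degrees of freedom, and
the combined p is mapped to a Z-score via the upper-tail standard-normal
quantile Z = Phi^-1(1 - p).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError, NetwarpWarning

__all__ = [
    "ExpressionStratum",
    "read_stratum",
    "gene_pvalues",
    "fisher_combine",
    "p_to_z",
    "initial_scores",
]

_P_FLOOR = 1e-300  # clip before log in Fisher's statistic
_Z_CLIP = 1e-15  # clip before the normal quantile


@dataclass
class ExpressionStratum:
    """One stratum's expression data: genes x samples for each arm."""

    label: str
    genes: list[str]
    case_matrix: np.ndarray  # genes x case samples
    control_matrix: np.ndarray  # genes x control samples

    def __post_init__(self):
        self.case_matrix = np.asarray(self.case_matrix, dtype=float)
        self.control_matrix = np.asarray(self.control_matrix, dtype=float)
        if self.case_matrix.shape[0] != len(self.genes) or self.control_matrix.shape[0] != len(
            self.genes
        ):
            raise InputError(f"stratum {self.label!r}: matrix rows do not match gene list")
        if self.case_matrix.shape[1] < 2 or self.control_matrix.shape[1] < 2:
            raise InputError(
                f"stratum {self.label!r}: need >= 2 samples per arm "
                f"(got {self.case_matrix.shape[1]} case, {self.control_matrix.shape[1]} control)"
            )


def read_stratum(expression_path, metadata_path, label: str | None = None) -> ExpressionStratum:
    """Load a stratum from a genes x samples TSV plus a sample-arm metadata TSV.

    The metadata file has columns ``sample`` and ``arm`` with arm in
    {case, control}.
    """
    expr = pd.read_csv(expression_path, sep="\t", index_col=0)
    meta = pd.read_csv(metadata_path, sep="\t")
    if not {"sample", "arm"} <= set(meta.columns):
        raise InputError(f"{metadata_path}: need columns 'sample' and 'arm'")
    bad = set(meta["arm"]) - {"case", "control"}
    if bad:
        raise InputError(f"{metadata_path}: unknown arm value(s) {sorted(bad)}")
    missing = set(meta["sample"]) - set(expr.columns)
    if missing:
        raise InputError(f"samples in metadata but not expression: {sorted(missing)[:5]}")
    case_cols = meta.loc[meta["arm"] == "case", "sample"].tolist()
    control_cols = meta.loc[meta["arm"] == "control", "sample"].tolist()
    return ExpressionStratum(
        label=label or str(expression_path),
        genes=expr.index.astype(str).tolist(),
        case_matrix=expr[case_cols].to_numpy(),
        control_matrix=expr[control_cols].to_numpy(),
    )


def gene_pvalues(stratum: ExpressionStratum, equal_var: bool = False) -> pd.Series:
    """Two-sided t-test p-value per gene (Welch by default).

    Genes with zero variance in both arms and equal means get p = 1 with a
    warning (the statistic is 0/0 there).
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        result = stats.ttest_ind(
            stratum.case_matrix, stratum.control_matrix, axis=1, equal_var=equal_var
        )
    p = np.asarray(result.pvalue, dtype=float)
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        case_mean = stratum.case_matrix.mean(axis=1)
        ctrl_mean = stratum.control_matrix.mean(axis=1)
        equal_means = np.isclose(case_mean, ctrl_mean)
        p[degenerate & equal_means] = 1.0
        p[degenerate & ~equal_means] = _P_FLOOR
        warnings.warn(
            f"stratum {stratum.label!r}: {int(degenerate.sum())} gene(s) with zero "
            "variance in both arms; p set to 1 (equal means) or the floor",
            NetwarpWarning,
            stacklevel=2,
        )
    return pd.Series(p, index=stratum.genes, name=stratum.label)


def fisher_combine(pvals: pd.DataFrame) -> pd.Series:
    """Fisher's method across strata columns; NaN entries are skipped per gene.

    Returns the combined upper-tail chi-square p-value with 2 * (number of
    strata actually used for that gene) degrees of freedom; genes with no
    finite p-value at all get NaN.
    """
    clipped = pvals.clip(lower=_P_FLOOR, upper=1.0)
    logs = np.log(clipped.to_numpy(dtype=float))
    available = np.isfinite(logs)
    k = available.sum(axis=1)
    S = -2.0 * np.nansum(np.where(available, logs, 0.0), axis=1)
    combined = np.full(len(pvals), np.nan)
    has_any = k > 0
    combined[has_any] = stats.chi2.sf(S[has_any], df=2 * k[has_any])
    return pd.Series(combined, index=pvals.index, name="combined_p")


def p_to_z(p) -> np.ndarray:
    """Upper-tail standard-normal quantile Z = Phi^-1(1 - p), clipped away from 0/1."""
    arr = np.clip(np.asarray(p, dtype=float), _Z_CLIP, 1.0 - _Z_CLIP)
    return stats.norm.isf(arr)


def initial_scores(
    strata: list[ExpressionStratum],
    combine: bool = True,
    equal_var: bool = False,
) -> pd.Series | pd.DataFrame:
    """Full scoring pipeline: t-tests per stratum, Fisher combination, Z-scores.

    With ``combine=False`` the per-stratum Z matrix is returned instead
    (multidimensional passthrough for methods that accept one).
    """
    if not strata:
        raise InputError("no strata supplied")
    table = pd.concat([gene_pvalues(s, equal_var=equal_var) for s in strata], axis=1)
    if not combine:
        return pd.DataFrame(p_to_z(table.to_numpy()), index=table.index, columns=table.columns)
    combined = fisher_combine(table)
    z = pd.Series(p_to_z(combined.to_numpy()), index=combined.index, name="z")
    z[combined.isna()] = np.nan
    return z
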