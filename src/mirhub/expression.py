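"""Gene-level expression analysis.

Quantile normalization of a log2 expression matrix, per-gene two-sample
t-tests against a reference group, Benjamini-Hochberg FDR control, gating
by FDR and linear fold change, and overlap accounting between the
per-condition significant gene sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from . import _defaults
from .io import read_groups, read_matrix

log = logging.getLogger(__name__)

DE_COLUMNS = [
    "t_statistic",
    "p_value",
    "q_value",
    "log2_fold_change",
    "fold_change",
    "zero_variance",
]


@dataclass
class ExpressionMatrix:
    """A genes-by-samples log2 expression matrix with sample group labels.

    Parameters
    ----------
    values
        DataFrame of log2 expression, genes in rows, samples in columns.
    group_of
        Mapping from sample ID to group label; every column must be present.
    """

    values: pd.DataFrame
    group_of: Mapping[str, str]

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if self.values.index.has_duplicates:
            raise ValueError("gene ids are not unique")
        missing = [s for s in self.values.columns if s not in self.group_of]
        if missing:
            raise ValueError(f"samples without a group label: {missing}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.group_of[s] == group]

    @classmethod
    def from_tsv(cls, matrix_path: str | Path, groups_path: str | Path) -> "ExpressionMatrix":
        return cls(read_matrix(matrix_path), read_groups(groups_path))


@dataclass
class GeneSet:
    """A labelled set of gene IDs with an optional per-member direction."""

    label: str
    directions: dict[str, str | None] = field(default_factory=dict)

    @property
    def members(self) -> list[str]:
        return list(self.directions)

    def __len__(self) -> int:
        return len(self.directions)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.directions

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("gene_id\tdirection\n")
            for gene, direction in self.directions.items():
                fh.write(f"{gene}\t{direction if direction else 'NA'}\n")

    @classmethod
    def from_tsv(cls, path: str | Path, label: str | None = None) -> "GeneSet":
        df = pd.read_csv(path, sep="\t")
        directions = {
            str(row.gene_id): (None if str(row.direction) == "NA" else str(row.direction))
            for row in df.itertuples()
        }
        return cls(label or Path(path).stem, directions)


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize columns so all samples share one value distribution.

    The reference distribution is the row-wise mean of the column-sorted
    matrix. Ties within a column receive the mean of the reference values
    their rank span covers, so tied inputs stay tied in the output.
    """
    X = matrix.values.to_numpy(dtype=float)
    n, m = X.shape
    if m < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    reference = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(m):
        col = X[:, j]
        order = np.argsort(col, kind="mergesort")
        sorted_col = col[order]
        # run boundaries of tied values in the sorted column
        starts = np.flatnonzero(np.r_[True, sorted_col[1:] != sorted_col[:-1]])
        counts = np.diff(np.r_[starts, n])
        run_means = np.add.reduceat(reference, starts) / counts
        out[order, j] = np.repeat(run_means, counts)
    values = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return ExpressionMatrix(values, dict(matrix.group_of))


def _two_sample_t(
    a: np.ndarray, b: np.ndarray, *, welch: bool = False
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized two-sided two-sample t-test along axis 1.

    Returns (t, p, zero_variance_flag). Degenerate rows where both groups
    have zero variance use the documented convention: equal means give
    t=0, p=1; unequal means give p = smallest positive float with t = +/-inf.
    """
    import warnings

    with warnings.catch_warnings():
        # degenerate rows are handled by the documented convention below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(a, b, axis=1, equal_var=not welch)
    t = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    var_a = a.var(axis=1, ddof=1)
    var_b = b.var(axis=1, ddof=1)
    diff = a.mean(axis=1) - b.mean(axis=1)
    degenerate = (var_a == 0) & (var_b == 0)
    flagged = degenerate.copy()
    equal = degenerate & (diff == 0)
    unequal = degenerate & (diff != 0)
    t[equal] = 0.0
    p[equal] = 1.0
    t[unequal] = np.sign(diff[unequal]) * np.inf
    p[unequal] = np.nextafter(0.0, 1.0)
    return t, p, flagged


def differential_expression(
    matrix: ExpressionMatrix,
    group_a: str,
    group_b: str,
    *,
    welch: bool = False,
) -> pd.DataFrame:
    """Per-gene differential expression of ``group_a`` versus ``group_b``.

    Performs an equal-variance two-sided t-test per gene (Welch behind a
    flag), with log2 fold change = mean(a) - mean(b) and signed linear fold
    change ``sign * 2**|log2FC|``. BH q-values over all tested genes are
    included.

    Returns a DataFrame indexed by gene ID with columns ``t_statistic``,
    ``p_value``, ``q_value``, ``log2_fold_change``, ``fold_change`` and
    ``zero_variance``.
    """
    samples_a = matrix.samples_in_group(group_a)
    samples_b = matrix.samples_in_group(group_b)
    for group, samples in ((group_a, samples_a), (group_b, samples_b)):
        if len(samples) < 2:
            raise ValueError(f"group {group!r} has {len(samples)} samples; need >= 2")
    a = matrix.values[samples_a].to_numpy(dtype=float)
    b = matrix.values[samples_b].to_numpy(dtype=float)
    t, p, flagged = _two_sample_t(a, b, welch=welch)
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    fold = np.sign(log2fc) * np.power(2.0, np.abs(log2fc))
    fold[log2fc == 0] = 1.0
    q = bh_fdr(p)
    return pd.DataFrame(
        {
            "t_statistic": t,
            "p_value": p,
            "q_value": q,
            "log2_fold_change": log2fc,
            "fold_change": fold,
            "zero_variance": flagged,
        },
        index=matrix.values.index,
    )


def anova_f(matrix: ExpressionMatrix, groups: Iterable[str]) -> pd.DataFrame:
    """One-way fixed-effects F-test per gene across several groups."""
    blocks = [
        matrix.values[matrix.samples_in_group(g)].to_numpy(dtype=float) for g in groups
    ]
    if any(b.shape[1] < 2 for b in blocks):
        raise ValueError("every group needs >= 2 samples for the F-test")
    res = stats.f_oneway(*blocks, axis=1)
    return pd.DataFrame(
        {"f_statistic": res.statistic, "p_value": res.pvalue},
        index=matrix.values.index,
    )


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    q_(i) = min_{j >= i} p_(j) * m / j, clipped to [0, 1]; order-preserving.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D vector of p-values")
    if np.isnan(p).any():
        raise ValueError("NaN p-values are not allowed")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m, dtype=float)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def significant_genes(
    results: pd.DataFrame,
    *,
    fdr_max: float = _defaults.FDR_MAX,
    fold_min: float = _defaults.FOLD_MIN,
    label: str = "significant",
) -> GeneSet:
    """Gate DE results at ``q < fdr_max`` and linear ``|FC| >= fold_min``.

    FDR is a strict inequality; the fold-change gate is inclusive. The
    direction recorded per member follows the sign of the log2 fold change.
    """
    if results.empty:
        raise ValueError("empty DE result table")
    passing = (results["q_value"] < fdr_max) & (
        np.abs(results["fold_change"]) >= fold_min
    )
    directions: dict[str, str | None] = {}
    for gene_id, row in results.loc[passing].iterrows():
        directions[str(gene_id)] = "up" if row["log2_fold_change"] > 0 else "down"
    log.info(
        "significant_genes: %d/%d pass q<%g and |FC|>=%g",
        len(directions), len(results), fdr_max, fold_min,
    )
    return GeneSet(label, directions)


@dataclass(frozen=True)
class OverlapReport:
    common: tuple[str, ...]
    unique_a: tuple[str, ...]
    unique_b: tuple[str, ...]
    concordant: int

    @property
    def n_common(self) -> int:
        return len(self.common)

    def to_dict(self) -> dict:
        return {
            "n_common": len(self.common),
            "n_unique_a": len(self.unique_a),
            "n_unique_b": len(self.unique_b),
            "n_concordant": self.concordant,
            "common": list(self.common),
            "unique_a": list(self.unique_a),
            "unique_b": list(self.unique_b),
        }


def overlap_analysis(set_a: GeneSet, set_b: GeneSet) -> OverlapReport:
    """Common/unique members of two gene sets plus direction concordance."""
    ids_a = set(set_a.directions)
    ids_b = set(set_b.directions)
    common = sorted(ids_a & ids_b)
    concordant = sum(
        1 for g in common if set_a.directions[g] == set_b.directions[g]
        and set_a.directions[g] is not None
    )
    return OverlapReport(
        common=tuple(common),
        unique_a=tuple(sorted(ids_a - ids_b)),
        unique_b=tuple(sorted(ids_b - ids_a)),
        concordant=concordant,
    )
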