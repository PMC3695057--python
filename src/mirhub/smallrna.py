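"""miRNA read-count filtering, normalization and differential testing.

Counts are normalized to the total number of uniquely mapped reads per
sample (counts per million by default). Low-abundance miRNAs are removed
on raw counts before normalization. Differential testing is a two-sided
Student's t-test on log2(normalized + pseudocount); significance is raw
p < 0.05 (no multiple-testing correction is applied, though a BH column
is emitted for transparency).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import _defaults
from .expression import _two_sample_t, bh_fdr
from .io import read_groups, read_library_sizes, read_matrix

log = logging.getLogger(__name__)


@dataclass
class MiRNACountTable:
    """Raw miRNA read counts with per-sample library sizes and groups."""

    counts: pd.DataFrame
    library_sizes: pd.Series
    group_of: Mapping[str, str]

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("miRNA ids are not unique")
        values = self.counts.to_numpy()
        if (values < 0).any():
            raise ValueError("negative counts")
        if not np.allclose(values, np.round(values)):
            raise ValueError("counts must be integers")
        missing = [s for s in self.counts.columns if s not in self.library_sizes.index]
        if missing:
            raise ValueError(f"samples without library sizes: {missing}")
        if (self.library_sizes.loc[list(self.counts.columns)] <= 0).any():
            raise ValueError("library sizes must be positive")
        unlabelled = [s for s in self.counts.columns if s not in self.group_of]
        if unlabelled:
            raise ValueError(f"samples without a group label: {unlabelled}")

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.counts.index)

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.counts.columns if self.group_of[s] == group]

    @classmethod
    def from_tsv(
        cls,
        counts_path: str | Path,
        library_sizes_path: str | Path,
        groups_path: str | Path,
    ) -> "MiRNACountTable":
        return cls(
            read_matrix(counts_path),
            read_library_sizes(library_sizes_path),
            read_groups(groups_path),
        )


def filter_low_counts(
    table: MiRNACountTable,
    *,
    min_count: int = _defaults.MIN_COUNT,
    mode: str = "any",
) -> MiRNACountTable:
    """Drop miRNAs whose raw counts fall below ``min_count``.

    ``mode='any'`` (default) retains a miRNA if its raw count reaches
    ``min_count`` in at least one sample; ``mode='total'`` requires the
    summed count across samples to reach the threshold. Filtering always
    operates on raw counts, so it commutes with normalization.
    """
    if mode == "any":
        keep = (table.counts >= min_count).any(axis=1)
    elif mode == "total":
        keep = table.counts.sum(axis=1) >= min_count
    else:
        raise ValueError(f"unknown filter mode {mode!r}")
    dropped = table.counts.index[~keep].tolist()
    if dropped:
        log.info("filter_low_counts: dropped %d miRNAs below %d (%s): %s",
                 len(dropped), min_count, mode, ", ".join(map(str, dropped[:10])))
    return MiRNACountTable(
        table.counts.loc[keep].copy(), table.library_sizes, dict(table.group_of)
    )


def normalize_counts(
    table: MiRNACountTable, *, scale: float = _defaults.CPM_SCALE
) -> pd.DataFrame:
    """Scale counts to ``raw * scale / library_size`` per sample (CPM)."""
    sizes = table.library_sizes.loc[list(table.counts.columns)].to_numpy(float)
    if (sizes <= 0).any():
        raise ValueError("library sizes must be positive")
    return table.counts.astype(float) * scale / sizes


def mirna_de(
    normalized: pd.DataFrame,
    group_of: Mapping[str, str],
    group_a: str,
    group_b: str,
    *,
    p_max: float = _defaults.MIRNA_P_MAX,
    pseudocount: float = _defaults.LOG_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-miRNA differential expression of ``group_a`` vs ``group_b``.

    Two-sided Student's t-test on log2(normalized + pseudocount); log2FC is
    mean(a) - mean(b) on that scale. Returns a DataFrame indexed by miRNA
    ID with columns ``mean_a``, ``mean_b``, ``log2_fold_change``,
    ``p_value``, ``q_value``, ``significant`` and ``direction``.
    """
    samples_a = [s for s in normalized.columns if group_of[s] == group_a]
    samples_b = [s for s in normalized.columns if group_of[s] == group_b]
    for group, samples in ((group_a, samples_a), (group_b, samples_b)):
        if len(samples) < 2:
            raise ValueError(f"group {group!r} has {len(samples)} samples; need >= 2")
    loga = np.log2(normalized[samples_a].to_numpy(float) + pseudocount)
    logb = np.log2(normalized[samples_b].to_numpy(float) + pseudocount)
    t, p, _ = _two_sample_t(loga, logb)
    log2fc = loga.mean(axis=1) - logb.mean(axis=1)
    significant = p < p_max
    direction = np.where(significant, np.where(log2fc > 0, "up", "down"), "ns")
    return pd.DataFrame(
        {
            "mean_a": normalized[samples_a].mean(axis=1),
            "mean_b": normalized[samples_b].mean(axis=1),
            "log2_fold_change": log2fc,
            "t_statistic": t,
            "p_value": p,
            "q_value": bh_fdr(p),
            "significant": significant,
            "direction": direction,
        },
        index=normalized.index,
    )
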