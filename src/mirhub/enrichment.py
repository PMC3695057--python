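"""Monte Carlo test for regulatory-hub miRNAs.

For a miRNA and a gene set of interest, count predicted targets inside the
set and normalize by the set's mean 3'UTR length (in kb); repeat on many
equally sized gene sets sampled at random from the background universe to
obtain a null distribution, and report an add-one empirical p-value for
the observed, length-normalized target count. Up-regulated miRNAs are
tested against the down-regulated gene set and vice versa; candidates are
ranked by empirical p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import _defaults
from .expression import GeneSet
from .targets import DEFAULT_SITE_TYPES, MiRNASequence, UTRSet, predict_targets

log = logging.getLogger(__name__)


@dataclass
class HubTestConfig:
    """Parameters of the Monte Carlo enrichment test."""

    n_iterations: int = _defaults.N_ITERATIONS
    rng_seed: int = 0
    site_types: frozenset[str] = DEFAULT_SITE_TYPES
    #: sample null gene sets with probability proportional to UTR length
    #: instead of uniformly (alternative normalization strategy).
    length_weighted_null: bool = False
    significance_p: float = _defaults.HUB_P_MAX

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


@dataclass
class HubResult:
    """Observed statistic, null summary and empirical p for one miRNA."""

    mirna_id: str
    direction: str
    n_targets: int
    mean_utr_kb: float
    statistic: float
    null_mean: float
    null_sd: float
    empirical_p: float
    neg_log10_p: float
    significant: bool
    set_size: int
    null_draws: np.ndarray = field(repr=False, default_factory=lambda: np.empty(0))


def observed_statistic(
    mirna: MiRNASequence,
    gene_set: GeneSet | Sequence[str],
    utrs: UTRSet,
    *,
    site_types: frozenset[str] | set[str] = DEFAULT_SITE_TYPES,
) -> tuple[int, float, float]:
    """(T, L, X): target count, mean UTR length in kb, and X = T / L."""
    members = list(gene_set.members if isinstance(gene_set, GeneSet) else gene_set)
    if not members:
        raise ValueError("empty gene set")
    missing = [g for g in members if g not in utrs]
    if missing:
        raise ValueError(f"gene set members without a UTR: {missing[:10]}")
    subset = UTRSet({g: utrs.sequences[g] for g in members})
    n_targets = len(predict_targets(mirna, subset, site_types=site_types))
    mean_kb = float(np.mean([utrs.length_of(g) for g in members])) / 1000.0
    return n_targets, mean_kb, n_targets / mean_kb


def _target_mask(
    mirna: MiRNASequence,
    universe: Sequence[str],
    utrs: UTRSet,
    site_types: frozenset[str] | set[str],
) -> np.ndarray:
    targets = predict_targets(
        mirna, UTRSet({g: utrs.sequences[g] for g in universe}), site_types=site_types
    )
    member_set = set(targets.members)
    return np.fromiter((g in member_set for g in universe), dtype=bool, count=len(universe))


def _null_from_mask(
    is_target: np.ndarray,
    lengths_kb: np.ndarray,
    set_size: int,
    config: HubTestConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    n_universe = is_target.size
    if set_size > n_universe:
        raise ValueError(f"set_size {set_size} exceeds universe size {n_universe}")
    probs = None
    if config.length_weighted_null:
        probs = lengths_kb / lengths_kb.sum()
    draws = np.empty(config.n_iterations, dtype=float)
    for r in range(config.n_iterations):
        idx = rng.choice(n_universe, size=set_size, replace=False, p=probs, shuffle=False)
        draws[r] = is_target[idx].sum() / lengths_kb[idx].mean()
    return draws


def null_distribution(
    mirna: MiRNASequence,
    set_size: int,
    config: HubTestConfig,
    utrs: UTRSet,
    *,
    universe: Sequence[str] | None = None,
) -> np.ndarray:
    """Null draws of X from random same-size gene sets.

    Each of ``config.n_iterations`` draws samples ``set_size`` genes
    uniformly without replacement from the universe (all genes with a UTR
    by default) and computes the length-normalized target count on that
    random set. Bit-reproducible for a fixed ``config.rng_seed``.
    """
    universe = list(universe) if universe is not None else utrs.gene_ids
    is_target = _target_mask(mirna, universe, utrs, config.site_types)
    lengths_kb = np.array([utrs.length_of(g) for g in universe], dtype=float) / 1000.0
    rng = np.random.default_rng(config.rng_seed)
    return _null_from_mask(is_target, lengths_kb, set_size, config, rng)


def empirical_pvalue(observed: float, null_draws: np.ndarray) -> float:
    """Add-one right-tail empirical p: (1 + #{X_r >= X}) / (N + 1)."""
    null_draws = np.asarray(null_draws, dtype=float)
    if null_draws.size == 0:
        raise ValueError("null distribution is empty")
    return (1.0 + int(np.sum(null_draws >= observed))) / (null_draws.size + 1.0)


def run_enrichment_test(
    mirna: MiRNASequence,
    gene_set: GeneSet | Sequence[str],
    utrs: UTRSet,
    config: HubTestConfig,
    *,
    universe: Sequence[str] | None = None,
    direction: str = "NA",
    rng: np.random.Generator | None = None,
) -> HubResult:
    """Full enrichment test of one miRNA against one gene set."""
    members = list(gene_set.members if isinstance(gene_set, GeneSet) else gene_set)
    n_targets, mean_kb, observed = observed_statistic(
        mirna, members, utrs, site_types=config.site_types
    )
    universe = list(universe) if universe is not None else utrs.gene_ids
    is_target = _target_mask(mirna, universe, utrs, config.site_types)
    lengths_kb = np.array([utrs.length_of(g) for g in universe], dtype=float) / 1000.0
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    draws = _null_from_mask(is_target, lengths_kb, len(members), config, rng)
    p = empirical_pvalue(observed, draws)
    return HubResult(
        mirna_id=mirna.id,
        direction=direction,
        n_targets=n_targets,
        mean_utr_kb=mean_kb,
        statistic=observed,
        null_mean=float(draws.mean()),
        null_sd=float(draws.std(ddof=1)) if draws.size > 1 else 0.0,
        empirical_p=p,
        neg_log10_p=-np.log10(p),
        significant=p < config.significance_p,
        set_size=len(members),
        null_draws=draws,
    )


def identify_hubs(
    mirna_results: pd.DataFrame,
    up_genes: GeneSet,
    down_genes: GeneSet,
    utrs: UTRSet,
    mirnas: Mapping[str, MiRNASequence],
    config: HubTestConfig,
    *,
    universe: Sequence[str] | None = None,
) -> list[HubResult]:
    """Rank candidate hub miRNAs for one condition.

    ``mirna_results`` is the output of :func:`mirhub.smallrna.mirna_de`;
    only significant miRNAs are tested. Up-regulated miRNAs are tested
    against the down-regulated gene set and down-regulated miRNAs against
    the up-regulated gene set. Gene-set members without a UTR are dropped
    with a warning before testing. Results are sorted by empirical p
    ascending, ties broken by the observed statistic descending, then ID.
    """
    universe = list(universe) if universe is not None else utrs.gene_ids
    pairing = {"up": down_genes, "down": up_genes}
    results: list[HubResult] = []
    rng = np.random.default_rng(config.rng_seed)
    significant = mirna_results.loc[mirna_results["significant"]]
    for mirna_id, row in significant.iterrows():
        direction = str(row["direction"])
        gene_set = pairing.get(direction)
        if gene_set is None:
            continue
        if mirna_id not in mirnas:
            raise KeyError(f"significant miRNA {mirna_id!r} has no mature sequence")
        members = [g for g in gene_set.members if g in utrs]
        dropped = len(gene_set) - len(members)
        if dropped:
            log.warning("identify_hubs: %d/%d genes in %s lack a UTR and were dropped",
                        dropped, len(gene_set), gene_set.label)
        if not members:
            log.warning("identify_hubs: empty gene set for %s; skipping", mirna_id)
            continue
        results.append(
            run_enrichment_test(
                mirnas[str(mirna_id)], members, utrs, config,
                universe=universe, direction=direction, rng=rng,
            )
        )
    if not results:
        log.warning("identify_hubs: no testable miRNAs")
    results.sort(key=lambda r: (r.empirical_p, -r.statistic, r.mirna_id))
    return results


def hub_table(results: Sequence[HubResult]) -> pd.DataFrame:
    """Flatten HubResults into the report table."""
    return pd.DataFrame(
        [
            {
                "mirna_id": r.mirna_id,
                "direction": r.direction,
                "n_targets": r.n_targets,
                "mean_utr_kb": r.mean_utr_kb,
                "targets_per_kb": r.statistic,
                "null_mean": r.null_mean,
                "null_sd": r.null_sd,
                "empirical_p": r.empirical_p,
                "neg_log10_p": r.neg_log10_p,
                "significant": r.significant,
                "set_size": r.set_size,
            }
            for r in results
        ]
    )


def plot_hubs(results: Sequence[HubResult], path, *, significance_p: float = _defaults.HUB_P_MAX):
    """Bar plot of -log10 empirical p per miRNA with the significance line."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(4, 0.5 * len(results)), 4))
    ids = [r.mirna_id for r in results]
    heights = [r.neg_log10_p for r in results]
    ax.bar(ids, heights, color=["tab:orange" if r.significant else "tab:gray" for r in results])
    ax.axhline(-np.log10(significance_p), linestyle="--", color="black", linewidth=1)
    ax.set_ylabel("-log10 empirical p")
    ax.set_xlabel("miRNA")
    plt.xticks(rotation=90)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
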