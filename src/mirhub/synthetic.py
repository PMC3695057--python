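"""Synthetic dataset generation with planted ground truth.

Generates every input the pipeline consumes — 3'UTR FASTA, mature miRNA
FASTA, a three-condition log2 expression matrix, a miRNA count table with
library sizes, promoter sequences and TRANSFAC matrices — while recording
which miRNAs are hubs, which genes carry planted target sites and where
motifs were planted, so every downstream stage can be tested without
external data.

The default scenario mirrors a paired design: one hub miRNA is
down-regulated in condition 1 with its planted targets up-regulated, and
a second hub is up-regulated in condition 2 with its targets
down-regulated.

Every generator is a pure function of its configuration and seed.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .io import write_fasta, write_json, write_matrix
from .seq import revcomp
from .smallrna import MiRNACountTable
from .targets import MiRNASequence, UTRSet, site_words
from .promoter import PWMModel

log = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class HubSpec:
    """One planted hub miRNA: its direction and the effect on its targets."""

    condition: str
    mirna_id: str
    direction: str  # regulation of the miRNA itself in `condition`
    target_fraction: float = 0.4
    target_log2_effect: float = 1.0
    site_type: str = "8mer"
    # 8-fold shift: with 4 replicates and NB dispersion 0.2 the per-sample
    # log2-CPM sd is ~0.65, so smaller shifts are frequently missed by the
    # 4v4 t-test and the hub is never tested downstream
    mirna_log2_effect: float = 3.0

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down"):
            raise ValueError(f"hub direction must be up/down, got {self.direction!r}")
        if not 0.0 <= self.target_fraction <= 1.0:
            raise ValueError("target_fraction must lie in [0, 1]")
        for name in ("target_log2_effect", "mirna_log2_effect"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    @property
    def target_shift_sign(self) -> float:
        """Targets move opposite to the miRNA: down-miRNA -> up-targets."""
        return 1.0 if self.direction == "down" else -1.0


@dataclass
class ScenarioConfig:
    """Configuration of a full synthetic study."""

    n_genes: int = 2000
    n_mirnas: int = 30
    utr_length_mean: float = 800.0
    utr_length_sd: float = 200.0
    gc_fraction: float = 0.5
    mirna_length: int = 22
    groups: Sequence[tuple[str, int]] = (("naive", 4), ("cond1", 4), ("cond2", 4))
    reference_group: str = "naive"
    hubs: Sequence[HubSpec] = field(
        default_factory=lambda: [
            HubSpec(condition="cond1", mirna_id="mir-001", direction="down"),
            HubSpec(condition="cond2", mirna_id="mir-002", direction="up"),
        ]
    )
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    noise_sd: float = 0.25
    nb_dispersion: float = 0.2
    mirna_count_log_mean: float = 6.0
    mirna_count_log_sd: float = 1.0
    hub_min_base_mean: float = 500.0
    nominal_library_size: float = 2_000_000.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.utr_length_mean < 30:
            raise ValueError("utr_length_mean must be >= 30")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction must lie in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.noise_sd <= 0 or not math.isfinite(self.noise_sd):
            raise ValueError("noise_sd must be positive and finite")
        group_labels = [g for g, _ in self.groups]
        if len(set(group_labels)) != len(group_labels):
            raise ValueError("duplicate group labels")
        if self.reference_group not in group_labels:
            raise ValueError(f"reference group {self.reference_group!r} not in groups")
        for label, n_rep in self.groups:
            if n_rep < 2:
                raise ValueError(f"group {label!r} needs >= 2 replicates")
        for hub in self.hubs:
            if hub.condition not in group_labels:
                raise ValueError(f"hub condition {hub.condition!r} not in groups")
            if hub.target_fraction > 0 and hub.target_fraction * self.n_genes < 1:
                raise ValueError("target_fraction * n_genes must be >= 1 for a planted hub")

    @property
    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"gene_{i + 1:0{width}d}" for i in range(self.n_genes)]

    @property
    def mirna_ids(self) -> list[str]:
        width = max(3, len(str(self.n_mirnas)))
        return [f"mir-{i + 1:0{width}d}" for i in range(self.n_mirnas)]

    @property
    def sample_ids(self) -> list[str]:
        return [f"{label}_{i + 1}" for label, n in self.groups for i in range(n)]

    @property
    def group_of(self) -> dict[str, str]:
        return {f"{label}_{i + 1}": label for label, n in self.groups for i in range(n)}


@dataclass
class TruthTable:
    """Planted ground truth of a scenario."""

    hub_by_condition: dict[str, str] = field(default_factory=dict)
    targets_by_hub: dict[str, list[str]] = field(default_factory=dict)
    site_positions: dict[str, dict[str, int]] = field(default_factory=dict)
    motif_positions: dict[str, tuple[int, str]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        write_json(
            {
                "hub_by_condition": self.hub_by_condition,
                "targets_by_hub": self.targets_by_hub,
                "site_positions": self.site_positions,
                "motif_positions": {k: list(v) for k, v in self.motif_positions.items()},
            },
            path,
        )


@dataclass
class ScenarioBundle:
    """All generated inputs plus the truth table."""

    config: ScenarioConfig
    expression: ExpressionMatrix
    mirna_counts: MiRNACountTable
    utrs: UTRSet
    mirnas: dict[str, MiRNASequence]
    truth: TruthTable


def _random_sequences(
    rng: np.random.Generator, lengths: Sequence[int], gc_fraction: float
) -> list[str]:
    p = np.array(
        [
            (1 - gc_fraction) / 2,  # A
            gc_fraction / 2,        # C
            gc_fraction / 2,        # G
            (1 - gc_fraction) / 2,  # T
        ]
    )
    total = int(np.sum(lengths))
    flat = _BASES[rng.choice(4, size=total, p=p)]
    out: list[str] = []
    offset = 0
    for n in lengths:
        out.append(flat[offset:offset + n].tobytes().decode())
        offset += n
    return out


def generate_utr_set(
    config: ScenarioConfig, rng: np.random.Generator | None = None
) -> UTRSet:
    """One random 3'UTR per gene; lengths ~ Normal(mean, sd) truncated >= 30."""
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    lengths = np.round(
        rng.normal(config.utr_length_mean, config.utr_length_sd, size=config.n_genes)
    ).astype(int)
    while (lengths < 30).any():
        redo = lengths < 30
        lengths[redo] = np.round(
            rng.normal(config.utr_length_mean, config.utr_length_sd, size=int(redo.sum()))
        ).astype(int)
    seqs = _random_sequences(rng, lengths, config.gc_fraction)
    return UTRSet(dict(zip(config.gene_ids, seqs)))


def generate_mirna_set(
    config: ScenarioConfig, rng: np.random.Generator | None = None
) -> dict[str, MiRNASequence]:
    """Random mature miRNA sequences (uniform base composition)."""
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    seqs = _random_sequences(rng, [config.mirna_length] * config.n_mirnas, 0.5)
    return {mid: MiRNASequence(mid, seq) for mid, seq in zip(config.mirna_ids, seqs)}


def _round_half_up(x: float) -> int:
    """Nearest integer, ties rounded up (the documented planting rule)."""
    return int(math.floor(x + 0.5))


def plant_seed_sites(
    utrs: UTRSet,
    mirna: MiRNASequence,
    fraction: float,
    site_type: str,
    rng: np.random.Generator | int,
    *,
    reserved: dict[str, list[tuple[int, int]]] | None = None,
) -> tuple[UTRSet, dict[str, int]]:
    """Overwrite a random fraction of UTRs with one exact site each.

    Recipients are chosen uniformly; within each recipient the site word of
    ``site_type`` overwrites existing bases at a random position, so UTR
    lengths are unchanged. The number of recipients is
    ``round_half_up(fraction * n_genes)``. Positions overlapping spans in
    ``reserved`` (earlier plants) are avoided; chosen spans are appended to
    ``reserved`` in place. Chance sites in non-recipients are neither
    removed nor recorded.

    Returns the modified UTR set and ``{gene_id: planted_start}``.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    word = site_words(mirna)[site_type]
    shortest = min(len(s) for s in utrs.sequences.values())
    if len(word) > shortest:
        raise ValueError(f"site word ({len(word)} nt) longer than shortest UTR ({shortest} nt)")
    gene_ids = utrs.gene_ids
    n_recipients = _round_half_up(fraction * len(gene_ids))
    if n_recipients == 0:
        return UTRSet(dict(utrs.sequences)), {}
    recipients = [gene_ids[i] for i in sorted(rng.choice(len(gene_ids), size=n_recipients, replace=False))]
    sequences = dict(utrs.sequences)
    planted: dict[str, int] = {}
    reserved = reserved if reserved is not None else {}
    w = len(word)
    for gene_id in recipients:
        seq = sequences[gene_id]
        blocked = reserved.get(gene_id, [])
        allowed = [
            p for p in range(len(seq) - w + 1)
            if all(p + w <= s or p >= e for s, e in blocked)
        ]
        if not allowed:
            log.warning("plant_seed_sites: no free position in %s; skipped", gene_id)
            continue
        pos = int(allowed[rng.integers(len(allowed))])
        sequences[gene_id] = seq[:pos] + word + seq[pos + w:]
        reserved.setdefault(gene_id, []).append((pos, pos + w))
        planted[gene_id] = pos
    return UTRSet(sequences), planted


def generate_hub_scenario(config: ScenarioConfig) -> ScenarioBundle:
    """Full synthetic dataset with planted hub structure.

    Baseline log2 expression per gene is Normal(mu_g, noise_sd) around a
    gene-level mean mu_g; planted targets are shifted by the hub's
    ``target_log2_effect`` (sign opposite to the hub miRNA's direction) in
    the hub's condition. miRNA counts are negative binomial with the hub
    miRNAs shifted by ``mirna_log2_effect`` in their condition; per-sample
    library sizes scale with a simulated sequencing-depth factor.
    """
    rng = np.random.default_rng(config.rng_seed)
    utrs = generate_utr_set(config, rng)
    mirnas = generate_mirna_set(config, rng)
    truth = TruthTable()
    reserved: dict[str, list[tuple[int, int]]] = {}
    for hub in config.hubs:
        if hub.mirna_id not in mirnas:
            raise ValueError(f"hub miRNA {hub.mirna_id!r} not in generated miRNA set")
        utrs, planted = plant_seed_sites(
            utrs, mirnas[hub.mirna_id], hub.target_fraction, hub.site_type, rng,
            reserved=reserved,
        )
        truth.hub_by_condition[hub.condition] = hub.mirna_id
        truth.targets_by_hub[hub.mirna_id] = sorted(planted)
        truth.site_positions[hub.mirna_id] = planted

    # --- expression matrix -------------------------------------------------
    sample_ids = config.sample_ids
    group_of = config.group_of
    mu = rng.normal(config.baseline_mean, config.baseline_sd, size=config.n_genes)
    values = mu[:, None] + rng.normal(
        0.0, config.noise_sd, size=(config.n_genes, len(sample_ids))
    )
    gene_index = {g: i for i, g in enumerate(config.gene_ids)}
    for hub in config.hubs:
        cols = [j for j, s in enumerate(sample_ids) if group_of[s] == hub.condition]
        rows = [gene_index[g] for g in truth.targets_by_hub.get(hub.mirna_id, [])]
        if rows and cols:
            shift = hub.target_shift_sign * hub.target_log2_effect
            values[np.ix_(rows, cols)] += shift
    expression = ExpressionMatrix(
        pd.DataFrame(values, index=config.gene_ids, columns=sample_ids), group_of
    )

    # --- miRNA counts ------------------------------------------------------
    base_means = np.exp(
        rng.normal(config.mirna_count_log_mean, config.mirna_count_log_sd,
                   size=config.n_mirnas)
    )
    mirna_index = {m: i for i, m in enumerate(config.mirna_ids)}
    for hub in config.hubs:
        i = mirna_index[hub.mirna_id]
        base_means[i] = max(base_means[i], config.hub_min_base_mean)
    depth = rng.uniform(0.7, 1.3, size=len(sample_ids))
    means = base_means[:, None] * depth[None, :]
    for hub in config.hubs:
        i = mirna_index[hub.mirna_id]
        cols = [j for j, s in enumerate(sample_ids) if group_of[s] == hub.condition]
        factor = 2.0 ** (hub.mirna_log2_effect if hub.direction == "up" else -hub.mirna_log2_effect)
        means[i, cols] *= factor
    n_param = 1.0 / config.nb_dispersion
    counts = rng.negative_binomial(n_param, n_param / (n_param + means))
    library_sizes = pd.Series(
        np.round(depth * config.nominal_library_size).astype(np.int64), index=sample_ids
    )
    mirna_counts = MiRNACountTable(
        pd.DataFrame(counts, index=config.mirna_ids, columns=sample_ids),
        library_sizes,
        group_of,
    )
    return ScenarioBundle(config, expression, mirna_counts, utrs, mirnas, truth)


def generate_promoter_set(
    n: int,
    pwm: PWMModel,
    plant_fraction: float,
    rng_seed: int,
    *,
    length: int = 1500,
    gc_fraction: float = 0.5,
) -> tuple[dict[str, str], dict[str, tuple[int, str]]]:
    """Random promoter sequences with the PWM consensus planted in some.

    Planted promoters receive the consensus word (reverse-complemented for
    a minus-strand plant) at a recorded position. Returns the sequences
    and ``{promoter_id: (position, strand)}`` for the recipients.
    """
    if not 0.0 <= plant_fraction <= 1.0:
        raise ValueError("plant_fraction must lie in [0, 1]")
    if pwm.width > length:
        raise ValueError("PWM wider than promoter length")
    rng = np.random.default_rng(rng_seed)
    width = len(str(max(n, 1)))
    ids = [f"promoter_{i + 1:0{width}d}" for i in range(n)]
    seqs = dict(zip(ids, _random_sequences(rng, [length] * n, gc_fraction)))
    n_recipients = _round_half_up(plant_fraction * n)
    truth: dict[str, tuple[int, str]] = {}
    if n_recipients:
        recipients = [ids[i] for i in sorted(rng.choice(n, size=n_recipients, replace=False))]
        consensus = pwm.consensus
        w = pwm.width
        for pid in recipients:
            pos = int(rng.integers(length - w + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            word = consensus if strand == "+" else revcomp(consensus)
            seq = seqs[pid]
            seqs[pid] = seq[:pos] + word + seq[pos + w:]
            truth[pid] = (pos, strand)
    return seqs, truth


def write_scenario(bundle: ScenarioBundle, outdir: str | Path) -> dict[str, Path]:
    """Write every generated input as plain-text files plus metadata."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "utrs": outdir / "utrs.fasta",
        "mirnas": outdir / "mirnas.fasta",
        "expression": outdir / "expression.tsv",
        "groups": outdir / "groups.tsv",
        "mirna_counts": outdir / "mirna_counts.tsv",
        "library_sizes": outdir / "library_sizes.tsv",
        "truth": outdir / "truth.json",
        "metadata": outdir / "metadata.json",
    }
    bundle.utrs.to_fasta(paths["utrs"])
    write_fasta({m.id: m.sequence for m in bundle.mirnas.values()}, paths["mirnas"])
    write_matrix(bundle.expression.values, paths["expression"], index_label="gene_id")
    with open(paths["groups"], "w") as fh:
        fh.write("sample\tgroup\n")
        for sample, group in bundle.expression.group_of.items():
            fh.write(f"{sample}\t{group}\n")
    write_matrix(bundle.mirna_counts.counts, paths["mirna_counts"], index_label="mirna_id")
    with open(paths["library_sizes"], "w") as fh:
        fh.write("sample\tlibrary_size\n")
        for sample, size in bundle.mirna_counts.library_sizes.items():
            fh.write(f"{sample}\t{int(size)}\n")
    bundle.truth.to_json(paths["truth"])
    meta = asdict(bundle.config)
    meta["groups"] = [list(g) for g in bundle.config.groups]
    write_json({"scenario_config": meta, "rng_seed": bundle.config.rng_seed}, paths["metadata"])
    return paths
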