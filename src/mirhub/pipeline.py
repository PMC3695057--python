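"""End-to-end workflow: inputs -> DE -> miRNA DE -> hub ranking.

A pipeline run is driven by a single configuration (YAML or dict) naming
either a synthetic scenario to generate or paths to real inputs, plus all
module parameters. Outputs are plain-text tables and a JSON manifest that
records parameters, seeds and input checksums, sufficient to re-run the
exact computation. Runs are deterministic: identical config and seeds
yield byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import _defaults, __version__
from .enrichment import HubTestConfig, hub_table, identify_hubs
from .expression import (
    ExpressionMatrix,
    differential_expression,
    overlap_analysis,
    quantile_normalize,
    significant_genes,
)
from .io import sha256_file, write_json, write_matrix
from .smallrna import MiRNACountTable, filter_low_counts, mirna_de, normalize_counts
from .targets import DEFAULT_SITE_TYPES, UTRSet, load_mirnas

log = logging.getLogger(__name__)

_INPUT_KEYS = ("expression", "groups", "mirna_counts", "library_sizes", "utrs", "mirnas")


class PipelineConfigError(ValueError):
    """Bad or contradictory pipeline configuration."""


@dataclass
class PipelineConfig:
    """Validated pipeline configuration.

    Exactly one of ``scenario`` (synthetic-data parameters) or ``inputs``
    (paths to expression/groups/mirna_counts/library_sizes/utrs/mirnas
    files) must be provided.
    """

    output_dir: str
    scenario: dict[str, Any] | None = None
    inputs: dict[str, str] | None = None
    parameters: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.scenario is None) == (self.inputs is None):
            raise PipelineConfigError(
                "config must provide exactly one of 'scenario' or 'inputs'"
            )
        if self.inputs is not None:
            missing_keys = [k for k in _INPUT_KEYS if k not in self.inputs]
            if missing_keys:
                raise PipelineConfigError(f"missing input paths: {missing_keys}")
            absent = [p for p in self.inputs.values() if not Path(p).exists()]
            if absent:
                raise PipelineConfigError(f"input files do not exist: {absent}")
        unknown = set(self.parameters) - set(default_parameters())
        if unknown:
            raise PipelineConfigError(f"unknown parameters: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise PipelineConfigError(f"config {path} is not a mapping")
        try:
            return cls(
                output_dir=raw["output_dir"],
                scenario=raw.get("scenario"),
                inputs=raw.get("inputs"),
                parameters=raw.get("parameters", {}),
            )
        except KeyError as exc:
            raise PipelineConfigError(f"missing config key: {exc}") from None

    def resolved_parameters(self) -> dict[str, Any]:
        params = default_parameters()
        params.update(self.parameters)
        return params


def default_parameters() -> dict[str, Any]:
    """The single defaults table surfaced in config schema and CLI help."""
    return {
        "quantile_normalize": True,
        "reference_group": "naive",
        "fdr_max": _defaults.FDR_MAX,
        "fold_min": _defaults.FOLD_MIN,
        "welch": False,
        "min_count": _defaults.MIN_COUNT,
        "filter_mode": "any",
        "cpm_scale": _defaults.CPM_SCALE,
        "log_pseudocount": _defaults.LOG_PSEUDOCOUNT,
        "mirna_p_max": _defaults.MIRNA_P_MAX,
        "n_iterations": _defaults.N_ITERATIONS,
        "hub_seed": 0,
        "hub_p_max": _defaults.HUB_P_MAX,
        "site_types": sorted(DEFAULT_SITE_TYPES),
        "length_weighted_null": False,
    }


def _load_inputs(config: PipelineConfig):
    from .synthetic import ScenarioConfig, HubSpec, generate_hub_scenario

    if config.scenario is not None:
        raw = dict(config.scenario)
        if "hubs" in raw:
            raw["hubs"] = [HubSpec(**h) for h in raw["hubs"]]
        if "groups" in raw:
            raw["groups"] = [tuple(g) for g in raw["groups"]]
        scenario = ScenarioConfig(**raw)
        bundle = generate_hub_scenario(scenario)
        return bundle.expression, bundle.mirna_counts, bundle.utrs, bundle.mirnas, bundle
    paths = config.inputs
    expression = ExpressionMatrix.from_tsv(paths["expression"], paths["groups"])
    counts = MiRNACountTable.from_tsv(
        paths["mirna_counts"], paths["library_sizes"], paths["groups"]
    )
    utrs = UTRSet.from_fasta(paths["utrs"])
    mirnas = load_mirnas(paths["mirnas"])
    return expression, counts, utrs, mirnas, None


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run the full scenario -> hub report workflow.

    Stages: (optional) quantile normalization; per-condition gene DE vs the
    reference group gated at FDR/fold-change; miRNA count filtering,
    normalization and DE; Monte Carlo hub identification per condition;
    overlap accounting between condition gene sets; manifest.

    Returns a summary dict (also written as ``manifest.json``).
    """
    params = config.resolved_parameters()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    expression, counts, utrs, mirnas, bundle = _load_inputs(config)
    if bundle is not None:
        from .synthetic import write_scenario

        write_scenario(bundle, outdir / "scenario")

    reference = params["reference_group"]
    groups = sorted({g for g in expression.group_of.values() if g != reference})
    if reference not in expression.group_of.values():
        raise PipelineConfigError(f"reference group {reference!r} not found in samples")

    if params["quantile_normalize"]:
        expression = quantile_normalize(expression)
    log.info("expression: %d genes x %d samples; conditions %s vs %s",
             len(expression.gene_ids), len(expression.sample_ids), groups, reference)

    filtered = filter_low_counts(
        counts, min_count=params["min_count"], mode=params["filter_mode"]
    )
    normalized = normalize_counts(filtered, scale=params["cpm_scale"])
    log.info("miRNAs: %d raw, %d after count filter", len(counts.mirna_ids),
             len(filtered.mirna_ids))

    site_types = frozenset(params["site_types"])
    hub_config = HubTestConfig(
        n_iterations=params["n_iterations"],
        rng_seed=params["hub_seed"],
        site_types=site_types,
        length_weighted_null=params["length_weighted_null"],
        significance_p=params["hub_p_max"],
    )

    summary: dict[str, Any] = {"conditions": {}}
    gene_sets = {}
    for condition in groups:
        de = differential_expression(
            expression, condition, reference, welch=params["welch"]
        )
        write_matrix(de, outdir / f"de_{condition}.tsv", index_label="gene_id")
        sig = significant_genes(
            de, fdr_max=params["fdr_max"], fold_min=params["fold_min"],
            label=f"{condition}_vs_{reference}",
        )
        sig.to_tsv(outdir / f"genes_{condition}.tsv")
        gene_sets[condition] = sig
        up = {g: d for g, d in sig.directions.items() if d == "up"}
        down = {g: d for g, d in sig.directions.items() if d == "down"}

        mde = mirna_de(
            normalized, counts.group_of, condition, reference,
            p_max=params["mirna_p_max"], pseudocount=params["log_pseudocount"],
        )
        write_matrix(mde, outdir / f"mirna_de_{condition}.tsv", index_label="mirna_id")

        from .expression import GeneSet

        hubs = identify_hubs(
            mde,
            GeneSet(f"up_{condition}", dict(up)),
            GeneSet(f"down_{condition}", dict(down)),
            utrs,
            mirnas,
            hub_config,
        )
        table = hub_table(hubs)
        write_matrix(
            table.set_index("mirna_id") if not table.empty else table,
            outdir / f"hubs_{condition}.tsv",
            index_label="mirna_id",
        )
        write_json(
            {
                "condition": condition,
                "n_iterations": hub_config.n_iterations,
                "rng_seed": hub_config.rng_seed,
                "universe_size": len(utrs),
                "results": table.to_dict(orient="records"),
            },
            outdir / f"hubs_{condition}.json",
        )
        summary["conditions"][condition] = {
            "n_genes_significant": len(sig),
            "n_genes_up": len(up),
            "n_genes_down": len(down),
            "n_mirnas_significant": int(mde["significant"].sum()),
            "n_hubs_tested": len(hubs),
            "top_hub": hubs[0].mirna_id if hubs else None,
        }

    if len(groups) >= 2:
        report = overlap_analysis(gene_sets[groups[0]], gene_sets[groups[1]])
        write_json(report.to_dict(), outdir / "overlap.json")
        summary["overlap"] = {
            "n_common": report.n_common,
            "n_unique_a": len(report.unique_a),
            "n_unique_b": len(report.unique_b),
            "n_concordant": report.concordant,
        }

    manifest = {
        "mirhub_version": __version__,
        "parameters": params,
        "scenario": config.scenario,
        "input_checksums": (
            {k: sha256_file(v) for k, v in config.inputs.items()}
            if config.inputs
            else None
        ),
        "summary": summary,
    }
    write_json(manifest, outdir / "manifest.json")
    return manifest
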