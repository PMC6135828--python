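"""End-to-end orchestration: quant → enrichment → profiles → differential net.

The pipeline mirrors the analysis order of a tag-position AP-MS study:
per-run quantitation, enrichment calls against tag-only controls,
complex-profile summaries with hierarchical clustering, and the N-vs-C
differential network.  All stage outputs are written as fixed-column,
full-precision TSV (plus GraphML/SIF/JSON and Newick) with a JSON manifest,
so reruns with the same inputs are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict, field
from pathlib import Path

import pandas as pd
import yaml

from . import diffnet, enrichment, profiles, quant
from .errors import APMSError, ConfigurationError
from .io import ProteinDB, read_evidence_table, read_protein_fasta, read_sample_sheet

logger = logging.getLogger("apmsnet")


@dataclass
class PipelineConfig:
    """Thresholds and knobs of the full pipeline (defaults as published)."""

    log2fc_min: float = 2.0
    fdr_max: float = 0.05
    detect_min: float = 0.5
    min_change: float = 0.2
    pseudocount: float = 0.5
    linkage: str = "complete"
    scale: float = 1000.0
    consensus: str = "mean"
    network_formats: tuple[str, ...] = ("graphml", "sif", "json")
    seed: int = 0
    out_dir: str = "apmsnet_out"

    def validate(self) -> None:
        if self.fdr_max <= 0 or self.fdr_max > 1:
            raise ConfigurationError("fdr_max must lie in (0, 1]")
        if self.detect_min < 0 or self.detect_min > 1:
            raise ConfigurationError("detect_min must lie in [0, 1]")
        if self.min_change < 0:
            raise ConfigurationError("min_change must be non-negative")
        if self.pseudocount <= 0:
            raise ConfigurationError("pseudocount must be positive")
        if self.scale <= 0:
            raise ConfigurationError("scale must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "network_formats" in data:
            data["network_formats"] = tuple(data["network_formats"])
        return cls(**data)


@dataclass
class PipelineResult:
    quant: pd.DataFrame
    aggregates: pd.DataFrame
    enrichment: pd.DataFrame
    edges: pd.DataFrame
    node_shares: pd.DataFrame
    profile: pd.DataFrame
    paths: dict[str, Path] = field(default_factory=dict)


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            logger.info("stage %s: start", name)
            try:
                return fn(*args, **kwargs)
            except APMSError as exc:
                raise APMSError(f"[{name}] {exc}") from exc

        return wrapper

    return deco


def run_pipeline(
    config: PipelineConfig,
    evidence_by_run: dict[str, pd.DataFrame],
    sample_sheet: pd.DataFrame,
    db: ProteinDB,
    definitions: pd.DataFrame | None = None,
    write: bool = True,
) -> PipelineResult:
    """Run every stage on in-memory inputs; optionally write all outputs."""
    config.validate()
    definitions = definitions if definitions is not None else profiles.load_builtin_complexes()
    thresholds = {
        "log2fc_min": config.log2fc_min,
        "fdr_max": config.fdr_max,
        "detect_min": config.detect_min,
    }

    quant_long = _stage("quant")(quant.quantify_experiment)(
        evidence_by_run, db, sample_sheet
    )
    aggregates = quant.aggregate_experiment(quant_long, sample_sheet)

    records = _stage("enrich")(enrichment.call_enrichment)(
        quant_long, sample_sheet, pseudocount=config.pseudocount, thresholds=thresholds
    )
    sig = enrichment.significant_sets(records)

    conditions = sorted(
        set(sample_sheet.loc[sample_sheet["condition"] != "control", "condition"])
    )
    edges = pd.DataFrame(
        columns=["prey_id", "w_N", "w_C", "delta", "direction", "width_value"]
    )
    node_shares = pd.DataFrame()
    if set(conditions) >= {"N", "C"}:
        net_n = _stage("diffnet")(diffnet.build_condition_network)(
            aggregates, sig, "N", consensus=config.consensus
        )
        net_c = diffnet.build_condition_network(
            aggregates, sig, "C", consensus=config.consensus
        )
        edges = diffnet.build_differential_network(
            net_n, net_c, min_change=config.min_change
        )
        mat = profiles.profile_matrix(aggregates, scale=1.0)
        involved = mat.reindex(edges["prey_id"], fill_value=0.0)
        node_shares = diffnet.node_share_attributes(involved)

    profile = _stage("profile")(profiles.profile_matrix)(aggregates, scale=config.scale)

    result = PipelineResult(quant_long, aggregates, records, edges, node_shares, profile)
    if write:
        result.paths = _write_outputs(config, result, definitions, aggregates)
    return result


def _write_outputs(
    config: PipelineConfig,
    result: PipelineResult,
    definitions: pd.DataFrame,
    aggregates: pd.DataFrame,
) -> dict[str, Path]:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def save(name: str, frame: pd.DataFrame, index: bool = False) -> None:
        p = out / name
        frame.to_csv(p, sep="\t", index=index, float_format="%.17g")
        paths[name] = p

    save("quant.tsv", result.quant)
    save("aggregates.tsv", aggregates)
    save("enrichment.tsv", result.enrichment)
    for fmt in config.network_formats:
        ext = {"graphml": "graphml", "sif": "sif", "json": "json"}[fmt]
        p = out / f"differential_network.{ext}"
        diffnet.export_network(
            result.edges,
            p,
            fmt,
            result.node_shares if not result.node_shares.empty else None,
        )
        paths[p.name] = p
    if not result.node_shares.empty:
        save("node_shares.tsv", result.node_shares, index=True)
    if result.profile.shape[0] >= 2:
        ppaths = profiles.write_profile_outputs(
            result.profile, out, definitions=definitions, aggregates=aggregates
        )
        paths.update({p.name: p for p in ppaths.values()})
    manifest = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(config).items()
        },
        "outputs": sorted(str(p.name) for p in paths.values()),
        "thresholds": {
            "log2fc_min": config.log2fc_min,
            "fdr_max": config.fdr_max,
            "detect_min": config.detect_min,
            "min_change": config.min_change,
        },
    }
    logger.info("thresholds used: %s", manifest["thresholds"])
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    paths["manifest.json"] = out / "manifest.json"
    return paths


def run_pipeline_from_paths(
    config: PipelineConfig,
    fasta: str | Path,
    sample_sheet_path: str | Path,
    evidence_dir: str | Path,
    definitions: pd.DataFrame | None = None,
) -> PipelineResult:
    """File-based entry point: read inputs with the package readers, then run."""
    db = read_protein_fasta(fasta)
    sheet = read_sample_sheet(sample_sheet_path)
    evidence_dir = Path(evidence_dir)
    evidence = {
        run_id: read_evidence_table(evidence_dir / f"{run_id}.tsv")
        for run_id in sheet["run_id"]
    }
    return run_pipeline(config, evidence, sheet, db, definitions=definitions)
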