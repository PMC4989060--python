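"""End-to-end orchestration: build -> partition -> select -> score (-> enrich).

``run_pipeline`` executes the full analysis from a single
:class:`PipelineConfig`, writes every intermediate table into a run
directory and records a machine-readable manifest (parameters, seed,
input checksums, per-stage row counts). Identical configuration and
inputs produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io, network as net, partition as part, scoring, selection
from .datatypes import ModuleSet
from .enrichment import enrich_modules
from .errors import ConfigurationError

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All inputs and thresholds for one pipeline run."""

    normal_expression: str
    cancer_expression: str
    string_network: str
    gene_sets: str | None = None
    outdir: str = "coexmark_run"
    top_fraction: float = 0.01
    min_score: int = 500
    min_module_size: int = 5
    fdr_cut: float = 0.01
    lfc_cut: float = 2.0
    top_k: int = 10
    seed: int = 0
    normalization: str = "quantile"
    lfc_scale: str = "linear"
    restrict_pairs_to_network: bool = False
    within_module_only: bool = False

    def validate(self) -> None:
        if not 0.0 < self.top_fraction < 0.5:
            raise ConfigurationError(f"top_fraction: must lie in (0, 0.5), got {self.top_fraction}")
        if not 0 <= self.min_score <= 1000:
            raise ConfigurationError(f"min_score: must lie in [0, 1000], got {self.min_score}")
        if self.min_module_size < 1:
            raise ConfigurationError("min_module_size: must be >= 1")
        if not 0.0 <= self.fdr_cut <= 1.0:
            raise ConfigurationError(f"fdr_cut: must lie in [0, 1], got {self.fdr_cut}")
        if self.lfc_cut < 0:
            raise ConfigurationError("lfc_cut: must be >= 0")
        if self.top_k < 1:
            raise ConfigurationError("top_k: must be >= 1")
        if self.normalization not in ("quantile", "none"):
            raise ConfigurationError(f"normalization: unknown method {self.normalization!r}")
        if self.lfc_scale not in ("linear", "log"):
            raise ConfigurationError(f"lfc_scale: must be 'linear' or 'log'")
        for name in ("normal_expression", "cancer_expression", "string_network"):
            p = getattr(self, name)
            if not Path(p).is_file():
                raise ConfigurationError(f"{name}: file not found: {p}")
        if self.gene_sets is not None and not Path(self.gene_sets).is_file():
            raise ConfigurationError(f"gene_sets: file not found: {self.gene_sets}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text())
        if not isinstance(payload, dict):
            raise ConfigurationError(f"{path}: expected a mapping at top level")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ConfigurationError(f"{path}: unknown keys {sorted(unknown)}")
        return cls(**payload)


@dataclass
class PipelineResult:
    """Handles to everything a run produced."""

    outdir: Path
    specific_network: "object"
    modules: ModuleSet
    module_results: list
    biomarkers: list
    up: list
    down: list
    manifest: dict


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full biomarker-prediction analysis; see module docstring."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "parameters": dataclasses.asdict(config),
        "inputs": {
            "normal_expression": _sha256(config.normal_expression),
            "cancer_expression": _sha256(config.cancer_expression),
            "string_network": _sha256(config.string_network),
        },
        "stages": {},
    }
    if config.gene_sets:
        manifest["inputs"]["gene_sets"] = _sha256(config.gene_sets)

    stage = "load"
    try:
        normal = net.read_expression(config.normal_expression, condition="normal")
        cancer = net.read_expression(config.cancer_expression, condition="cancer")
        functional = io.read_string_network(config.string_network)

        stage = "build-network"
        normal = net.normalize(normal, method=config.normalization)
        cancer = net.normalize(cancer, method=config.normalization)
        filtered = net.filter_functional_network(functional, min_score=config.min_score)
        universe = sorted(filtered.scores) if config.restrict_pairs_to_network else None
        status_n = net.coexpression_status(
            normal, pair_universe=universe, top_fraction=config.top_fraction
        )
        status_c = net.coexpression_status(
            cancer, pair_universe=universe, top_fraction=config.top_fraction
        )
        specific = net.build_specific_network(status_n, status_c, filtered)
        io.write_specific_network(specific, outdir / "specific_network.tsv")
        manifest["stages"]["build-network"] = {
            "functional_edges": functional.n_edges,
            "filtered_edges": filtered.n_edges,
            "specific_nodes": specific.n_nodes,
            "specific_edges": specific.n_edges,
        }

        stage = "partition"
        mods = part.partition_network(specific, seed=config.seed)
        mods = part.filter_modules(mods, min_size=config.min_module_size)
        io.write_modules(mods, outdir / "modules.tsv")
        manifest["stages"]["partition"] = {
            "modules": len(mods),
            "genes_in_modules": len(mods.genes),
        }

        stage = "select-modules"
        results = selection.select_specific_modules(
            mods, normal, cancer,
            fdr_cut=config.fdr_cut, lfc_cut=config.lfc_cut, lfc_scale=config.lfc_scale,
        )
        results_table = selection.results_frame(results)
        results_table.to_csv(outdir / "module_results.tsv", sep="\t", index=False,
                             float_format=io.FLOAT_FORMAT)
        manifest["stages"]["select-modules"] = {
            "modules_tested": len(results),
            "modules_selected": int(sum(r.selected for r in results)),
        }

        stage = "score"
        scores = scoring.score_genes(
            results, mods, specific, within_module_only=config.within_module_only
        )
        up, down = scoring.rank_biomarkers(scores, top_k=config.top_k)
        table = scoring.scores_frame(scores)
        table = table.sort_values(["final_score", "gene"],
                                  ascending=[False, True], kind="stable")
        table.to_csv(outdir / "biomarkers.tsv", sep="\t", index=False,
                     float_format=io.FLOAT_FORMAT)
        ranked = scoring.scores_frame(up + down)
        ranked.to_csv(outdir / "biomarkers_topk.tsv", sep="\t", index=False,
                      float_format=io.FLOAT_FORMAT)
        manifest["stages"]["score"] = {
            "genes_scored": len(scores),
            "nonzero_scores": int(sum(1 for s in scores if s.final_score != 0)),
            "top_up": len(up),
            "top_down": len(down),
        }

        if config.gene_sets:
            stage = "enrich"
            collection = io.read_gmt(config.gene_sets)
            selected_modules = [mods.by_id(r.module_id) for r in results if r.selected]
            enrichment = enrich_modules(
                selected_modules, collection, universe=set(specific.nodes)
            )
            enrichment.to_csv(outdir / "enrichment.tsv", sep="\t", index=False,
                              float_format="%.6g")
            manifest["stages"]["enrich"] = {"tests": len(enrichment)}
    except Exception as exc:
        manifest["failed_stage"] = stage
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # recorded row counts must equal the written tables' row counts
    manifest["tables"] = {
        "specific_network.tsv": specific.n_edges,
        "modules.tsv": sum(len(m.genes) for m in mods),
        "module_results.tsv": len(results),
        "biomarkers.tsv": len(scores),
        "biomarkers_topk.tsv": len(up) + len(down),
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return PipelineResult(
        outdir=outdir,
        specific_network=specific,
        modules=mods,
        module_results=results,
        biomarkers=scores,
        up=up,
        down=down,
        manifest=manifest,
    )
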