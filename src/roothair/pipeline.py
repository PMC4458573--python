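"""End-to-end orchestration: simulate -> de-filter -> scan-rhe -> coexpress
-> modules -> enrich, with a content-hash manifest for reproducibility.

Every stage reads its inputs from, and writes its outputs to, a single run
directory, so stages can be re-run individually. The manifest maps each
output file to its SHA-256 digest; two runs with the same seed must produce
byte-identical manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

from . import coexpression, diffexpr, go_enrichment, io_formats, module_mining, motif_scan
from .synthetic_data import SyntheticConfig, gen_dataset

logger = logging.getLogger(__name__)

STAGES = ("simulate", "de-filter", "scan-rhe", "coexpress", "modules", "enrich")

# inputs each stage requires when it is run without the stages producing them
_STAGE_INPUTS = {
    "simulate": (),
    "de-filter": ("diff.tsv",),
    "scan-rhe": ("genome.fa", "genes.gff3"),
    "coexpress": ("compendium.tsv", "up_in_rh.txt", "go.obo", "annotations.tsv"),
    "modules": ("network_edges.tsv",),
    "enrich": ("go.obo", "annotations.tsv", "network_edges.tsv", "up_in_rh.txt", "up_in_nrh.txt"),
}
_STAGE_OUTPUTS = {
    "simulate": ("diff.tsv", "compendium.tsv", "genome.fa", "genes.gff3", "go.obo", "annotations.tsv"),
    "de-filter": ("up_in_rh.txt", "up_in_nrh.txt", "rh_only.txt"),
    "scan-rhe": ("hits.tsv",),
    "coexpress": ("network_edges.tsv", "network_edges.tsv.nodes", "components.tsv", "sweep.tsv"),
    "modules": ("modules.tsv",),
    "enrich": ("enrichment.tsv",),
}


@dataclass
class PipelineConfig:
    out_dir: str
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    synthetic: SyntheticConfig | None = None
    de_criteria: diffexpr.DeCriteria = field(default_factory=diffexpr.DeCriteria)
    region_spec: motif_scan.RegionSpec = field(default_factory=motif_scan.RegionSpec)
    consensus: str = motif_scan.RHE_CONSENSUS
    threshold: float = 0.83
    sweep: bool = True
    sweep_grid: tuple[float, ...] = coexpression.DEFAULT_GRID
    sweep_alpha: float = 1e-3
    module_config: module_mining.ModuleConfig = field(default_factory=module_mining.ModuleConfig)
    elim_config: go_enrichment.ElimConfig = field(default_factory=go_enrichment.ElimConfig)

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if self.synthetic is None:
            self.synthetic = SyntheticConfig(seed=self.seed)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception, partial_outputs: list[str]):
        super().__init__(
            f"stage {stage!r} failed: {cause} "
            f"(partial outputs flagged: {partial_outputs or 'none'})"
        )
        self.stage = stage
        self.cause = cause
        self.partial_outputs = partial_outputs


def validate_config(config: PipelineConfig) -> None:
    """Check, before anything runs, that every required input will exist."""
    out = Path(config.out_dir)
    produced: set[str] = set()
    for stage in STAGES:
        if stage not in config.stages:
            continue
        for name in _STAGE_INPUTS[stage]:
            if name in produced:
                continue
            if not (out / name).exists():
                raise FileNotFoundError(
                    f"stage {stage!r} needs {name} which no earlier stage produces "
                    f"and {out / name} does not exist"
                )
        produced.update(_STAGE_OUTPUTS[stage])


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; return the manifest (also written).

    The manifest lists, per stage, the output files with SHA-256 content
    hashes. Stage timings and record counts go to the log only, so the
    manifest is byte-stable across equal-seed runs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    validate_config(config)
    manifest: dict = {"seed": config.seed, "stages": {}}
    consensus = motif_scan.parse_consensus(config.consensus)

    def finish(stage: str, t0: float, counts: dict) -> None:
        files = {}
        for name in _STAGE_OUTPUTS[stage]:
            p = out / name
            if p.exists():
                files[name] = _sha256(p)
        manifest["stages"][stage] = {"outputs": files}
        logger.info(
            "STAGE %s done in %.2fs %s",
            stage,
            time.perf_counter() - t0,
            " ".join(f"{k}={v}" for k, v in counts.items()),
        )

    current_stage = "setup"
    try:
        if "simulate" in config.stages:
            current_stage = "simulate"
            t0 = time.perf_counter()
            ds = gen_dataset(config.synthetic)
            io_formats.write_diff_table(ds.diff_table, out / "diff.tsv")
            io_formats.write_compendium(ds.compendium, out / "compendium.tsv")
            io_formats.write_fasta(ds.genome, out / "genome.fa")
            io_formats.write_gff3(ds.gene_models, out / "genes.gff3")
            io_formats.write_obo(ds.ontology, out / "go.obo")
            io_formats.write_annotations(ds.ontology.annotations, out / "annotations.tsv")
            finish("simulate", t0, {"genes": len(ds.diff_table)})

        if "de-filter" in config.stages:
            current_stage = "de-filter"
            t0 = time.perf_counter()
            table = io_formats.read_diff_table(out / "diff.tsv")
            parts = diffexpr.filter_de(table, config.de_criteria)
            rh_only = diffexpr.rh_only_genes(table)
            io_formats.write_gene_set(parts["up_in_rh"], out / "up_in_rh.txt")
            io_formats.write_gene_set(parts["up_in_nrh"], out / "up_in_nrh.txt")
            io_formats.write_gene_set(rh_only, out / "rh_only.txt")
            finish(
                "de-filter",
                t0,
                {
                    "up_in_rh": len(parts["up_in_rh"]),
                    "up_in_nrh": len(parts["up_in_nrh"]),
                    "rh_only": len(rh_only),
                },
            )

        if "scan-rhe" in config.stages:
            current_stage = "scan-rhe"
            t0 = time.perf_counter()
            genome = io_formats.read_fasta(out / "genome.fa")
            models = io_formats.read_gff3(out / "genes.gff3")
            hits = []
            for m in models:
                hits.extend(motif_scan.scan_gene(m, genome, consensus, config.region_spec))
            io_formats.write_hits(hits, out / "hits.tsv")
            finish("scan-rhe", t0, {"hits": len(hits), "genes": len(models)})

        if "coexpress" in config.stages:
            current_stage = "coexpress"
            t0 = time.perf_counter()
            matrix = io_formats.read_compendium(out / "compendium.tsv")
            genes = sorted(
                io_formats.read_gene_set(out / "up_in_rh.txt") & set(matrix.genes)
            )
            threshold = config.threshold
            with open(out / "sweep.tsv", "w", encoding="utf-8") as fh:
                fh.write("threshold\tn_enriched_terms\tchosen\n")
                if config.sweep:
                    dag = io_formats.load_ontology(out / "go.obo", out / "annotations.tsv")
                    sweep = coexpression.select_threshold(
                        matrix, genes, dag, config.sweep_grid, config.sweep_alpha
                    )
                    threshold = sweep.chosen
                    for t, s in zip(sweep.thresholds, sweep.scores):
                        fh.write(f"{t}\t{s}\t{int(t == sweep.chosen)}\n")
            net = coexpression.build_network(matrix, genes, threshold)
            io_formats.write_network(net, out / "network_edges.tsv")
            comps = coexpression.connected_components(net)
            with open(out / "components.tsv", "w", encoding="utf-8") as fh:
                fh.write("component\tgene\n")
                for i, comp in enumerate(comps, start=1):
                    for g in sorted(comp):
                        fh.write(f"{i}\t{g}\n")
            finish(
                "coexpress",
                t0,
                {"nodes": len(net.nodes), "edges": len(net.edges), "threshold": threshold},
            )

        if "modules" in config.stages:
            current_stage = "modules"
            t0 = time.perf_counter()
            net = io_formats.read_network(out / "network_edges.tsv")
            mods = module_mining.find_modules(net, config.module_config)
            with open(out / "modules.tsv", "w", encoding="utf-8") as fh:
                fh.write("module\tseed\tscore\tgene\n")
                for i, m in enumerate(mods, start=1):
                    for g in sorted(m.nodes):
                        fh.write(f"{i}\t{m.seed}\t{m.score:.6f}\t{g}\n")
            finish("modules", t0, {"modules": len(mods)})

        if "enrich" in config.stages:
            current_stage = "enrich"
            t0 = time.perf_counter()
            dag = io_formats.load_ontology(out / "go.obo", out / "annotations.tsv")
            net = io_formats.read_network(out / "network_edges.tsv")
            population = io_formats.read_gene_set(
                out / "up_in_rh.txt"
            ) | io_formats.read_gene_set(out / "up_in_nrh.txt")
            study = net.nodes & population
            results = go_enrichment.elim_enrichment(dag, study, population, config.elim_config)
            io_formats.write_enrichment(results, out / "enrichment.tsv")
            finish("enrich", t0, {"terms": len(results), "study": len(study)})
    except Exception as exc:  # noqa: BLE001 - stage name + cause reported
        partial = [
            n for n in _STAGE_OUTPUTS.get(current_stage, ()) if (out / n).exists()
        ]
        raise PipelineError(current_stage, exc, partial) from exc

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
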