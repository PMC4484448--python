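"""End-to-end orchestration: identify -> quantify -> enrich -> network.

The pipeline consumes a PSM table per sample plus annotation (GMT) and
interaction (edge-list) files, and emits the full set of result tables:
per-sample protein groups, the differential table with signed RSc and
partitions, categorical enrichment of the up- and down-regulated sets,
scored interaction modules, and a run log recording the package version,
seed and every numeric threshold applied. Re-running with identical
config and inputs reproduces byte-identical tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__, io as sc_io
from .enrich import EnrichmentRecord, enrich_set
from .identify import (
    IdentificationSummary,
    ProteinGroup,
    estimate_fdr,
    filter_significant_psms,
    infer_proteins,
)
from .network import ModuleResult, build_graph, extract_modules, score_modules
from .quantify import DifferentialRecord, QuantConfig, quantify_pair, summarize_partition

logger = logging.getLogger("spectracount")


@dataclass
class PipelineConfig:
    """Paths and thresholds of one pipeline run.

    ``psm_paths`` maps the two sample labels to their PSM TSVs; the first
    entry is the reference sample A, the second the test sample B.
    """

    psm_paths: dict[str, str | Path]
    gmt_path: str | Path | None = None
    edges_path: str | Path | None = None
    out_dir: str | Path = "results"
    quant: QuantConfig = field(default_factory=QuantConfig)
    min_unique_peptides: int = 2
    fdr_mode: str = "decoy_over_target"
    alpha: float = 0.05
    module_min_size: int = 3
    module_split_threshold: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.psm_paths) != 2:
            raise ValueError("psm_paths must map exactly two sample labels")


@dataclass
class PipelineResult:
    groups: dict[str, list[ProteinGroup]]
    identification: IdentificationSummary
    records: list[DifferentialRecord]
    partition_summary: dict[str, int]
    enrichment: dict[str, list[EnrichmentRecord]]
    modules: list[ModuleResult]
    outputs: dict[str, Path]


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    samples = list(config.psm_paths)
    sample_a, sample_b = samples

    # --- identification, per sample -------------------------------------
    groups: dict[str, list[ProteinGroup]] = {}
    for sample, path in config.psm_paths.items():
        try:
            psms = sc_io.read_psm_table(path)
            significant = filter_significant_psms(psms)
            groups[sample] = infer_proteins(
                significant, min_unique_peptides=config.min_unique_peptides
            )
        except Exception as err:
            raise RuntimeError(f"identification ({sample}): {err}") from err
        out = out_dir / f"protein_groups_{_safe(sample)}.tsv"
        sc_io.write_protein_groups(groups[sample], out, samples=[sample])
        outputs[f"groups:{sample}"] = out
        logger.info("%s: %d protein groups", sample, len(groups[sample]))

    union: dict[str, ProteinGroup] = {}
    for sample in samples:
        for g in groups[sample]:
            union.setdefault(g.protein, g)
    try:
        identification = estimate_fdr(list(union.values()), mode=config.fdr_mode)
    except Exception as err:
        raise RuntimeError(f"identification (FDR): {err}") from err

    # --- quantitation ----------------------------------------------------
    try:
        records = quantify_pair(groups[sample_a], groups[sample_b], config.quant)
        summary = summarize_partition(records)
    except Exception as err:
        raise RuntimeError(f"quantitation: {err}") from err
    diff_path = out_dir / "differential.tsv"
    sc_io.write_differential_table(records, diff_path)
    outputs["differential"] = diff_path

    background = {r.protein for r in records}
    up = {r.protein for r in records if r.partition in ("unique_B", "common_higher_B")}
    down = {r.protein for r in records if r.partition in ("unique_A", "common_lower_B")}

    # --- enrichment ------------------------------------------------------
    enrichment: dict[str, list[EnrichmentRecord]] = {}
    if config.gmt_path is not None:
        try:
            annotations = sc_io.read_gmt(config.gmt_path)
            for name, query in (("up_in_B", up), ("down_in_B", down)):
                if not query:
                    logger.info("enrichment: %s query empty, skipped", name)
                    continue
                enrichment[name] = enrich_set(
                    query, background, annotations, alpha=config.alpha
                )
                out = out_dir / f"enrichment_{name}.tsv"
                sc_io.write_enrichment_table(enrichment[name], out)
                outputs[f"enrichment:{name}"] = out
        except Exception as err:
            raise RuntimeError(f"enrichment: {err}") from err

    # --- network modules -------------------------------------------------
    modules: list[ModuleResult] = []
    if config.edges_path is not None:
        try:
            edges = sc_io.read_edge_list(config.edges_path)
            graph = build_graph(edges, restrict_to=background)
            modules = extract_modules(
                graph,
                min_size=config.module_min_size,
                split_threshold=config.module_split_threshold,
            )
            if up:
                modules = score_modules(modules, up, background)
        except Exception as err:
            raise RuntimeError(f"network: {err}") from err
        mod_path = out_dir / "modules.tsv"
        _write_modules(modules, mod_path)
        outputs["modules"] = mod_path
        if any(m.enrichment for m in modules):
            score_path = out_dir / "module_enrichment.tsv"
            sc_io.write_enrichment_table(
                [m.enrichment for m in modules if m.enrichment], score_path
            )
            outputs["module_enrichment"] = score_path

    # --- summaries and run log -------------------------------------------
    summary_path = out_dir / "partition_summary.json"
    sc_io.write_json_summary(
        {
            **summary,
            "fdr": identification.fdr,
            "n_target_proteins": identification.n_target_proteins,
            "n_decoy_proteins": identification.n_decoy_proteins,
        },
        summary_path,
    )
    outputs["summary"] = summary_path

    log_path = out_dir / "run_log.json"
    sc_io.write_json_summary(
        {
            "package": "spectracount",
            "version": __version__,
            "seed": config.seed,
            "samples": {"reference_A": sample_a, "test_B": sample_b},
            "thresholds": {
                "c": config.quant.c,
                "fold_cutoff": config.quant.fold_cutoff,
                "high_tier_cutoff": config.quant.high_tier_cutoff,
                "alpha": config.alpha,
                "min_unique_peptides": config.min_unique_peptides,
                "module_min_size": config.module_min_size,
                "module_split_threshold": config.module_split_threshold,
            },
            "fdr_mode": config.fdr_mode,
        },
        log_path,
    )
    outputs["run_log"] = log_path

    return PipelineResult(
        groups=groups,
        identification=identification,
        records=records,
        partition_summary=summary,
        enrichment=enrichment,
        modules=modules,
        outputs=outputs,
    )


def _write_modules(modules: list[ModuleResult], path: Path) -> None:
    rows = [
        {"module_id": m.module_id, "member": member, "density": f"{m.density:.4f}"}
        for m in modules
        for member in sorted(m.members)
    ]
    pd.DataFrame(rows, columns=["module_id", "member", "density"]).to_csv(
        path, sep="\t", index=False
    )


def _safe(name: str) -> str:
    return name.replace("/", "_").replace(" ", "_")
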