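"""End-to-end orchestration: simulate/load -> distill -> qc -> network ->
cluster -> enrich, with a machine-readable summary.

The pipeline either consumes real tables (runs, controls or SAINT-style
scored interactions, contaminant profile) or generates a synthetic
experiment first. All randomness flows from the single top-level seed.
"""
from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd

from . import __version__, clustering, enrichment, filtering, io, network, qc
from .simulate import SimConfig, generate_experiment, evaluate_recovery
from .types import APMS, BIOID, FilterThresholds, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Run-level configuration; file paths may be None when unused."""

    outdir: str = "baitnet_out"
    # input mode A: synthetic experiment
    simulate: SimConfig | None = None
    # input mode B: real tables
    runs_path: str | None = None
    controls_path: str | None = None
    saint_bioid_path: str | None = None
    saint_apms_path: str | None = None
    crapome_path: str | None = None
    # optional annotation inputs
    reference_paths: dict[str, str] = field(default_factory=dict)
    localization_path: str | None = None
    complexes_path: str | None = None
    gmt_path: str | None = None
    # analysis parameters
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    cluster_metric: str = "pearson"
    cluster_linkage: str = "average"
    n_clusters: int = 0  # 0 = skip flat cut
    enrichment_background: str = "all_interactome"  # or "custom_file"
    enrichment_background_path: str | None = None
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        d = dict(d)
        if "simulate" in d and isinstance(d["simulate"], dict):
            sim = dict(d["simulate"])
            for key in ("methods", "contaminant_freq_range"):
                if key in sim and isinstance(sim[key], list):
                    sim[key] = tuple(sim[key])
            if "planted_modules" in sim:
                sim["planted_modules"] = tuple(
                    tuple(m) for m in sim["planted_modules"])
            d["simulate"] = SimConfig(**sim)
        if "thresholds" in d and isinstance(d["thresholds"], dict):
            d["thresholds"] = FilterThresholds(**d["thresholds"])
        return cls(**d)


def _load_inputs(config: PipelineConfig, outdir: Path):
    """Returns (runs, controls, crapome, scored_by_method, truth)."""
    truth = None
    if config.simulate is not None:
        from dataclasses import replace
        sim_cfg = replace(config.simulate, seed=config.seed)
        data = generate_experiment(sim_cfg)
        inputs = outdir / "inputs"
        inputs.mkdir(parents=True, exist_ok=True)
        io.write_runs(data.runs, inputs / "runs.tsv")
        io.write_controls(data.controls, inputs / "controls.tsv")
        io.write_crapome(data.crapome.values(), inputs / "crapome.tsv")
        return data.runs, data.controls, data.crapome, None, data.truth
    if config.crapome_path is None:
        raise ValidationError("crapome_path is required when not simulating")
    crapome = io.read_crapome(config.crapome_path)
    runs = io.read_runs(config.runs_path) if config.runs_path else []
    controls = (io.read_controls(config.controls_path)
                if config.controls_path else [])
    scored = None
    if config.saint_bioid_path or config.saint_apms_path:
        scored = []
        if config.saint_bioid_path:
            scored += io.read_saint_output(config.saint_bioid_path, BIOID)
        if config.saint_apms_path:
            scored += io.read_saint_output(config.saint_apms_path, APMS)
    elif not (runs and controls):
        raise ValidationError(
            "need either SAINT-style scored tables or runs plus controls")
    return runs, controls, crapome, scored, truth


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute every stage and write reports plus summary.json to outdir."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict[str, Any] = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": asdict(config.thresholds),
    }

    runs, controls, crapome, scored, truth = _load_inputs(config, outdir)
    if scored is None:
        scored = filtering.score_interactions(runs, controls)

    # stage: distill per method
    tables = {}
    for method, fname in ((BIOID, "bioid"), (APMS, "apms")):
        subset = [si for si in scored if si.method == method]
        table, decisions = filtering.distill_interactome(
            subset, crapome, config.thresholds)
        tables[method] = table
        io.write_interaction_table(table, outdir / f"interactions_{fname}.tsv")
        filtering.decisions_frame(decisions).to_csv(
            outdir / f"decisions_{fname}.tsv", sep="\t", index=False)
    summary["n_interactions"] = {m: int(len(t)) for m, t in tables.items()}

    # stage: qc (only when replicate-level runs are available)
    if runs:
        report = qc.report_frame(qc.replicate_report(runs))
        report.to_csv(outdir / "qc.tsv", sep="\t", index=False)
        summary["qc_median_r"] = (float(report["r"].median())
                                  if len(report) else None)

    # stage: network
    net = network.build_network(tables[BIOID], tables[APMS])
    overlap = network.method_overlap_counts(tables[BIOID], tables[APMS])
    summary["overlap"] = {"bioid_only": overlap[0], "apms_only": overlap[1],
                          "both": overlap[2]}
    if config.reference_paths:
        refs = {name: io.read_edge_list(path)
                for name, path in config.reference_paths.items()}
        summary["known_fraction"] = network.annotate_known(net, refs)
    degrees = network.prey_degree(net)
    pd.Series(degrees, name="n_baits").rename_axis("prey").sort_values(
        ascending=False).to_csv(outdir / "prey_degree.tsv", sep="\t")
    if degrees:
        top = max(sorted(degrees), key=degrees.get)
        summary["top_prey"] = {"prey": top, "n_baits": degrees[top]}
    if config.localization_path:
        loc = io.read_localization(config.localization_path)
        loc_summary = network.localization_fraction(net, loc)
        summary["nuclear_fraction"] = loc_summary.nuclear_fraction
    bait_ids = sorted({r.bait_id for r in runs} | net.baits())
    bb = network.bait_bait_edges(net, bait_ids)
    pd.DataFrame(bb, columns=["bait", "prey_bait", "provenance"]).to_csv(
        outdir / "bait_bait.tsv", sep="\t", index=False)
    summary["n_bait_bait_edges"] = len(bb)
    summary["n_bidirectional_pairs"] = len(network.bidirectional_pairs(bb))
    contacts, per_nfi = network.nfi_partition(bb, bait_ids)
    summary["nfi_partition"] = {
        "per_nfi": per_nfi,
        "n_touching_any": sum(1 for c in contacts if c.direction != "none"),
    }
    if config.complexes_path:
        complexes = io.read_complexes(config.complexes_path)
        coverage, denom = network.complex_coverage(net, complexes)
        coverage.to_csv(outdir / "complex_coverage.tsv", sep="\t")
        summary["complex_denominators"] = denom

    # stage: prey-prey correlation clustering on the BioID table
    bioid = tables[BIOID]
    if config.n_clusters > 0 and len(bioid) > 0:
        matrix = clustering.build_bait_prey_matrix(bioid)
        if len(matrix.baits) >= 2 and len(matrix.preys) >= 2:
            tree = clustering.hierarchical_cluster(
                matrix, axis="prey", metric=config.cluster_metric,
                linkage=config.cluster_linkage)
            clusters = clustering.extract_clusters(
                tree, k=min(config.n_clusters, len(matrix.preys)))
            clustering.cluster_report(clusters, bioid).to_csv(
                outdir / "clusters.tsv", sep="\t", index=False)
            summary["cluster_sizes"] = {c.cluster_id: len(c.members)
                                        for c in clusters}

    # stage: enrichment of per-bait interactomes against the full prey set
    if config.gmt_path:
        sets = io.read_gmt(config.gmt_path)
        if config.enrichment_background == "custom_file":
            if not config.enrichment_background_path:
                raise ValidationError(
                    "custom_file background needs enrichment_background_path")
            background = {g for pair in
                          io.read_edge_list(config.enrichment_background_path)
                          for g in pair}
        else:
            background = net.preys()
        rows = []
        for bait in sorted(net.baits()):
            query = set(net.graph.successors(bait)) & background
            if not query:
                continue
            for rec in enrichment.enrich(query, background, sets):
                rows.append((bait, rec.term_id, rec.term_name, rec.k, rec.n,
                             rec.K, rec.N, rec.p_value, rec.fdr))
        pd.DataFrame(rows, columns=["bait", "term_id", "term_name", "k", "n",
                                    "K", "N", "p_value", "fdr"]).to_csv(
            outdir / "enrichment.tsv", sep="\t", index=False)
        summary["n_enrichment_tests"] = len(rows)

    if truth is not None:
        precision, recall = evaluate_recovery(tables[BIOID], truth)
        summary["recovery_bioid"] = {"precision": precision, "recall": recall}

    with open(outdir / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    logger.info("pipeline complete; summary written to %s",
                outdir / "summary.json")
    return summary
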