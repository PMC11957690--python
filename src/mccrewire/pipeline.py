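"""Orchestration of the two analysis arms on synthetic fixtures.

The cohort arm runs marker scoring -> signature -> reversal screen; the
time-course arm runs differential expression -> coexpression modules and
message-passing networks -> period averaging -> differential communities ->
enrichment.  Every stage writes TSV/GMT/JSON artifacts into the work
directory and records them, with content digests, in a run manifest;
re-running with the same config and seed reproduces identical digests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import coexpr, enrichstats, io, regnet, reversal, signature, synthetic
from .config import PipelineConfig, validate_config
from .data import ExpressionMatrix

log = logging.getLogger(__name__)

_STAGE_ORDER = ("simulate", "signature", "reversal", "coexpr", "regnet", "enrich")


@dataclass
class StageRecord:
    inputs: list[str] = field(default_factory=list)
    outputs: list[str] = field(default_factory=list)
    digests: dict[str, str] = field(default_factory=dict)
    seed: int = 0
    duration: float = 0.0
    warnings: list[str] = field(default_factory=list)
    info: dict = field(default_factory=dict)


@dataclass
class RunManifest:
    stages: dict[str, StageRecord] = field(default_factory=dict)
    planned: list[str] = field(default_factory=list)
    completed: bool = False

    def to_json(self) -> str:
        payload = {"planned": self.planned, "completed": self.completed,
                   "stages": {k: dataclasses.asdict(v)
                              for k, v in self.stages.items()}}
        return json.dumps(payload, indent=1, sort_keys=True)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _record_outputs(record: StageRecord, workdir: Path, names: list[str]) -> None:
    for name in names:
        path = workdir / name
        record.outputs.append(name)
        record.digests[name] = _digest(path)


def _timecourse_config(config: PipelineConfig) -> synthetic.TimecourseConfig:
    return synthetic.TimecourseConfig(periods=dict(config.periods))


def run_pipeline(config, workdir, dry_run: bool = False) -> RunManifest:
    """Execute the enabled stages in dependency order.

    A stage failure aborts its downstream dependents; the manifest records
    the partial state.  With ``dry_run`` the manifest only lists the planned
    stages and nothing is written.
    """
    config = validate_config(config)
    workdir = Path(workdir)
    enabled = [s for s in _STAGE_ORDER if s in config.stages]
    manifest = RunManifest(planned=enabled)
    if dry_run:
        return manifest

    workdir.mkdir(parents=True, exist_ok=True)
    aborted = False
    for stage in enabled:
        record = StageRecord(seed=config.seed)
        if aborted:
            record.warnings.append("skipped: upstream stage failed")
            manifest.stages[stage] = record
            continue
        start = time.perf_counter()
        try:
            _STAGE_FNS[stage](config, workdir, record)
        except Exception as exc:  # noqa: BLE001 - recorded, then surfaced
            record.warnings.append(f"failed: {exc}")
            manifest.stages[stage] = record
            log.error("stage %s failed: %s", stage, exc)
            aborted = True
            continue
        record.duration = time.perf_counter() - start
        manifest.stages[stage] = record
        log.info("stage %s done in %.2fs (%d outputs)", stage, record.duration,
                 len(record.outputs))
    manifest.completed = not aborted
    (workdir / "manifest.json").write_text(manifest.to_json())
    return manifest


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(config: PipelineConfig, workdir: Path,
                    record: StageRecord) -> None:
    cohort_cfg = synthetic.CohortConfig(n_genes=config.cohort_n_genes,
                                        signature_size=config.n_per_tail)
    cohort, cohort_truth = synthetic.gen_cohort(cohort_cfg, seed=config.seed)
    io.write_expression(cohort, workdir / "cohort_expression.tsv",
                        workdir / "cohort_meta.tsv")
    io.write_truth(cohort_truth, workdir / "cohort_truth.json")

    tc, tc_truth = synthetic.gen_timecourse(_timecourse_config(config),
                                            seed=config.seed)
    io.write_expression(tc, workdir / "timecourse_expression.tsv",
                        workdir / "timecourse_meta.tsv")
    io.write_truth(tc_truth, workdir / "timecourse_truth.json")

    prior_cfg = synthetic.PriorConfig(
        n_tfs=config.regnet_n_tfs, n_genes=config.regnet_n_genes,
        gene_names=tuple(tc.genes[:config.regnet_n_genes]))
    motif, ppi = synthetic.gen_network_priors(prior_cfg, seed=config.seed)
    io.write_edge_list(motif, workdir / "motif_prior.tsv")
    io.write_dense_matrix(ppi, workdir / "ppi.tsv", index_label="tf")

    canonical = [g for g, b in tc_truth.planted_module_labels.items() if b == 1]
    ann_cfg = synthetic.AnnotationConfig(query_set=tuple(canonical),
                                         size_range=(10, min(100, tc.n_genes)))
    annotation, ann_truth = synthetic.gen_annotation(tc.genes, ann_cfg,
                                                     seed=config.seed)
    io.write_gmt(annotation, workdir / "annotation.gmt")
    io.write_truth(ann_truth, workdir / "annotation_truth.json")
    _record_outputs(record, workdir, [
        "cohort_expression.tsv", "cohort_meta.tsv", "cohort_truth.json",
        "timecourse_expression.tsv", "timecourse_meta.tsv",
        "timecourse_truth.json", "motif_prior.tsv", "ppi.tsv",
        "annotation.gmt", "annotation_truth.json"])


def _stage_signature(config: PipelineConfig, workdir: Path,
                     record: StageRecord) -> None:
    record.inputs += ["cohort_expression.tsv", "cohort_meta.tsv"]
    cohort = io.read_expression(workdir / "cohort_expression.tsv",
                                workdir / "cohort_meta.tsv")
    panel = signature.MarkerPanel(synthetic.DEFAULT_MARKERS)
    scores = signature.marker_correlation_scores(cohort, panel)
    sig = signature.build_signature(scores, n_per_tail=config.n_per_tail)
    io.write_signature(sig, workdir / "signature.gmt",
                       workdir / "signature_scores.tsv")
    record.info["n_per_tail"] = sig.n_per_tail
    _record_outputs(record, workdir, ["signature.gmt", "signature_scores.tsv"])


def _stage_reversal(config: PipelineConfig, workdir: Path,
                    record: StageRecord) -> None:
    record.inputs += ["signature.gmt", "signature_scores.tsv"]
    sig = io.read_signature(workdir / "signature.gmt",
                            workdir / "signature_scores.tsv")
    pert_cfg = synthetic.PerturbationConfig(
        reversal_fraction=config.reversal_fraction)
    profiles, truth = synthetic.gen_perturbations(sig, pert_cfg,
                                                  seed=config.seed)
    io.write_profiles(profiles, workdir / "perturbation_profiles.tsv")
    io.write_truth(truth, workdir / "perturbation_truth.json")
    results = reversal.reversal_screen(sig, profiles, k=config.top_k)
    table = reversal.results_table(results)
    table.to_csv(workdir / "reversal_screen.tsv", sep="\t",
                 float_format=io.FLOAT_FMT)
    record.info["planted_reverser"] = truth.planted_reverser
    record.info["planted_reverser_rank"] = int(
        table.loc[truth.planted_reverser, "rank"])
    _record_outputs(record, workdir, ["perturbation_profiles.tsv",
                                      "perturbation_truth.json",
                                      "reversal_screen.tsv"])


def _stage_coexpr(config: PipelineConfig, workdir: Path,
                  record: StageRecord) -> None:
    record.inputs += ["timecourse_expression.tsv", "timecourse_meta.tsv"]
    tc = io.read_expression(workdir / "timecourse_expression.tsv",
                            workdir / "timecourse_meta.tsv")
    er = tc.for_condition("ER")
    network = coexpr.build_network(er, power=config.power)
    partition = coexpr.detect_modules(network, min_size=config.min_module_size,
                                      merge_height=config.merge_height)
    hubs, edges = coexpr.hub_and_leading_edges(network, partition,
                                               n_hubs=config.n_hubs,
                                               edge_quantile=config.edge_quantile)
    partition.hub_lists = hubs
    io.write_partition(partition.labels, workdir / "modules.tsv")
    io.write_dense_matrix(partition.eigengenes, workdir / "eigengenes.tsv",
                          index_label="sample")
    io.write_gmt({f"MODULE_{m}_HUBS": genes for m, genes in hubs.items()},
                 workdir / "hubs.gmt")
    edges.to_csv(workdir / "leading_edges.tsv", sep="\t", index=False,
                 float_format=io.FLOAT_FMT)
    trait = er.meta["time_hours"].to_numpy(dtype=float)
    mt = coexpr.module_trait_correlation(partition, trait)
    mt.to_csv(workdir / "module_trait.tsv", sep="\t", float_format=io.FLOAT_FMT)
    record.info["n_modules"] = len(partition.module_ids())
    _record_outputs(record, workdir, ["modules.tsv", "eigengenes.tsv",
                                      "hubs.gmt", "leading_edges.tsv",
                                      "module_trait.tsv"])


def _stage_regnet(config: PipelineConfig, workdir: Path,
                  record: StageRecord) -> None:
    record.inputs += ["timecourse_expression.tsv", "timecourse_meta.tsv",
                      "motif_prior.tsv", "ppi.tsv"]
    tc = io.read_expression(workdir / "timecourse_expression.tsv",
                            workdir / "timecourse_meta.tsv")
    motif = io.read_edge_list(workdir / "motif_prior.tsv")
    motif = motif.loc[sorted(motif.index), [g for g in tc.genes
                                            if g in motif.columns]]
    ppi = io.read_dense_matrix(workdir / "ppi.tsv", index_label="tf")
    ppi = ppi.loc[motif.index, motif.index]

    period_map = regnet.PeriodMap(dict(config.periods))
    averaged: dict[tuple[str, int], regnet.BipartiteNetwork] = {}
    for condition in sorted(tc.meta["condition"].unique()):
        sub = tc.for_condition(condition)
        nets = regnet.single_sample_networks(sub, motif, ppi,
                                             alpha=config.alpha)
        averaged.update(regnet.transform_and_average(nets, period_map))
    outputs = []
    for (condition, period), net in averaged.items():
        name = f"network_{condition}_t{period}.tsv"
        io.write_network(net, workdir / name,
                         workdir / f"network_{condition}_t{period}.json")
        outputs += [name, f"network_{condition}_t{period}.json"]

    summary = []
    for period in period_map.periods():
        base = averaged.get(("CTRL", period))
        pert = averaged.get(("ER", period))
        if base is None or pert is None:
            continue
        result = regnet.differential_communities(
            base, pert, min_size=config.community_min_size)
        name = f"communities_t{period}.tsv"
        io.write_communities(result, workdir / name)
        outputs.append(name)
        summary.append({"period": period, "n_retained": len(result.retained),
                        "modularity": result.modularity})
    pd.DataFrame(summary).to_csv(workdir / "community_summary.tsv", sep="\t",
                                 index=False, float_format=io.FLOAT_FMT)
    outputs.append("community_summary.tsv")
    _record_outputs(record, workdir, outputs)


def _stage_enrich(config: PipelineConfig, workdir: Path,
                  record: StageRecord) -> None:
    record.inputs += ["timecourse_expression.tsv", "timecourse_meta.tsv",
                      "annotation.gmt", "timecourse_truth.json"]
    tc = io.read_expression(workdir / "timecourse_expression.tsv",
                            workdir / "timecourse_meta.tsv")
    truth = io.read_truth(workdir / "timecourse_truth.json")
    annotation = io.read_gmt(workdir / "annotation.gmt")

    last_t = int(tc.meta["time_hours"].max())
    de_table, hits = enrichstats.de_test(
        tc, tc.samples_at("ER", last_t), tc.samples_at("CTRL", last_t),
        padj_thresh=config.padj_threshold, lfc_thresh=config.lfc_threshold)
    de_table.to_csv(workdir / "de_table.tsv", sep="\t",
                    float_format=io.FLOAT_FMT, index_label="gene")
    if hits:
        enrich = enrichstats.set_enrichment(hits, tc.genes, annotation)
    else:
        record.warnings.append("no differentially expressed genes at the "
                               "final time point")
        enrich = enrichstats.set_enrichment(tc.genes[:1], tc.genes, annotation)
    enrich.to_csv(workdir / "enrichment.tsv", sep="\t",
                  float_format=io.FLOAT_FMT)

    blocks: dict[int, list[str]] = {}
    for gene, label in truth.planted_module_labels.items():
        blocks.setdefault(label, []).append(gene)
    dyn_rows = []
    if 1 in blocks and 3 in blocks:
        groups = enrichstats.period_groups(
            tc, regnet.PeriodMap(dict(config.periods)))
        dynamics = enrichstats.interset_correlation(tc, blocks[1], blocks[3],
                                                    groups)
        dyn_rows = [{"condition": cond, "period": period,
                     "mean_abs_r": stats["mean_abs_r"]}
                    for (cond, period), stats in dynamics.items()]
    pd.DataFrame(dyn_rows).to_csv(workdir / "interset_dynamics.tsv", sep="\t",
                                  index=False, float_format=io.FLOAT_FMT)

    rel = enrichstats.relative_log2fc(tc.for_condition("ER"),
                                      tc.for_condition("CTRL"))
    rel.to_csv(workdir / "relative_log2fc.tsv", sep="\t",
               float_format=io.FLOAT_FMT, index_label="gene")
    _record_outputs(record, workdir, ["de_table.tsv", "enrichment.tsv",
                                      "interset_dynamics.tsv",
                                      "relative_log2fc.tsv"])


_STAGE_FNS = {"simulate": _stage_simulate, "signature": _stage_signature,
              "reversal": _stage_reversal, "coexpr": _stage_coexpr,
              "regnet": _stage_regnet, "enrich": _stage_enrich}
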