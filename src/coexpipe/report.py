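"""End-to-end pipeline orchestration and run ledgers.

Two execution paths share every stage implementation:

* ``run_complete`` — dedup → QC → normalization → IQR filtering →
  (optional) network construction on the full array set;
* ``run_partitioned`` — the same pre-processing, then keyword
  classification of submissions, an *independent* normalization +
  filtering run per category sub-matrix, per-category networks and their
  unions (per basis and overall).

Every run produces a RunLedger whose arithmetic identities (arrays
remaining = collected − duplicates − QC failures; union gain = union
vertices − complete vertices) mirror the audit tables of a compendium
study.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import annotate, classify, dedup_qc, filtersel, netinfer, normalize
from .core import (
    AnnotationMap,
    ExpressionMatrix,
    GeneNetwork,
    Space,
    SubmissionRecord,
)


@dataclass
class PipelineConfig:
    """Thresholds and stage parameters for one pipeline run."""

    scale_multiplier: float = 3.0
    rle_nuse_iqr_max: float = 0.75
    center_deviation_max: float = 0.075
    normalization_target: float = 1000.0
    filter_method: str = "histogram"  # histogram | derivative | fixed
    fixed_q: float | None = None
    histogram_bin_width: float = 0.025
    profile_grid_step: float = 0.01
    min_arrays_per_class: int = 8
    methods: tuple[str, ...] = ("pcc", "mi")
    pcc: netinfer.PCCConfig | None = None
    mi: netinfer.MIEstimatorConfig | None = None
    keyword_config: classify.KeywordConfig | None = None
    exclusion_list: tuple[str, ...] = ()  # arrays rejected by manual screening
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("scale_multiplier", "rle_nuse_iqr_max",
                     "center_deviation_max", "normalization_target"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if "pcc" in self.methods and self.pcc is None:
            self.pcc = netinfer.PCCConfig(seed=self.seed)
        if "mi" in self.methods and self.mi is None:
            self.mi = netinfer.MIEstimatorConfig(seed=self.seed + 1)


@dataclass
class DatasetCounts:
    n_arrays: int = 0
    genes_in_input: int = 0
    q: float = float("nan")
    genes_retained: int = 0
    networks: dict[str, dict[str, int]] = field(default_factory=dict)


@dataclass
class RunLedger:
    arrays_collected: int = 0
    duplicates_removed: int = 0
    qc_failed: int = 0
    arrays_remaining: int = 0
    datasets: dict[str, DatasetCounts] = field(default_factory=dict)
    retained_genes: dict[str, list[str]] = field(default_factory=dict)
    unions: dict[str, dict[str, int]] = field(default_factory=dict)
    flagged_submissions: list[tuple[str, str, float]] = field(default_factory=list)

    def check_arithmetic(self) -> None:
        assert self.arrays_remaining == (
            self.arrays_collected - self.duplicates_removed - self.qc_failed
        ), "ledger arithmetic violated"

    def to_dict(self) -> dict:
        return {
            "arrays_collected": self.arrays_collected,
            "duplicates_removed": self.duplicates_removed,
            "qc_failed": self.qc_failed,
            "arrays_remaining": self.arrays_remaining,
            "datasets": {
                k: {
                    "n_arrays": d.n_arrays,
                    "genes_in_input": d.genes_in_input,
                    "q": d.q,
                    "genes_retained": d.genes_retained,
                    "networks": d.networks,
                }
                for k, d in self.datasets.items()
            },
            "unions": self.unions,
        }


class StageError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {err}")
        self.stage = stage


def _preprocess(
    mat: ExpressionMatrix,
    submissions: list[SubmissionRecord],
    annotation: AnnotationMap,
    cfg: PipelineConfig,
) -> tuple[ExpressionMatrix, list[SubmissionRecord], RunLedger, dedup_qc.QCReport]:
    """Dedup + QC + summarization + annotation collapse, shared by both paths.

    Returns the gene-level raw matrix restricted to passing arrays.
    """
    ledger = RunLedger(arrays_collected=len(mat.col_ids))
    report = dedup_qc.QCReport()

    # exact duplicates
    dup_pairs = dedup_qc.find_exact_duplicates(submissions)
    dedup_qc.mark_duplicates(report, dup_pairs)
    _, flagged = dedup_qc.match_descriptions(submissions)
    ledger.flagged_submissions = flagged
    ledger.duplicates_removed = len(report.failed())

    # manual-screening exclusion list stands in for visual inspection
    for a in cfg.exclusion_list:
        if report.record(a).verdict == "pass":
            report.record(a).verdict = "excluded"

    # summarize to probe-set level for scale factors
    try:
        ps_mat = normalize.summarize_probesets(mat)
    except Exception as e:  # matrix may already be probe-set level
        raise StageError("summarize", e)

    factors = dedup_qc.compute_scale_factors(ps_mat, cfg.normalization_target)
    spikes = dedup_qc.detect_spikeins(ps_mat)
    dedup_qc.filter_scale_and_spikein(
        submissions, factors, spikes, report, cfg.scale_multiplier
    )

    # probe-level model within submissions on log2 probe data
    log_mat = mat.with_values(
        np.log2(np.maximum(mat.values, 1e-6)), Space.LOG2
    )
    rle, nuse, _ = dedup_qc.fit_probe_level_model(log_mat, submissions)
    dedup_qc.qc_outliers(
        rle, nuse, mat.col_ids, report,
        iqr_max=cfg.rle_nuse_iqr_max, center_max=cfg.center_deviation_max,
    )

    failed = set(report.failed())
    ledger.qc_failed = len(failed) - ledger.duplicates_removed
    keep_arrays = [a for a in mat.col_ids if a not in failed]
    ledger.arrays_remaining = len(keep_arrays)
    ledger.check_arithmetic()

    ps_kept = ps_mat.subset_cols(keep_arrays)
    # annotation cleanup and probe-set collapse to genes
    cleaned, _ = annotate.clean_annotation(annotation)
    clusters = annotate.cluster_and_select(cleaned)
    clusters = [c for c in clusters if c.representative in ps_kept.row_ids]
    gene_mat = annotate.collapse_matrix(ps_kept, clusters, cleaned)

    kept_submissions = []
    for s in submissions:
        arrays = [a for a in s.array_ids if a not in failed]
        if arrays:
            kept_submissions.append(
                SubmissionRecord(s.submission_id, s.source, s.description,
                                 arrays, {a: s.content_hashes.get(a, "") for a in arrays})
            )
    return gene_mat, kept_submissions, ledger, report


def _filter_dataset(
    raw_gene_mat: ExpressionMatrix, cfg: PipelineConfig, name: str,
    ledger: RunLedger,
) -> ExpressionMatrix:
    """Independent normalization + IQR filtering of one dataset."""
    norm, _ = normalize.normalize_pipeline(
        raw_gene_mat, target=cfg.normalization_target, summarize=False
    )
    iqrs = filtersel.gene_iqr(norm)
    q = filtersel.select_threshold(
        norm, cfg.filter_method, cfg.fixed_q,
        cfg.histogram_bin_width, cfg.profile_grid_step, iqrs,
    )
    filtered, rep = filtersel.apply_filter(norm, q, cfg.filter_method, iqrs)
    ledger.datasets[name] = DatasetCounts(
        n_arrays=len(norm.col_ids),
        genes_in_input=len(norm.row_ids),
        q=q,
        genes_retained=rep.n_retained,
    )
    ledger.retained_genes[name] = list(rep.retained)
    return filtered


def _build_networks(
    filtered: ExpressionMatrix, cfg: PipelineConfig, name: str,
    ledger: RunLedger,
) -> dict[str, GeneNetwork]:
    nets: dict[str, GeneNetwork] = {}
    if filtered.shape[0] < 2:
        return nets
    for method in cfg.methods:
        if method == "pcc":
            net = netinfer.pcc_network(filtered, cfg.pcc, provenance=name)
        elif method == "mi":
            net = netinfer.mi_network(filtered, cfg.mi, provenance=name)
        else:
            raise ValueError(f"unknown network method {method!r}")
        nets[method] = net
        ledger.datasets[name].networks[method] = netinfer.network_stats(net)
    return nets


def run_complete(
    mat: ExpressionMatrix,
    submissions: list[SubmissionRecord],
    annotation: AnnotationMap,
    cfg: PipelineConfig,
) -> tuple[RunLedger, dict[str, GeneNetwork]]:
    """Full pipeline on the aggregate (complete) dataset."""
    gene_mat, _, ledger, _ = _preprocess(mat, submissions, annotation, cfg)
    filtered = _filter_dataset(gene_mat, cfg, "complete", ledger)
    nets = _build_networks(filtered, cfg, "complete", ledger)
    return ledger, nets


def run_partitioned(
    mat: ExpressionMatrix,
    submissions: list[SubmissionRecord],
    annotation: AnnotationMap,
    cfg: PipelineConfig,
    overrides: list[classify.Override] | None = None,
) -> tuple[RunLedger, dict[str, dict[str, GeneNetwork]]]:
    """Per-category pipelines plus union networks.

    Each category sub-matrix is re-normalized and re-filtered from the
    post-QC raw gene matrix (independent pre-processing), so a gene's
    survival is judged against its own category's dynamic range.
    """
    gene_mat, kept_subs, ledger, _ = _preprocess(mat, submissions, annotation, cfg)

    # complete path for comparison
    filtered_complete = _filter_dataset(gene_mat, cfg, "complete", ledger)
    nets_complete = _build_networks(filtered_complete, cfg, "complete", ledger)

    assignments, _ = classify.keyword_assign(kept_subs, cfg.keyword_config)
    if overrides:
        assignments, _ = classify.apply_overrides(
            assignments, overrides, [s.submission_id for s in kept_subs]
        )
    class_basis = {a.class_name: a.basis.value for a in assignments}
    partitions = classify.partition_matrices(gene_mat, assignments, kept_subs)

    nets_by_class: dict[str, dict[str, GeneNetwork]] = {"complete": nets_complete}
    for cls, sub_mat in sorted(partitions.items()):
        if len(sub_mat.col_ids) < cfg.min_arrays_per_class:
            warnings.warn(
                f"class {cls!r} has {len(sub_mat.col_ids)} arrays "
                f"(< {cfg.min_arrays_per_class}); skipped"
            )
            continue
        filtered = _filter_dataset(sub_mat, cfg, cls, ledger)
        nets_by_class[cls] = _build_networks(filtered, cfg, cls, ledger)

    # unions per method: tissue, process, full
    for method in cfg.methods:
        members = {
            cls: nets[method]
            for cls, nets in nets_by_class.items()
            if cls != "complete" and method in nets
        }
        if not members:
            continue
        for basis in ("tissue", "process"):
            group = [n for c, n in members.items() if class_basis.get(c) == basis]
            if group:
                u = netinfer.union_networks(group)
                ledger.unions[f"{basis}_union_{method}"] = netinfer.network_stats(u)
        full = netinfer.union_networks(list(members.values()))
        ledger.unions[f"full_union_{method}"] = netinfer.network_stats(full)
        nets_by_class.setdefault("union", {})[method] = full
    return ledger, nets_by_class


def gain_report(ledger: RunLedger) -> dict[str, dict[str, int]]:
    """Union-vs-complete comparison per method.

    Reports union vertices, complete-network vertices and their
    difference (the coverage gain), plus the complete dataset's
    input-vs-network coverage gap.
    """
    if "complete" not in ledger.datasets:
        raise ValueError("ledger has no complete-dataset run")
    out: dict[str, dict[str, int]] = {}
    comp = ledger.datasets["complete"]
    for method, stats in comp.networks.items():
        key = f"full_union_{method}"
        if key not in ledger.unions:
            raise ValueError(f"ledger has no union run for {method!r}")
        union_v = ledger.unions[key]["nonisolated_vertices"]
        complete_v = stats["nonisolated_vertices"]
        out[method] = {
            "union_vertices": union_v,
            "complete_vertices": complete_v,
            "gain": union_v - complete_v,
            "coverage_gap": comp.genes_retained - complete_v,
        }
    return out


def filtered_gene_gain(ledger: RunLedger) -> dict[str, object]:
    """Union-of-category filtered gene sets vs the aggregate filtered set."""
    union_genes: set[str] = set()
    for name, genes in ledger.retained_genes.items():
        if name != "complete":
            union_genes.update(genes)
    complete_genes = set(ledger.retained_genes.get("complete", []))
    return {
        "union_retained": len(union_genes),
        "complete_retained": len(complete_genes),
        "gain": len(union_genes - complete_genes),
        "is_superset": complete_genes <= union_genes,
        "gained_genes": sorted(union_genes - complete_genes),
    }
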