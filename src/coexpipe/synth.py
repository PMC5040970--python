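"""Synthetic microarray compendium generator.

Emulates the statistical structure of a large multi-submission Affymetrix
compendium so that every pipeline stage can be tested against ground truth:

* **Bulk genes** are expressed in every array with a gene-specific dynamic
  range; their across-array IQRs follow a broad unimodal (log-normal)
  distribution, giving the IQR histogram its characteristic mode.
* **Category-specific genes** sit at a low, nearly flat baseline in most
  arrays and switch to a high, variable regime only in the arrays of their
  own tissue/process category.  On the aggregate matrix their IQR collapses
  into a narrow low-IQR spike (the high regime occupies less than a quartile
  of the arrays), while inside their own category they show a full dynamic
  range — the phenomenon that motivates partitioned filtering.
* **Submissions** group arrays; exact-duplicate arrays are re-emitted
  byte-identically under new ids in an extra submission, near-duplicate
  submissions repeat another submission's description with slightly
  perturbed values.
* **Outlier arrays** carry a global additive log2 shift (bad hybridization),
  detectable through RLE/NUSE diagnostics.
* **Control (spike-in) probe-sets** are high-intensity everywhere except in
  a configurable set of failed-hybridization arrays.
* **Planted gene–gene dependencies** (linear, quadratic, sinusoidal) give
  network inference a ground-truth edge set; nonlinear relations are
  invisible to Pearson correlation but not to mutual information.

Each probe-set is emitted as ``n_probes_per_set`` probe rows with fixed
per-probe affinity offsets, so probe-level model QC has structure to fit.
All randomness flows from ``SynthConfig.seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import (
    AnnotationMap,
    ExpressionMatrix,
    GeneNetwork,
    Method,
    Source,
    Space,
    SubmissionRecord,
    ValidationError,
    NO_MATCH,
)


class ConfigError(ValueError):
    """Infeasible or inconsistent generator configuration."""


@dataclass(frozen=True)
class CategorySpec:
    basis: str  # "tissue" | "process"
    class_name: str
    n_submissions: int
    arrays_per_submission: int


@dataclass(frozen=True)
class PlantedEdge:
    gene_a: int  # index into the gene list
    gene_b: int
    relation: str  # "linear" | "quadratic" | "sinusoidal"
    strength: float  # in [0, 1]


@dataclass
class SynthConfig:
    """Study conditions for one synthetic compendium.

    Defaults describe a compendium large enough for the IQR-threshold
    geometry to be stable: 4500 genes (10% category-specific), six
    tissue/process categories of 8 submissions x 20 arrays (960 arrays),
    a handful of duplicates, QC outliers and spike-in failures.
    """

    n_genes: int = 4500
    # 5 probes per set keeps probe-level tables desk-sized while giving the
    # per-array NUSE standard errors enough residual df for a stable spread
    n_probes_per_set: int = 5
    categories: tuple[CategorySpec, ...] = (
        CategorySpec("tissue", "Root", 8, 20),
        CategorySpec("tissue", "Leaf", 8, 20),
        CategorySpec("tissue", "Flower", 8, 20),
        CategorySpec("process", "Stress", 8, 20),
        CategorySpec("process", "Light", 8, 20),
        CategorySpec("process", "Hormone", 8, 20),
    )
    frac_category_specific_genes: float = 0.11
    planted_edges: tuple[PlantedEdge, ...] = ()
    n_exact_duplicates: int = 2
    n_near_duplicates: int = 1
    n_outlier_arrays: int = 3
    outlier_shift: float = 1.0  # log2 units
    n_spikein_failures: int = 1
    n_control_probesets: int = 3
    n_decoy_probesets: int = 12  # no_match / multi-AGI probe-sets
    seed: int | None = None

    # gene model parameters (log2 space)
    bulk_mean_loc: float = 7.0
    bulk_mean_scale: float = 1.0
    bulk_iqr_median: float = 0.45  # median of the bulk across-array IQR
    bulk_iqr_log_sd: float = 0.30
    specific_baseline: float = 5.0
    # baseline noise of category-specific genes: within a foreign category
    # their IQR sits at 1.349*sd = 0.0375 (inside the lowest occupied
    # histogram bin), on the aggregate at ~1.81*sd = 0.050
    specific_off_sd: float = 0.0278
    specific_on_shift: float = 3.0
    specific_on_sd: float = 0.70
    # probe affinity offsets are kept moderate so the robust summary's
    # residual jitter stays below the specific-gene baseline spread
    probe_affinity_sd: float = 0.15
    # residual per-probe noise beyond the affinity offsets; kept well below
    # the specific-gene baseline sd so summarization preserves the IQR
    # geometry the category-specific design calibrates
    probe_noise_sd: float = 0.02
    # residual per-array brightness after platform scaling; kept small because
    # the probe-level QC model is fit to unscaled log2 intensities
    array_gain_log_sd: float = 0.015
    near_duplicate_sd: float = 0.05
    control_present_log2: float = 9.5
    control_absent_log2: float = 3.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        if not 0.0 <= self.frac_category_specific_genes <= 1.0:
            raise ConfigError("frac_category_specific_genes must be in [0, 1]")
        for name in (
            "n_genes", "n_probes_per_set", "n_exact_duplicates",
            "n_near_duplicates", "n_outlier_arrays", "n_spikein_failures",
            "n_control_probesets", "n_decoy_probesets",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.n_probes_per_set < 1:
            raise ConfigError("n_probes_per_set must be >= 1")
        for e in self.planted_edges:
            if not 0.0 <= e.strength <= 1.0:
                raise ConfigError("planted edge strength must be in [0, 1]")
            if e.relation not in ("linear", "quadratic", "sinusoidal"):
                raise ConfigError(f"unknown relation {e.relation!r}")
        if self.categories:
            n_specific = self._n_specific
            if n_specific > self.n_genes:
                raise ConfigError("more category-specific genes than genes")

    @property
    def _n_specific(self) -> int:
        n = int(round(self.n_genes * self.frac_category_specific_genes))
        # spread evenly; truncate to a multiple of the category count
        k = len(self.categories)
        return (n // k) * k if k else 0

    @property
    def n_arrays(self) -> int:
        return sum(c.n_submissions * c.arrays_per_submission for c in self.categories)


@dataclass
class GroundTruth:
    """What the generator planted, for downstream verification."""

    category_specific_genes: dict[str, set[str]]
    planted_network: GeneNetwork
    duplicate_pairs: list[tuple[str, str]]
    near_duplicate_submissions: list[tuple[str, str]]
    outlier_array_ids: set[str]
    spikein_absent_arrays: set[str]
    gene_ids: list[str] = field(default_factory=list)
    probeset_of_gene: dict[str, str] = field(default_factory=dict)
    category_arrays: dict[str, list[str]] = field(default_factory=dict)


def _agi(i: int) -> str:
    """Synthetic Arabidopsis-style gene identifier."""
    return f"AT{i % 5 + 1}G{(i + 1) * 10:05d}"


_DESCRIPTIONS = [
    "transcriptome profiling of {cls} samples under controlled conditions",
    "expression analysis of {cls} tissue collected from wild type plants",
    "microarray study of {cls} response in arabidopsis seedlings",
    "time course of {cls} treatment replicate series",
    "comparison of mutant and wild type {cls} expression profiles",
]


def _apply_relation(x: np.ndarray, relation: str, strength: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Return a response in z-score units with dependence of given strength."""
    z = (x - x.mean()) / (x.std() + 1e-12)
    if relation == "linear":
        f = z
    elif relation == "quadratic":
        f = (z * z - 1.0) / math.sqrt(2.0)
    elif relation == "sinusoidal":
        f = np.sin(2.0 * math.pi * z) * math.sqrt(2.0)
    else:  # pragma: no cover - guarded by config validation
        raise ConfigError(f"unknown relation {relation!r}")
    f = (f - f.mean()) / (f.std() + 1e-12)
    noise = rng.standard_normal(x.shape)
    return strength * f + math.sqrt(max(0.0, 1.0 - strength**2)) * noise


def generate_compendium(
    cfg: SynthConfig, probe_level: bool = True
) -> tuple[ExpressionMatrix, list[SubmissionRecord], AnnotationMap, GroundTruth]:
    """Generate one compendium.

    Returns the raw expression matrix (probe-level when ``probe_level`` is
    true, otherwise the ideal probe-set-level signals without probe affinity
    effects — convenient when only post-summarization behaviour is under
    study), the submission metadata, the probe-set annotation map and the
    ground truth.
    """
    rng = np.random.default_rng(cfg.seed)

    # --- layout: categories -> submissions -> arrays ---------------------
    submissions: list[SubmissionRecord] = []
    category_arrays: dict[str, list[str]] = {}
    array_category: list[str] = []
    sub_idx = 0
    for cat in cfg.categories:
        category_arrays[cat.class_name] = []
        for _ in range(cat.n_submissions):
            sub_id = f"SUB{sub_idx:04d}"
            arrays = [
                f"{sub_id}_A{a:02d}" for a in range(cat.arrays_per_submission)
            ]
            desc = _DESCRIPTIONS[sub_idx % len(_DESCRIPTIONS)].format(
                cls=cat.class_name.lower()
            )
            submissions.append(
                SubmissionRecord(sub_id, Source.OTHER, desc, arrays)
            )
            category_arrays[cat.class_name].extend(arrays)
            array_category.extend([cat.class_name] * cat.arrays_per_submission)
            sub_idx += 1
    n_arrays = len(array_category)
    if n_arrays == 0:
        raise ConfigError("configuration yields zero arrays")

    # --- gene-level log2 expression --------------------------------------
    n_spec = cfg._n_specific
    n_bulk = cfg.n_genes - n_spec
    gene_ids = [_agi(i) for i in range(cfg.n_genes)]

    log2 = np.empty((cfg.n_genes, n_arrays))
    # bulk genes: gene-specific mean and spread; IQR of a normal is 1.349 sigma
    bulk_mu = rng.normal(cfg.bulk_mean_loc, cfg.bulk_mean_scale, n_bulk)
    bulk_sigma = np.exp(
        rng.normal(math.log(cfg.bulk_iqr_median / 1.349), cfg.bulk_iqr_log_sd, n_bulk)
    )
    # genes carrying planted dependencies get a generous dynamic range
    # (co-regulated genes vary coordinately), so the dependency is not
    # erased by variance filtering before network construction
    for e in cfg.planted_edges:
        for gi in (e.gene_a, e.gene_b):
            if gi < n_bulk:
                bulk_sigma[gi] = max(bulk_sigma[gi], 1.5 * cfg.bulk_iqr_median / 1.349)
    log2[:n_bulk] = bulk_mu[:, None] + bulk_sigma[:, None] * rng.standard_normal(
        (n_bulk, n_arrays)
    )

    # category-specific genes: flat low baseline, active in own category only
    class_names = [c.class_name for c in cfg.categories]
    per_cat = n_spec // len(class_names) if class_names else 0
    category_specific: dict[str, set[str]] = {c: set() for c in class_names}
    cat_mask = {
        c: np.array([a == c for a in array_category]) for c in class_names
    }
    for k in range(n_spec):
        gi = n_bulk + k
        cls = class_names[k // per_cat] if per_cat else class_names[0]
        category_specific[cls].add(gene_ids[gi])
        row = cfg.specific_baseline + cfg.specific_off_sd * rng.standard_normal(n_arrays)
        m = cat_mask[cls]
        row[m] = (
            cfg.specific_baseline
            + cfg.specific_on_shift
            + cfg.specific_on_sd * rng.standard_normal(int(m.sum()))
        )
        log2[gi] = row

    # --- planted dependencies --------------------------------------------
    planted = GeneNetwork.from_edges([], Method.MI, provenance="planted")
    for e in cfg.planted_edges:
        if not (0 <= e.gene_a < cfg.n_genes and 0 <= e.gene_b < cfg.n_genes):
            raise ConfigError("planted edge gene index out of range")
        ga, gb = gene_ids[e.gene_a], gene_ids[e.gene_b]
        # dependence is imposed on the arrays where both genes are active
        scope = np.ones(n_arrays, bool)
        for cls, genes in category_specific.items():
            if ga in genes or gb in genes:
                scope &= cat_mask[cls]
        if not scope.any():
            raise ConfigError(
                f"planted edge {ga}-{gb}: genes are specific to disjoint categories"
            )
        x = log2[e.gene_a, scope]
        resp = _apply_relation(x, e.relation, e.strength, rng)
        mu, sd = log2[e.gene_b, scope].mean(), log2[e.gene_b, scope].std()
        log2[e.gene_b, scope] = mu + sd * resp
        planted.graph.add_edge(ga, gb, score=e.strength,
                               relation=e.relation)

    # --- outlier arrays: global additive shift ----------------------------
    candidate = rng.permutation(n_arrays)
    all_array_ids = [a for s in submissions for a in s.array_ids]
    outliers = set(candidate[: cfg.n_outlier_arrays].tolist())
    log2[:, list(outliers)] += cfg.outlier_shift
    outlier_ids = {all_array_ids[j] for j in outliers}

    # --- spike-in controls ------------------------------------------------
    spike_fail = set(
        candidate[cfg.n_outlier_arrays:
                  cfg.n_outlier_arrays + cfg.n_spikein_failures].tolist()
    )
    spike_fail_ids = {all_array_ids[j] for j in spike_fail}
    control_ids = [f"AFFX-BioB-{i}_at" for i in range(cfg.n_control_probesets)]
    controls = np.full((cfg.n_control_probesets, n_arrays), cfg.control_present_log2)
    controls += 0.2 * rng.standard_normal(controls.shape)
    if spike_fail:
        controls[:, list(spike_fail)] = cfg.control_absent_log2 + 0.2 * rng.standard_normal(
            (cfg.n_control_probesets, len(spike_fail))
        )

    # --- per-array gain (scale-factor structure) --------------------------
    gains = rng.normal(0.0, cfg.array_gain_log_sd, n_arrays)
    log2 += gains[None, :]
    controls += gains[None, :]

    # --- probe-set / annotation layout ------------------------------------
    probeset_ids = [f"PS{i:05d}_at" for i in range(cfg.n_genes)]
    entries: dict[str, list[str]] = {
        ps: [g] for ps, g in zip(probeset_ids, gene_ids)
    }
    for c in control_ids:
        entries[c] = [NO_MATCH]
    # decoys: alternate no_match / over-annotated (>3 AGIs) probe-sets
    decoy_ids = [f"PSX{i:04d}_at" for i in range(cfg.n_decoy_probesets)]
    for i, d in enumerate(decoy_ids):
        if i % 2 == 0:
            entries[d] = [NO_MATCH]
        else:
            entries[d] = [_agi(9000 + 4 * i + j) for j in range(4)]
    annotation = AnnotationMap(entries)

    # decoy expression: mid-level noise rows
    decoys = 6.0 + 0.5 * rng.standard_normal((cfg.n_decoy_probesets, n_arrays))

    gene_log2 = np.vstack([log2, controls, decoys])
    row_sets = probeset_ids + control_ids + decoy_ids

    # --- expand to probe level -------------------------------------------
    if probe_level:
        P = cfg.n_probes_per_set
        aff = cfg.probe_affinity_sd * rng.standard_normal((gene_log2.shape[0], P))
        aff -= aff.mean(axis=1, keepdims=True)  # affinities sum to zero
        noise = cfg.probe_noise_sd * rng.standard_normal((gene_log2.shape[0], P, n_arrays))
        probe_log2 = gene_log2[:, None, :] + aff[:, :, None] + noise
        values = np.power(2.0, probe_log2).reshape(-1, n_arrays)
        row_ids = [f"{ps}_p{p}" for ps in row_sets for p in range(P)]
    else:
        values = np.power(2.0, gene_log2)
        row_ids = list(row_sets)

    # --- duplicates -------------------------------------------------------
    duplicate_pairs: list[tuple[str, str]] = []
    if cfg.n_exact_duplicates > 0:
        src = candidate[
            cfg.n_outlier_arrays + cfg.n_spikein_failures:
            cfg.n_outlier_arrays + cfg.n_spikein_failures + cfg.n_exact_duplicates
        ].tolist()
        if len(src) < cfg.n_exact_duplicates:
            raise ConfigError("not enough arrays to duplicate")
        dup_ids = [f"ZDUP_A{k:02d}" for k in range(len(src))]
        values = np.hstack([values, values[:, src]])
        duplicate_pairs = [(all_array_ids[j], d) for j, d in zip(src, dup_ids)]
        submissions.append(
            SubmissionRecord(
                "ZDUPSUB", Source.OTHER,
                "resubmission of previously deposited hybridizations",
                dup_ids,
            )
        )
        all_array_ids = all_array_ids + dup_ids

    near_pairs: list[tuple[str, str]] = []
    for k in range(cfg.n_near_duplicates):
        orig = submissions[k % max(1, sub_idx)]
        nd_id = f"ZNEAR{k:02d}"
        col_idx = [all_array_ids.index(a) for a in orig.array_ids]
        pert = values[:, col_idx] * np.power(
            2.0, cfg.near_duplicate_sd * rng.standard_normal((values.shape[0], len(col_idx)))
        )
        nd_arrays = [f"{nd_id}_A{a:02d}" for a in range(len(col_idx))]
        values = np.hstack([values, pert])
        submissions.append(
            SubmissionRecord(nd_id, Source.OTHER, orig.description, nd_arrays)
        )
        near_pairs.append((orig.submission_id, nd_id))
        all_array_ids = all_array_ids + nd_arrays

    mat = ExpressionMatrix(values, row_ids, all_array_ids, Space.RAW)

    # content hashes for dedup
    hashes = mat.column_hashes()
    for s in submissions:
        s.content_hashes = {a: hashes[a] for a in s.array_ids}

    truth = GroundTruth(
        category_specific_genes=category_specific,
        planted_network=planted,
        duplicate_pairs=duplicate_pairs,
        near_duplicate_submissions=near_pairs,
        outlier_array_ids=outlier_ids,
        spikein_absent_arrays=spike_fail_ids,
        gene_ids=gene_ids,
        probeset_of_gene={g: ps for ps, g in zip(probeset_ids, gene_ids)},
        category_arrays=category_arrays,
    )
    return mat, submissions, annotation, truth


def expression_profile_histogram(
    mat: ExpressionMatrix, gene: str, bin_width: float = 0.25
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of one gene's expression values across arrays.

    Bins are anchored at 0 with the given width (log2 units for log-space
    matrices).  Returns ``(bin_edges, counts)``; counts sum to the number
    of arrays.
    """
    if bin_width <= 0:
        raise ConfigError("bin_width must be > 0")
    x = mat.row(gene)  # KeyError for unknown gene
    lo = math.floor(x.min() / bin_width)
    hi = math.floor(x.max() / bin_width) + 1
    edges = np.arange(lo, hi + 1) * bin_width
    counts, _ = np.histogram(x, bins=edges)
    return edges, counts


def count_histogram_modes(counts: np.ndarray, min_gap: int = 2) -> int:
    """Number of local maxima separated by at least ``min_gap`` empty bins.

    Used to verify the bimodal expression profile of category-specific
    genes: a low baseline mode and a high active mode.
    """
    occupied = counts > 0
    modes = 0
    in_block = False
    gap = min_gap
    for c in occupied:
        if c and not in_block:
            if gap >= min_gap:
                modes += 1
            else:
                pass  # same block, gap too small
            in_block = True
            gap = 0
        elif c:
            gap = 0
        else:
            if in_block:
                in_block = False
            gap += 1
    return modes


def small_network_config(seed: int, n_arrays: int = 300,
                         n_genes: int = 20) -> SynthConfig:
    """Structure-recovery study conditions: a small dense-sampled dataset
    with five strong planted dependencies (three linear, one quadratic,
    one sinusoidal) among 20 genes over 300 arrays."""
    edges = (
        PlantedEdge(0, 1, "linear", 0.9),
        PlantedEdge(2, 3, "linear", 0.9),
        PlantedEdge(4, 5, "linear", 0.85),
        PlantedEdge(6, 7, "quadratic", 0.9),
        PlantedEdge(8, 9, "sinusoidal", 0.9),
    )
    return SynthConfig(
        n_genes=n_genes,
        n_probes_per_set=1,
        categories=(CategorySpec("tissue", "Whole Plant", 1, n_arrays),),
        frac_category_specific_genes=0.0,
        planted_edges=edges,
        n_exact_duplicates=0,
        n_near_duplicates=0,
        n_outlier_arrays=0,
        n_spikein_failures=0,
        n_control_probesets=0,
        n_decoy_probesets=0,
        seed=seed,
    )


def partitioned_network_config(seed: int) -> SynthConfig:
    """Desk-scale conditions for the partition-vs-aggregate comparison:
    three categories, category-specific genes carrying planted edges that
    are only observable inside their own category.

    400 genes keep the per-array QC medians and the IQR histogram stable
    while holding all-pairs network construction to seconds; the last 25
    genes are category-specific (5 per each of 5 categories, so the active
    regime stays below a quartile of the aggregate arrays) with planted
    in-category dependencies, and the first bulk genes carry global
    dependencies.
    """
    n_genes = 400
    edges = [
        # global bulk-bulk dependencies, visible in every partition
        PlantedEdge(0, 1, "linear", 0.9),
        PlantedEdge(2, 3, "linear", 0.9),
        PlantedEdge(4, 5, "quadratic", 0.9),
    ]
    # category-specific dependencies among each category's own genes
    for c in range(5):
        base = 375 + 5 * c
        edges.append(PlantedEdge(base, base + 1, "linear", 0.9))
        edges.append(PlantedEdge(base + 2, base + 3, "quadratic", 0.9))
    return SynthConfig(
        n_genes=n_genes,
        n_probes_per_set=1,
        categories=(
            CategorySpec("tissue", "Root", 2, 30),
            CategorySpec("tissue", "Leaf", 2, 30),
            CategorySpec("tissue", "Flower", 2, 30),
            CategorySpec("process", "Stress", 2, 30),
            CategorySpec("process", "Light", 2, 30),
        ),
        frac_category_specific_genes=25 / 400,
        planted_edges=tuple(edges),
        n_exact_duplicates=0,
        n_near_duplicates=0,
        n_outlier_arrays=0,
        n_spikein_failures=0,
        n_control_probesets=0,
        n_decoy_probesets=0,
        seed=seed,
    )
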