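"""Probe-set annotation cleanup and collapsing to genes.

Probe-set → gene maps from evolving genome annotations are many-to-many.
The cleanup removes unannotated probe-sets and promiscuous ones (mapping
to more than ``max_agis`` gene identifiers), then clusters probe-sets that
share at least one gene id (connected components of the sharing graph) and
keeps a single representative per cluster — the member with the fewest
gene ids, ties broken by lexicographically smallest probe-set id.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .core import AnnotationMap, ExpressionMatrix, NO_MATCH


@dataclass
class CleanupReport:
    n_input: int = 0
    n_no_match: int = 0
    n_over_annotated: int = 0
    n_retained: int = 0


@dataclass
class ProbeCluster:
    members: list[str]
    representative: str
    agi_union: set[str] = field(default_factory=set)


def clean_annotation(
    amap: AnnotationMap, max_agis: int = 3
) -> tuple[AnnotationMap, CleanupReport]:
    """Drop no_match and over-annotated (> ``max_agis`` gene ids) probe-sets."""
    rep = CleanupReport(n_input=len(amap.entries))
    kept: dict[str, list[str]] = {}
    for probe, genes in amap.entries.items():
        if NO_MATCH in genes:
            rep.n_no_match += 1
        elif len(genes) > max_agis:
            rep.n_over_annotated += 1
        else:
            kept[probe] = list(genes)
    rep.n_retained = len(kept)
    return AnnotationMap(kept), rep


def cluster_and_select(amap: AnnotationMap) -> list[ProbeCluster]:
    """Connected components of the shared-gene graph, with representatives.

    Two probe-sets are linked when their gene lists intersect.  The
    clusters partition the (cleaned) probe-sets; output is sorted by
    representative id for determinism.
    """
    g = nx.Graph()
    g.add_nodes_from(amap.entries)
    by_gene: dict[str, list[str]] = {}
    for probe, genes in amap.entries.items():
        for gene in genes:
            by_gene.setdefault(gene, []).append(probe)
    for probes in by_gene.values():
        for other in probes[1:]:
            g.add_edge(probes[0], other)
    clusters = []
    for comp in nx.connected_components(g):
        members = sorted(comp)
        rep = min(members, key=lambda p: (len(amap.entries[p]), p))
        union: set[str] = set()
        for p in members:
            union.update(amap.entries[p])
        clusters.append(ProbeCluster(members, rep, union))
    clusters.sort(key=lambda c: c.representative)
    return clusters


def collapse_matrix(
    mat: ExpressionMatrix, clusters: list[ProbeCluster], amap: AnnotationMap
) -> ExpressionMatrix:
    """Keep one representative row per cluster, relabeled by its smallest gene id."""
    rows = []
    labels = []
    for c in clusters:
        if c.representative not in mat.row_ids:
            raise KeyError(
                f"representative probe-set {c.representative!r} missing from matrix"
            )
        rows.append(c.representative)
        labels.append(min(amap.entries[c.representative]))
    sub = mat.subset_rows(rows)
    return ExpressionMatrix(sub.values, labels, sub.col_ids, sub.space,
                            sub.allow_missing)
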