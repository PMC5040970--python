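"""Core domain types and file I/O for the pipeline.

The pipeline moves one central container — an expression matrix with
rows = probe-sets (later genes) and columns = arrays (chips) — through a
sequence of spaces: ``raw`` intensities, ``log2``, ``log2_centered`` (per-gene
mean subtracted) and ``normalized`` (quantile-normalized).  Around it live
lightweight records for repository submissions, probe-set → gene annotation
maps, experiment-category assignments and the inferred gene networks.

All on-disk formats are plain text: TSV matrices and edge lists, SIF
networks, JSON metadata.  Readers validate the structural invariants
(unique identifiers, shape consistency, non-negative raw intensities) and
writers are exact inverses up to float formatting.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

NO_MATCH = "no_match"


class Space(str, Enum):
    """Value space of an expression matrix."""

    RAW = "raw"
    LOG2 = "log2"
    LOG2_CENTERED = "log2_centered"
    NORMALIZED = "normalized"


class ValidationError(ValueError):
    """An input violates a structural invariant."""


class ParseError(ValueError):
    """A file could not be parsed."""


@dataclass
class ExpressionMatrix:
    """Genes/probe-sets × arrays table of expression values.

    Parameters
    ----------
    values : ndarray of shape (n_rows, n_cols)
        Expression values; intensity units in ``raw`` space, log2 units
        otherwise.
    row_ids : sequence of str
        Probe, probe-set or gene identifiers (unique).
    col_ids : sequence of str
        Array (chip) identifiers (unique).
    space : Space
        Which transformation stage the values are in.
    """

    values: np.ndarray
    row_ids: list[str]
    col_ids: list[str]
    space: Space = Space.RAW
    allow_missing: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.row_ids = [str(r) for r in self.row_ids]
        self.col_ids = [str(c) for c in self.col_ids]
        self.space = Space(self.space)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D matrix")
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValidationError(
                f"shape {self.values.shape} does not match "
                f"{len(self.row_ids)} row ids × {len(self.col_ids)} col ids"
            )
        if len(set(self.row_ids)) != len(self.row_ids):
            raise ValidationError("duplicate row ids")
        if len(set(self.col_ids)) != len(self.col_ids):
            raise ValidationError("duplicate column ids")
        if np.isnan(self.values).any():
            if self.space is Space.RAW or not self.allow_missing:
                raise ValidationError(
                    f"NaN values not permitted in space={self.space.value!r}"
                    + ("" if self.space is Space.RAW else " (set allow_missing=True)")
                )
        if self.space is Space.RAW and (self.values < 0).any():
            raise ValidationError("raw-space matrix contains negative values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def row_index(self, row_id: str) -> int:
        try:
            return self.row_ids.index(row_id)
        except ValueError:
            raise KeyError(f"unknown row id {row_id!r}") from None

    def row(self, row_id: str) -> np.ndarray:
        return self.values[self.row_index(row_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.col_ids)

    def subset_cols(self, col_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = {c: i for i, c in enumerate(self.col_ids)}
        missing = [c for c in col_ids if c not in idx]
        if missing:
            raise KeyError(f"unknown column ids: {missing}")
        sel = [idx[c] for c in col_ids]
        return ExpressionMatrix(
            self.values[:, sel], list(self.row_ids), list(col_ids),
            self.space, self.allow_missing,
        )

    def subset_rows(self, row_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = {r: i for i, r in enumerate(self.row_ids)}
        missing = [r for r in row_ids if r not in idx]
        if missing:
            raise KeyError(f"unknown row ids: {missing}")
        sel = [idx[r] for r in row_ids]
        return ExpressionMatrix(
            self.values[sel, :], list(row_ids), list(self.col_ids),
            self.space, self.allow_missing,
        )

    def with_values(self, values: np.ndarray, space: Space) -> "ExpressionMatrix":
        return ExpressionMatrix(
            values, list(self.row_ids), list(self.col_ids), space,
            self.allow_missing,
        )

    def column_hashes(self) -> dict[str, str]:
        """MD5 digest of each column's raw bytes (duplicate detection)."""
        out = {}
        for j, cid in enumerate(self.col_ids):
            out[cid] = hashlib.md5(
                np.ascontiguousarray(self.values[:, j]).tobytes()
            ).hexdigest()
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return (
            self.row_ids == other.row_ids
            and self.col_ids == other.col_ids
            and self.space == other.space
            and np.array_equal(self.values, other.values, equal_nan=True)
        )


class Source(str, Enum):
    ARRAYEXPRESS = "ArrayExpress"
    GEO = "GEO"
    NASC = "NASC"
    OTHER = "other"


@dataclass
class SubmissionRecord:
    """One repository submission: a named set of arrays plus free-text metadata."""

    submission_id: str
    source: Source = Source.OTHER
    description: str = ""
    array_ids: list[str] = field(default_factory=list)
    content_hashes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.source = Source(self.source)
        if not self.array_ids:
            raise ValidationError(
                f"submission {self.submission_id!r} has no arrays"
            )


@dataclass
class AnnotationMap:
    """Probe-set → gene-id list map; ``no_match`` marks unannotated probe-sets."""

    entries: dict[str, list[str]]

    def __post_init__(self) -> None:
        for probe, genes in self.entries.items():
            if not genes:
                raise ValidationError(f"probe-set {probe!r} has an empty gene list")

    @property
    def n_no_match(self) -> int:
        return sum(1 for g in self.entries.values() if g == [NO_MATCH])

    def __len__(self) -> int:
        return len(self.entries)


class Method(str, Enum):
    PCC = "pcc"
    MI = "mi"


@dataclass
class GeneNetwork:
    """Undirected weighted co-expression network.

    Edges carry a single ``score``: Pearson correlation in [−1, 1] or mutual
    information in nats (≥ 0).  ``provenance`` names the dataset the network
    was inferred from: a category name, ``"complete"`` or ``"union"``.
    """

    graph: nx.Graph
    method: Method
    provenance: str = "complete"

    def __post_init__(self) -> None:
        self.method = Method(self.method)
        for u, v in self.graph.edges():
            if u == v:
                raise ValidationError(f"self-edge on {u!r}")

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str, float]],
        method: Method | str,
        vertices: Iterable[str] = (),
        provenance: str = "complete",
    ) -> "GeneNetwork":
        g = nx.Graph()
        g.add_nodes_from(vertices)
        for u, v, s in edges:
            g.add_edge(u, v, score=float(s))
        return cls(g, Method(method), provenance)

    @property
    def vertices(self) -> set[str]:
        return set(self.graph.nodes())

    @property
    def n_vertices(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def n_nonisolated(self) -> int:
        return sum(1 for n in self.graph.nodes() if self.graph.degree(n) > 0)

    def edge_set(self) -> dict[tuple[str, str], float]:
        """Edges keyed by lexicographically sorted endpoint pair."""
        return {
            tuple(sorted((u, v))): d["score"]
            for u, v, d in self.graph.edges(data=True)
        }

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneNetwork):
            return NotImplemented
        return (
            self.method == other.method
            and self.vertices == other.vertices
            and self.edge_set() == other.edge_set()
        )


class Basis(str, Enum):
    TISSUE = "tissue"
    PROCESS = "process"


@dataclass
class CategoryAssignment:
    """Submissions assigned to one tissue or process class (multi-label)."""

    basis: Basis
    class_name: str
    submission_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.basis = Basis(self.basis)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_expression_matrix(
    path, space: Space | str, allow_missing: bool = False
) -> ExpressionMatrix:
    """Read a TSV expression matrix (header row = array ids, first column = row ids)."""
    # read the header line verbatim: pandas mangles duplicate column names
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
    if not header:
        raise ParseError(f"{path}: empty file")
    cols = header.split("\t")[1:]
    if len(set(cols)) != len(cols):
        raise ValidationError(f"{path}: duplicate column ids")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, header=0)
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: empty file") from None
    except pd.errors.ParserError as e:
        raise ParseError(f"{path}: {e}") from None
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicate row ids {dups}")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as e:
        raise ParseError(f"{path}: non-numeric value ({e})") from None
    return ExpressionMatrix(
        values, [str(r) for r in df.index], cols, Space(space), allow_missing
    )


def write_expression_matrix(mat: ExpressionMatrix, path) -> None:
    mat.to_frame().to_csv(path, sep="\t", index_label="id", float_format="%.10g")


def read_annotation(path, sep: str = ",") -> AnnotationMap:
    """Read a probe-set → gene-list TSV (column 2 is a ``sep``-joined list)."""
    entries: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            probe, genes = parts
            if probe in entries:
                raise ValidationError(f"{path}:{lineno}: duplicate probe-set {probe!r}")
            entries[probe] = [g.strip() for g in genes.split(sep) if g.strip()]
    return AnnotationMap(entries)


def write_annotation(amap: AnnotationMap, path, sep: str = ",") -> None:
    with open(path, "w") as fh:
        for probe in amap.entries:
            fh.write(f"{probe}\t{sep.join(amap.entries[probe])}\n")


_VERTEX_PREFIX = "#vertex\t"


def write_network(net: GeneNetwork, path, format: str = "tsv_edgelist") -> None:
    """Write a network as a TSV edge list or SIF file.

    Isolated vertices are preserved through ``#vertex`` comment lines so that
    a read of the written file reproduces the full vertex set.  Edge lines
    list the lexicographically smaller gene first, sorted, for stable diffs.
    """
    if format not in ("tsv_edgelist", "sif"):
        raise ValueError(f"unknown format {format!r}")
    edges = sorted(net.edge_set().items())
    with open(path, "w") as fh:
        fh.write(f"#method\t{net.method.value}\n")
        fh.write(f"#provenance\t{net.provenance}\n")
        for v in sorted(net.vertices):
            if net.graph.degree(v) == 0:
                fh.write(f"{_VERTEX_PREFIX}{v}\n")
        for (u, v), s in edges:
            if format == "tsv_edgelist":
                fh.write(f"{u}\t{v}\t{s:.6f}\n")
            else:
                fh.write(f"{u}\t{net.method.value}\t{v}\n")


def read_network(path) -> GeneNetwork:
    """Read a TSV edge list written by :func:`write_network`."""
    method = Method.PCC
    provenance = "complete"
    vertices: list[str] = []
    edges: list[tuple[str, str, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(_VERTEX_PREFIX):
                vertices.append(line[len(_VERTEX_PREFIX):])
            elif line.startswith("#method\t"):
                method = Method(line.split("\t")[1])
            elif line.startswith("#provenance\t"):
                provenance = line.split("\t")[1]
            elif line.startswith("#"):
                continue
            else:
                parts = line.split("\t")
                if len(parts) != 3:
                    raise ParseError(f"{path}:{lineno}: expected 3 columns")
                edges.append((parts[0], parts[1], float(parts[2])))
    return GeneNetwork.from_edges(edges, method, vertices, provenance)


def read_submissions(path) -> list[SubmissionRecord]:
    """Read submission metadata from a JSON list of records."""
    with open(path) as fh:
        raw = json.load(fh)
    return [
        SubmissionRecord(
            submission_id=r["submission_id"],
            source=Source(r.get("source", "other")),
            description=r.get("description", ""),
            array_ids=list(r["array_ids"]),
            content_hashes=dict(r.get("content_hashes", {})),
        )
        for r in raw
    ]


def write_submissions(subs: Sequence[SubmissionRecord], path) -> None:
    with open(path, "w") as fh:
        json.dump(
            [
                {
                    "submission_id": s.submission_id,
                    "source": s.source.value,
                    "description": s.description,
                    "array_ids": s.array_ids,
                    "content_hashes": s.content_hashes,
                }
                for s in subs
            ],
            fh,
            indent=1,
        )


def array_to_submission(subs: Sequence[SubmissionRecord]) -> dict[str, str]:
    """Map each array id to its submission id."""
    out: dict[str, str] = {}
    for s in subs:
        for a in s.array_ids:
            if a in out:
                raise ValidationError(
                    f"array {a!r} appears in submissions {out[a]!r} and {s.submission_id!r}"
                )
            out[a] = s.submission_id
    return out
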