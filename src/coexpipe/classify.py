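"""Keyword classification of submissions into tissue/process categories.

Submissions are assigned to every category whose keyword list hits their
free-text description: matching is case-insensitive, whole-word after
simple plural stripping ("roots" matches "root"), with multi-word phrases
matched as consecutive token runs.  An override file replays manual
curation decisions (add/remove, last wins) on top of the keyword pass.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import yaml

from .core import Basis, CategoryAssignment, ExpressionMatrix, SubmissionRecord, ValidationError

# Reconstruction of typical tissue/process vocabularies for a plant
# compendium; user-editable configuration, not ground truth.
DEFAULT_KEYWORDS: dict[tuple[str, str], list[str]] = {
    ("process", "Chemical"): ["chemical", "herbicide", "inhibitor", "ozone"],
    ("process", "Development"): ["development", "developmental", "embryo",
                                 "germination", "senescence"],
    ("process", "Hormone"): ["hormone", "auxin", "cytokinin", "ethylene",
                             "gibberellin", "abscisic", "aba", "jasmonate",
                             "brassinosteroid", "salicylic"],
    ("process", "Light"): ["light", "shade", "uv", "circadian", "photoperiod",
                           "dark"],
    ("process", "Metabolism"): ["metabolism", "metabolic", "starch", "sugar",
                                "nitrogen", "sulfur", "phosphate", "carbon"],
    ("process", "Pathogen"): ["pathogen", "infection", "bacteria", "fungus",
                              "virus", "elicitor", "pseudomonas", "botrytis"],
    ("process", "Stress"): ["stress", "drought", "salt", "cold", "heat",
                            "osmotic", "wounding", "oxidative"],
    ("tissue", "Flower"): ["flower", "floral", "petal", "stamen", "pollen",
                           "anther", "silique"],
    ("tissue", "Leaf"): ["leaf", "leaves", "rosette", "shoot"],
    ("tissue", "Root"): ["root", "lateral root", "root tip"],
    ("tissue", "Seedling"): ["seedling"],
    ("tissue", "Whole Plant"): ["whole plant", "whole seedling", "plant"],
}


@dataclass
class KeywordConfig:
    classes: dict[tuple[str, str], list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_KEYWORDS.items()}
    )

    def __post_init__(self) -> None:
        for (basis, cls), kws in self.classes.items():
            Basis(basis)
            if not kws:
                raise ValidationError(f"class {cls!r} has an empty keyword list")

    @classmethod
    def from_yaml(cls, path) -> "KeywordConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        classes = {
            (basis, name): [str(k).lower() for k in kws]
            for basis, group in raw.items()
            for name, kws in group.items()
        }
        return cls(classes)

    def to_yaml(self, path) -> None:
        out: dict[str, dict[str, list[str]]] = {}
        for (basis, name), kws in self.classes.items():
            out.setdefault(basis, {})[name] = list(kws)
        with open(path, "w") as fh:
            yaml.safe_dump(out, fh, sort_keys=True)


def _stem(token: str) -> str:
    """Light plural stripping: 'roots' -> 'root', 'leaves' -> 'leaf'."""
    if token.endswith("ves") and len(token) > 4:
        return token[:-3] + "f"
    if token.endswith("s") and not token.endswith("ss") and len(token) > 3:
        return token[:-1]
    return token


def _tokenize(text: str) -> list[str]:
    return [_stem(t) for t in re.findall(r"[a-z0-9]+", text.lower())]


def _phrase_hits(tokens: Sequence[str], phrase: str) -> bool:
    pt = _tokenize(phrase)
    if not pt:
        return False
    if len(pt) == 1:
        return pt[0] in tokens
    for i in range(len(tokens) - len(pt) + 1):
        if tokens[i:i + len(pt)] == pt:
            return True
    return False


def keyword_assign(
    submissions: Sequence[SubmissionRecord],
    cfg: KeywordConfig | None = None,
) -> tuple[list[CategoryAssignment], list[str]]:
    """Assign each submission to every class with at least one keyword hit.

    Returns the per-class assignments and the list of unassigned
    submission ids (no hits in any class).
    """
    cfg = cfg or KeywordConfig()
    assigned: dict[tuple[str, str], list[str]] = {k: [] for k in cfg.classes}
    hit_any: set[str] = set()
    for s in submissions:
        tokens = _tokenize(s.description)
        for key, keywords in cfg.classes.items():
            if any(_phrase_hits(tokens, kw) for kw in keywords):
                assigned[key].append(s.submission_id)
                hit_any.add(s.submission_id)
    assignments = [
        CategoryAssignment(Basis(basis), name, ids)
        for (basis, name), ids in assigned.items()
        if ids
    ]
    unassigned = [s.submission_id for s in submissions if s.submission_id not in hit_any]
    return assignments, unassigned


@dataclass
class Override:
    submission_id: str
    action: str  # "add" | "remove"
    basis: str
    class_name: str


def read_overrides(path) -> list[Override]:
    """TSV override file: submission_id, add|remove, basis, class."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValidationError(f"{path}:{lineno}: expected 4 columns")
            if parts[1] not in ("add", "remove"):
                raise ValidationError(f"{path}:{lineno}: unknown action {parts[1]!r}")
            out.append(Override(parts[0], parts[1], parts[2], parts[3]))
    return out


def apply_overrides(
    assignments: list[CategoryAssignment],
    overrides: Iterable[Override],
    known_submissions: Iterable[str],
) -> tuple[list[CategoryAssignment], list[str]]:
    """Replay curation overrides, last one wins.  Returns assignments + audit log."""
    known = set(known_submissions)
    table: dict[tuple[str, str], list[str]] = {
        (a.basis.value, a.class_name): list(a.submission_ids) for a in assignments
    }
    audit: list[str] = []
    for ov in overrides:
        if ov.submission_id not in known:
            raise ValidationError(f"override names unknown submission {ov.submission_id!r}")
        Basis(ov.basis)
        key = (ov.basis, ov.class_name)
        members = table.setdefault(key, [])
        if ov.action == "add":
            if ov.submission_id not in members:
                members.append(ov.submission_id)
                audit.append(f"add {ov.submission_id} -> {ov.basis}/{ov.class_name}")
        else:
            if ov.submission_id in members:
                members.remove(ov.submission_id)
                audit.append(f"remove {ov.submission_id} from {ov.basis}/{ov.class_name}")
    result = [
        CategoryAssignment(Basis(b), c, ids) for (b, c), ids in table.items() if ids
    ]
    return result, audit


def partition_matrices(
    mat: ExpressionMatrix,
    assignments: Sequence[CategoryAssignment],
    submissions: Sequence[SubmissionRecord],
) -> dict[str, ExpressionMatrix]:
    """One sub-matrix per class, holding the columns of its submissions' arrays.

    A column may appear in several class matrices (multi-label
    submissions); classes with no arrays present in the matrix are skipped
    with a warning.
    """
    import warnings

    arrays_of = {s.submission_id: s.array_ids for s in submissions}
    have = set(mat.col_ids)
    out: dict[str, ExpressionMatrix] = {}
    for a in assignments:
        cols: list[str] = []
        for sid in a.submission_ids:
            cols.extend(c for c in arrays_of.get(sid, []) if c in have)
        if not cols:
            warnings.warn(f"class {a.class_name!r} has no arrays in the matrix")
            continue
        out[a.class_name] = mat.subset_cols(cols)
    return out
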