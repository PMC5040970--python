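"""Reference summary statistics of the 11,760-chip Arabidopsis ATH1 compendium.

These are the printed audit numbers of the genome-scale compendium study
this pipeline reproduces at desk scale: per-repository collection and QC
counts, per-category dataset sizes, post-filter gene counts and network
sizes.  They are inputs to the reporting arithmetic (totals, coverage
gaps, union gains), not outputs of this package.
"""

from __future__ import annotations

# repository, experiments (submissions), CEL files collected, CEL files removed by QC
COLLECTION = {
    "ArrayExpress": {"experiments": 543, "cel_files": 7923, "qc_removed": 848},
    "GEO": {"experiments": 83, "cel_files": 1270, "qc_removed": 102},
    "NASC": {"experiments": 211, "cel_files": 2859, "qc_removed": 387},
    "AtGenExpress": {"experiments": 44, "cel_files": 1334, "qc_removed": 289},
}

# tissue/process categories: experiments and CEL files per class,
# and genes surviving per-category filtering
CATEGORIES = {
    ("process", "Chemical"): {"experiments": 75, "cel_files": 808, "genes": 18026},
    ("process", "Development"): {"experiments": 190, "cel_files": 2252, "genes": 17827},
    ("process", "Hormone"): {"experiments": 116, "cel_files": 1806, "genes": 17646},
    ("process", "Light"): {"experiments": 64, "cel_files": 1210, "genes": 17895},
    ("process", "Metabolism"): {"experiments": 214, "cel_files": 1535, "genes": 17989},
    ("process", "Pathogen"): {"experiments": 69, "cel_files": 1156, "genes": 17486},
    ("process", "Stress"): {"experiments": 153, "cel_files": 2476, "genes": 19041},
    ("tissue", "Flower"): {"experiments": 69, "cel_files": 764, "genes": 17209},
    ("tissue", "Leaf"): {"experiments": 279, "cel_files": 4268, "genes": 17215},
    ("tissue", "Root"): {"experiments": 121, "cel_files": 1939, "genes": 17775},
    ("tissue", "Seedling"): {"experiments": 379, "cel_files": 5234, "genes": 17960},
    ("tissue", "Whole Plant"): {"experiments": 144, "cel_files": 2359, "genes": 18805},
}

# complete-dataset networks: (A) fixed IQR threshold 0.65, (B) histogram-selected
COMPLETE_NETWORKS = {
    ("pcc", "A"): {"n_arrays": 11760, "genes_in_input": 13384, "genes_in_network": 2670},
    ("mi", "A"): {"n_arrays": 11760, "genes_in_input": 13384, "genes_in_network": 13181},
    ("pcc", "B"): {"n_arrays": 11760, "genes_in_input": 18806, "genes_in_network": 3940},
    ("mi", "B"): {"n_arrays": 11760, "genes_in_input": 18806, "genes_in_network": 18606},
}

# full-union networks over all tissue- and process-specific networks
UNION_NETWORKS = {
    "pcc": {"vertices": 8429, "edges": 131648},
    "mi": {"vertices": 20126, "edges": 638051},
}


def collection_totals() -> dict[str, int]:
    """Column totals of the collection table, plus the post-QC array count."""
    totals = {
        "experiments": sum(r["experiments"] for r in COLLECTION.values()),
        "cel_files": sum(r["cel_files"] for r in COLLECTION.values()),
        "qc_removed": sum(r["qc_removed"] for r in COLLECTION.values()),
    }
    totals["post_qc"] = totals["cel_files"] - totals["qc_removed"]
    return totals


def coverage_gap(genes_in_input: int, genes_in_network: int) -> int:
    """Genes present in the filtered input but absent from the network."""
    return genes_in_input - genes_in_network


def union_gain(union_vertices: int, complete_vertices: int) -> int:
    """Extra genes covered by the union network over the complete-dataset one."""
    return union_vertices - complete_vertices
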