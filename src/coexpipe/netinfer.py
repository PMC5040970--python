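"""Co-expression network construction: PCC and B-spline MI with DPI.

Two edge scores are supported:

* **Pearson correlation** with an empirical-FDR significance threshold:
  every gene's values are independently shuffled to build a pooled null
  distribution of |r|, and the threshold is the smallest t at which the
  expected number of null pairs ≥ t, per permutation, is at most
  ``fdr_level`` times the observed number.

* **Mutual information** estimated by fractional B-spline binning: each
  rank-scaled sample is spread over ``n_bins`` bins with B-spline basis
  weights (order ``spline_order``), and the plug-in MI (in nats) is
  computed from the weighted marginal and joint histograms.  Rank scaling
  makes the estimate invariant under strictly monotone transforms.
  Significance is a single network-wide threshold: the
  (1 − significance_level) quantile of MI values from permuted gene pairs.

The data processing inequality (DPI) prunes indirect edges: in every
triangle the strictly weakest edge is removed when its score falls below
``(1 − tolerance)`` times the smaller of the other two, judged against the
original scores in a single order-independent pass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .core import ExpressionMatrix, GeneNetwork, Method, ValidationError


class ConfigError(ValueError):
    pass


@dataclass
class MIEstimatorConfig:
    n_bins: int = 10
    spline_order: int = 3
    permutations: int = 1000
    significance_level: float = 0.01
    dpi_tolerance: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.spline_order > self.n_bins:
            raise ConfigError("spline_order must not exceed n_bins")
        if self.spline_order < 1:
            raise ConfigError("spline_order must be >= 1")
        if self.permutations < 100:
            raise ConfigError("permutations must be >= 100")
        if not 0.0 <= self.dpi_tolerance <= 1.0:
            raise ConfigError("dpi_tolerance must be in [0, 1]")
        if self.seed is None:
            raise ConfigError("seed is mandatory for permutation testing")


@dataclass
class PCCConfig:
    permutations: int = 100
    fdr_level: float = 0.01
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.permutations < 10:
            raise ConfigError("permutations must be >= 10")
        if self.seed is None:
            raise ConfigError("seed is mandatory for permutation testing")


# ---------------------------------------------------------------------------
# Pearson correlation
# ---------------------------------------------------------------------------

def _drop_zero_variance(mat: ExpressionMatrix) -> ExpressionMatrix:
    sd = mat.values.std(axis=1)
    keep = [g for g, s in zip(mat.row_ids, sd) if s > 0]
    if len(keep) < len(mat.row_ids):
        warnings.warn(
            f"excluding {len(mat.row_ids) - len(keep)} zero-variance genes"
        )
        return mat.subset_rows(keep)
    return mat


def pcc_all_pairs(mat: ExpressionMatrix) -> tuple[np.ndarray, list[str]]:
    """Full symmetric Pearson correlation table (zero-variance genes excluded)."""
    if len(mat.col_ids) < 3:
        raise ValidationError("correlation requires at least 3 arrays")
    mat = _drop_zero_variance(mat)
    r = np.corrcoef(mat.values)
    r = np.clip(r, -1.0, 1.0)
    return r, list(mat.row_ids)


def pcc_threshold(mat: ExpressionMatrix, cfg: PCCConfig) -> float:
    """Empirical-FDR significance threshold on |r|.

    Each permutation shuffles every gene's values independently,
    destroying all between-gene dependence while keeping the marginals;
    |r| values from all permutations form the pooled null.  The threshold
    is the smallest t with
    ``(expected null pairs >= t) / (observed pairs >= t) <= fdr_level``,
    or 1.0 (empty network) when no t qualifies.
    """
    rng = np.random.default_rng(cfg.seed)
    mat = _drop_zero_variance(mat)
    r, _ = pcc_all_pairs(mat)
    iu = np.triu_indices(r.shape[0], k=1)
    obs = np.sort(np.abs(r[iu]))
    null = []
    vals = mat.values
    for _ in range(cfg.permutations):
        perm = np.array([rng.permutation(row) for row in vals])
        rn = np.corrcoef(perm)
        null.append(np.abs(rn[iu]))
    null = np.sort(np.concatenate(null))
    # candidate thresholds: 0 and every observed |r|
    candidates = np.concatenate([[0.0], obs])
    n_obs_ge = obs.size - np.searchsorted(obs, candidates, side="left")
    n_null_ge = null.size - np.searchsorted(null, candidates, side="left")
    expected = n_null_ge / cfg.permutations
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(n_obs_ge > 0, expected / np.maximum(n_obs_ge, 1), np.inf)
    ok = np.flatnonzero(fdr <= cfg.fdr_level)
    if ok.size == 0:
        warnings.warn("no threshold achieves the requested FDR; returning 1.0")
        return 1.0
    return float(candidates[ok[0]])


def pcc_network(
    mat: ExpressionMatrix, cfg: PCCConfig, provenance: str = "complete"
) -> GeneNetwork:
    """PCC network: edges where |r| reaches the empirical-FDR threshold."""
    t = pcc_threshold(mat, cfg)
    r, genes = pcc_all_pairs(mat)
    iu = np.triu_indices(len(genes), k=1)
    edges = [
        (genes[i], genes[j], float(r[i, j]))
        for i, j in zip(*iu)
        if abs(r[i, j]) >= t
    ]
    return GeneNetwork.from_edges(edges, Method.PCC, vertices=genes,
                                  provenance=provenance)


# ---------------------------------------------------------------------------
# B-spline mutual information
# ---------------------------------------------------------------------------

def _bspline_knots(n_bins: int, order: int) -> np.ndarray:
    """Clamped uniform knot vector on [0, n_bins − order + 1]."""
    interior = np.arange(1, n_bins - order + 1, dtype=float)
    tmax = float(n_bins - order + 1)
    return np.concatenate([
        np.zeros(order), interior, np.full(order, tmax)
    ])


def bspline_weights(u: np.ndarray, n_bins: int, order: int) -> np.ndarray:
    """Fractional bin memberships for samples ``u`` in [0, 1].

    Evaluates all ``n_bins`` B-spline basis functions of the given order
    (order = degree + 1, so order 1 is hard binning) on the clamped
    uniform knot vector, by the Cox–de Boor recursion.  Rows sum to 1.
    """
    u = np.asarray(u, float)
    if (u < 0).any() or (u > 1).any():
        raise ValueError("samples must be scaled to [0, 1]")
    t = _bspline_knots(n_bins, order)
    tmax = t[-1]
    z = u * tmax
    # degree 0: indicator of the half-open knot span, right-closed at the end
    n_knots = t.size
    b = np.zeros((z.size, n_knots - 1))
    for i in range(n_knots - 1):
        if t[i + 1] > t[i]:
            b[:, i] = (z >= t[i]) & (z < t[i + 1])
    b[z == tmax, np.max(np.flatnonzero(np.diff(t) > 0))] = 1.0
    for k in range(1, order):
        nb = np.zeros((z.size, n_knots - 1 - k))
        for i in range(n_knots - 1 - k):
            left = np.zeros(z.size)
            if t[i + k] > t[i]:
                left = (z - t[i]) / (t[i + k] - t[i]) * b[:, i]
            right = np.zeros(z.size)
            if t[i + k + 1] > t[i + 1]:
                right = (t[i + k + 1] - z) / (t[i + k + 1] - t[i + 1]) * b[:, i + 1]
            nb[:, i] = left + right
        b = nb
    return b


def _rank_scale(x: np.ndarray) -> np.ndarray:
    """Map values to [0, 1] by average ranks (ties share a rank)."""
    n = x.size
    if n < 2:
        return np.zeros(n)
    return (rankdata(x, method="average") - 1.0) / (n - 1.0)


def _mi_from_weights(wx: np.ndarray, wy: np.ndarray) -> float:
    """Plug-in MI (nats) from two fractional-binning weight matrices."""
    n = wx.shape[0]
    pxy = wx.T @ wy / n
    px = wx.mean(axis=0)
    py = wy.mean(axis=0)
    mask = pxy > 0
    outer = px[:, None] * py[None, :]
    mi = float(np.sum(pxy[mask] * np.log(pxy[mask] / outer[mask])))
    return max(mi, 0.0)


def weighted_entropy(w: np.ndarray) -> float:
    """Entropy (nats) of the weighted marginal histogram."""
    p = w.mean(axis=0)
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)))


def bspline_mi(
    x: np.ndarray, y: np.ndarray, cfg: MIEstimatorConfig | None = None
) -> float:
    """Mutual information between two samples, in nats."""
    cfg = cfg or MIEstimatorConfig(seed=0)
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 20:
        raise ValueError("need at least 20 samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant vector: MI is 0")
        return 0.0
    wx = bspline_weights(_rank_scale(x), cfg.n_bins, cfg.spline_order)
    wy = bspline_weights(_rank_scale(y), cfg.n_bins, cfg.spline_order)
    return _mi_from_weights(wx, wy)


def _all_weights(mat: ExpressionMatrix, cfg: MIEstimatorConfig) -> np.ndarray:
    return np.stack([
        bspline_weights(_rank_scale(row), cfg.n_bins, cfg.spline_order)
        for row in mat.values
    ])


def mi_threshold(
    weights: np.ndarray, cfg: MIEstimatorConfig, rng: np.random.Generator
) -> float:
    """(1 − significance_level) quantile of MI from permuted gene pairs."""
    G, n, _ = weights.shape
    null = np.empty(cfg.permutations)
    for k in range(cfg.permutations):
        i, j = rng.integers(0, G, 2)
        perm = rng.permutation(n)
        null[k] = _mi_from_weights(weights[i][perm], weights[j])
    return float(np.quantile(null, 1.0 - cfg.significance_level))


def mi_network(
    mat: ExpressionMatrix, cfg: MIEstimatorConfig, provenance: str = "complete",
    apply_dpi: bool = True,
) -> GeneNetwork:
    """MI network with a pooled-null global threshold and optional DPI."""
    if len(mat.row_ids) < 2:
        raise ValidationError("need at least 2 genes")
    mat = _drop_zero_variance(mat)
    rng = np.random.default_rng(cfg.seed)
    weights = _all_weights(mat, cfg)
    if cfg.significance_level >= 1.0:
        threshold = -np.inf  # degenerate: every pair is an edge
    else:
        threshold = mi_threshold(weights, cfg, rng)
    genes = mat.row_ids
    edges = []
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            mi = _mi_from_weights(weights[i], weights[j])
            if mi > threshold:
                edges.append((genes[i], genes[j], mi))
    net = GeneNetwork.from_edges(edges, Method.MI, vertices=genes,
                                 provenance=provenance)
    if apply_dpi:
        net = dpi_prune(net, cfg.dpi_tolerance)
    return net


# ---------------------------------------------------------------------------
# DPI, unions, stats
# ---------------------------------------------------------------------------

def dpi_prune(net: GeneNetwork, tolerance: float = 0.0) -> GeneNetwork:
    """Remove the strictly weakest edge of every triangle (one pass).

    An edge is removed when its score is below ``(1 − tolerance)`` times
    the minimum of the other two edges of some triangle, judged against
    the original scores, so the outcome is independent of traversal order.
    Equal-score triangles have no strict minimum and lose nothing.
    """
    if not 0.0 <= tolerance <= 1.0:
        raise ConfigError("tolerance must be in [0, 1]")
    g = net.graph
    score = {tuple(sorted(e)): d["score"] for *e, d in g.edges(data=True)}
    to_remove: set[tuple[str, str]] = set()
    for u, v in g.edges():
        for w in set(g[u]) & set(g[v]):
            trio = [tuple(sorted((u, v))), tuple(sorted((u, w))),
                    tuple(sorted((v, w)))]
            scores = [score[e] for e in trio]
            smin = min(scores)
            if scores.count(smin) > 1:
                continue  # no strictly weakest edge
            weakest = trio[scores.index(smin)]
            second = min(s for e, s in zip(trio, scores) if e != weakest)
            if smin < second * (1.0 - tolerance):
                to_remove.add(weakest)
    pruned = g.copy()
    pruned.remove_edges_from(to_remove)
    return GeneNetwork(pruned, net.method, net.provenance)


def union_networks(nets: list[GeneNetwork]) -> GeneNetwork:
    """Set union of vertices and edges; duplicate edges keep the max score."""
    if not nets:
        raise ValueError("no networks to union")
    methods = {n.method for n in nets}
    if len(methods) > 1:
        raise ValidationError(f"mixed method tags: {sorted(m.value for m in methods)}")
    out = GeneNetwork.from_edges([], methods.pop(), provenance="union")
    for n in nets:
        out.graph.add_nodes_from(n.graph.nodes())
        for u, v, d in n.graph.edges(data=True):
            if out.graph.has_edge(u, v):
                out.graph[u][v]["score"] = max(out.graph[u][v]["score"], d["score"])
            else:
                out.graph.add_edge(u, v, score=d["score"])
    return out


def network_stats(net: GeneNetwork) -> dict[str, int]:
    """Vertex/edge counts; "genes in network" means non-isolated vertices."""
    return {
        "vertices": net.n_vertices,
        "nonisolated_vertices": net.n_nonisolated,
        "edges": net.n_edges,
    }
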