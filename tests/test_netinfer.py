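"""PCC and B-spline MI networks, permutation thresholds, DPI, unions."""

import itertools

import numpy as np
import pytest

from coexpipe.core import ExpressionMatrix, GeneNetwork, Method, Space, ValidationError
from coexpipe.netinfer import (
    ConfigError,
    MIEstimatorConfig,
    PCCConfig,
    _bspline_knots,
    _mi_from_weights,
    _rank_scale,
    bspline_mi,
    bspline_weights,
    dpi_prune,
    mi_network,
    network_stats,
    pcc_all_pairs,
    pcc_network,
    pcc_threshold,
    union_networks,
    weighted_entropy,
)


def _mat(values, space=Space.NORMALIZED):
    values = np.asarray(values, float)
    return ExpressionMatrix(values, [f"g{i}" for i in range(values.shape[0])],
                            [f"a{j}" for j in range(values.shape[1])], space)


class TestConfigs:
    def test_seed_mandatory(self):
        with pytest.raises(ConfigError):
            MIEstimatorConfig()
        with pytest.raises(ConfigError):
            PCCConfig()

    def test_order_vs_bins(self):
        with pytest.raises(ConfigError):
            MIEstimatorConfig(n_bins=2, spline_order=3, seed=0)

    def test_min_permutations(self):
        with pytest.raises(ConfigError):
            MIEstimatorConfig(permutations=10, seed=0)
        with pytest.raises(ConfigError):
            PCCConfig(permutations=5, seed=0)


class TestPCC:
    def test_perfect_linear_pairs(self):
        x = np.arange(10.0)
        r, genes = pcc_all_pairs(_mat([x, 2 * x, -x]))
        assert r[0, 1] == pytest.approx(1.0)
        assert r[0, 2] == pytest.approx(-1.0)
        assert np.allclose(np.diag(r), 1.0)
        assert np.allclose(r, r.T)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(10, 25))
        r, genes = pcc_all_pairs(_mat(vals))
        for i, j in itertools.combinations(range(10), 2):
            x, y = vals[i], vals[j]
            cov = ((x - x.mean()) * (y - y.mean())).mean()
            ref = cov / (x.std() * y.std())
            assert r[i, j] == pytest.approx(ref, abs=1e-12)

    def test_zero_variance_gene_excluded(self):
        vals = np.vstack([np.arange(5.0), np.full(5, 3.0)])
        with pytest.warns(UserWarning):
            r, genes = pcc_all_pairs(_mat(vals))
        assert genes == ["g0"]

    def test_fdr_one_gives_zero_threshold(self):
        rng = np.random.default_rng(1)
        m = _mat(rng.normal(size=(6, 30)))
        t = pcc_threshold(m, PCCConfig(fdr_level=1.0, seed=2))
        assert t == 0.0

    def test_planted_strong_pair_survives(self):
        rng = np.random.default_rng(3)
        n = 120
        x = rng.standard_normal(n)
        y = 0.95 * x + np.sqrt(1 - 0.95**2) * rng.standard_normal(n)
        vals = np.vstack([x, y, rng.standard_normal((8, n))])
        net = pcc_network(_mat(vals), PCCConfig(seed=4))
        assert ("g0", "g1") in net.edge_set()

    def test_independent_genes_nearly_empty_network(self):
        total_edges = 0
        total_pairs = 0
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            m = _mat(rng.standard_normal((12, 200)))
            net = pcc_network(m, PCCConfig(fdr_level=0.01, seed=seed))
            total_edges += net.n_edges
            total_pairs += 66
        assert total_edges <= 0.01 * total_pairs * 2 + 1


class TestBsplineBasis:
    @pytest.mark.parametrize("n_bins,order", [(10, 3), (5, 2), (10, 1), (6, 4)])
    def test_matches_scipy_design_matrix(self, n_bins, order):
        from scipy.interpolate import BSpline
        rng = np.random.default_rng(5)
        u = rng.random(300)
        ours = bspline_weights(u, n_bins, order)
        t = _bspline_knots(n_bins, order)
        ref = BSpline.design_matrix(u * t[-1], t, order - 1).toarray()
        np.testing.assert_allclose(ours, ref, atol=1e-12)

    def test_rows_sum_to_one_including_endpoints(self):
        u = np.array([0.0, 0.25, 0.5, 0.75, 1.0])
        w = bspline_weights(u, 10, 3)
        np.testing.assert_allclose(w.sum(axis=1), 1.0, atol=1e-12)
        assert w[0, 0] == pytest.approx(1.0)   # left endpoint in first bin
        assert w[-1, -1] == pytest.approx(1.0)  # right endpoint in last bin


class TestBsplineMI:
    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal(500)
        y = x**2 + 0.3 * rng.standard_normal(500)
        cfg = MIEstimatorConfig(seed=0)
        base = bspline_mi(x, y, cfg)
        assert abs(bspline_mi(np.exp(x), y, cfg) - base) < 1e-9
        assert abs(bspline_mi(x, np.sign(y) * np.abs(y) ** 3, cfg) - base) < 1e-9

    def test_independent_mi_below_own_null_tail(self):
        rng = np.random.default_rng(7)
        n = 1000
        x, y = rng.random(n), rng.random(n)
        cfg = MIEstimatorConfig(seed=0)
        mi = bspline_mi(x, y, cfg)
        null = [bspline_mi(rng.permutation(x), y, cfg) for _ in range(60)]
        assert mi < np.quantile(null, 0.95) + 0.02

    def test_self_mi_is_pairwise_maximum(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal(800)
        others = [0.9 * x + 0.44 * rng.standard_normal(800),
                  rng.standard_normal(800)]
        cfg = MIEstimatorConfig(seed=0)
        self_mi = bspline_mi(x, x, cfg)
        assert all(self_mi > bspline_mi(x, y, cfg) for y in others)

    def test_self_mi_equals_entropy_under_hard_binning(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal(500)
        w = bspline_weights(_rank_scale(x), 10, 1)
        assert _mi_from_weights(w, w) == pytest.approx(weighted_entropy(w), abs=1e-12)

    def test_constant_vector_gives_zero(self):
        with pytest.warns(UserWarning):
            assert bspline_mi(np.ones(50), np.arange(50.0)) == 0.0

    def test_length_checks(self):
        with pytest.raises(ValueError):
            bspline_mi(np.arange(30.0), np.arange(29.0))
        with pytest.raises(ValueError):
            bspline_mi(np.arange(10.0), np.arange(10.0))


class TestMINetwork:
    def test_significance_one_gives_complete_graph(self):
        rng = np.random.default_rng(10)
        m = _mat(rng.standard_normal((5, 40)))
        net = mi_network(m, MIEstimatorConfig(significance_level=1.0, seed=0),
                         apply_dpi=False)
        assert net.n_edges == 10

    def test_too_few_genes(self):
        with pytest.raises(ValidationError):
            mi_network(_mat(np.random.default_rng(0).random((1, 40))),
                       MIEstimatorConfig(seed=0))

    def test_independent_genes_sparse(self):
        total_edges, total_pairs = 0, 0
        for seed in range(5):
            rng = np.random.default_rng(200 + seed)
            m = _mat(rng.standard_normal((10, 150)))
            net = mi_network(m, MIEstimatorConfig(seed=seed), apply_dpi=False)
            total_edges += net.n_edges
            total_pairs += 45
        assert total_edges <= 0.01 * total_pairs * 2 + 2

    def test_quadratic_relation_found_by_mi_not_pcc(self):
        rng = np.random.default_rng(11)
        n = 300
        x = rng.standard_normal(n)
        y = x**2 + 0.2 * rng.standard_normal(n)
        vals = np.vstack([x, y, rng.standard_normal((8, n))])
        m = _mat(vals)
        minet = mi_network(m, MIEstimatorConfig(seed=12))
        assert ("g0", "g1") in minet.edge_set()
        pnet = pcc_network(m, PCCConfig(seed=12))
        assert ("g0", "g1") not in pnet.edge_set()


def _dpi_oracle(net: GeneNetwork, tolerance: float) -> set:
    """Enumerate all triangles; mark strictly weakest edges below bound."""
    scores = net.edge_set()
    removed = set()
    for trio in itertools.combinations(sorted(net.vertices), 3):
        edges = [tuple(sorted(p)) for p in itertools.combinations(trio, 2)]
        if not all(e in scores for e in edges):
            continue
        vals = [scores[e] for e in edges]
        smin = min(vals)
        if vals.count(smin) > 1:
            continue
        weakest = edges[vals.index(smin)]
        second = min(v for e, v in zip(edges, vals) if e != weakest)
        if smin < second * (1 - tolerance):
            removed.add(weakest)
    return removed


class TestDPI:
    def test_weakest_triangle_edge_removed(self):
        net = GeneNetwork.from_edges(
            [("X", "Y", 0.8), ("Y", "Z", 0.7), ("X", "Z", 0.2)], Method.MI)
        out = dpi_prune(net, 0.0)
        assert set(out.edge_set()) == {("X", "Y"), ("Y", "Z")}

    def test_equal_scores_untouched(self):
        net = GeneNetwork.from_edges(
            [("X", "Y", 0.5), ("Y", "Z", 0.5), ("X", "Z", 0.5)], Method.MI)
        assert dpi_prune(net, 0.0).n_edges == 3

    def test_tolerance_spares_near_ties(self):
        net = GeneNetwork.from_edges(
            [("X", "Y", 0.8), ("Y", "Z", 0.7), ("X", "Z", 0.65)], Method.MI)
        assert dpi_prune(net, 0.1).n_edges == 3
        assert dpi_prune(net, 0.0).n_edges == 2

    def test_global_max_edge_survives_and_removals_are_triangle_minima(self):
        # an edge strongest in one triangle can still be the strict minimum
        # of another and be removed there; the guarantees are that the
        # network-wide maximum edge survives and that every removed edge was
        # the strict minimum of at least one triangle
        rng = np.random.default_rng(13)
        for _ in range(5):
            net = _random_network(rng)
            out = dpi_prune(net, 0.0)
            scores = net.edge_set()
            if scores:
                global_max = max(scores, key=scores.get)
                assert global_max in out.edge_set()
            removed = set(scores) - set(out.edge_set())
            assert removed <= _dpi_oracle(net, 0.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_bruteforce_on_random_graphs(self, seed):
        rng = np.random.default_rng(1000 + seed)
        net = _random_network(rng)
        out = dpi_prune(net, 0.0)
        expected = set(net.edge_set()) - _dpi_oracle(net, 0.0)
        assert set(out.edge_set()) == expected


def _random_network(rng, n=8, p=0.5) -> GeneNetwork:
    genes = [f"g{i}" for i in range(n)]
    edges = [
        (a, b, float(rng.uniform(0.05, 1.0)))
        for a, b in itertools.combinations(genes, 2)
        if rng.random() < p
    ]
    return GeneNetwork.from_edges(edges, Method.MI, vertices=genes)


class TestUnionAndStats:
    def test_union_basic(self):
        n1 = GeneNetwork.from_edges([("A", "B", 0.5)], Method.PCC)
        n2 = GeneNetwork.from_edges([("B", "C", 0.6)], Method.PCC)
        u = union_networks([n1, n2])
        assert u.vertices == {"A", "B", "C"} and u.n_edges == 2
        assert u.provenance == "union"

    def test_union_idempotent(self):
        n = GeneNetwork.from_edges([("A", "B", 0.5)], Method.MI, vertices=["A", "B", "C"])
        assert union_networks([n, n]) == n or union_networks([n, n]).vertices == n.vertices

    def test_duplicate_edge_keeps_max_score(self):
        n1 = GeneNetwork.from_edges([("A", "B", 0.5)], Method.MI)
        n2 = GeneNetwork.from_edges([("A", "B", 0.7)], Method.MI)
        assert union_networks([n1, n2]).edge_set()[("A", "B")] == 0.7

    def test_mixed_methods_rejected(self):
        n1 = GeneNetwork.from_edges([("A", "B", 0.5)], Method.MI)
        n2 = GeneNetwork.from_edges([("A", "B", 0.5)], Method.PCC)
        with pytest.raises(ValidationError):
            union_networks([n1, n2])

    def test_union_is_superset_of_constituents(self):
        rng = np.random.default_rng(14)
        nets = [_random_network(rng, n=6) for _ in range(3)]
        u = union_networks(nets)
        for n in nets:
            assert n.vertices <= u.vertices
            assert set(n.edge_set()) <= set(u.edge_set())
        assert u.n_vertices <= sum(n.n_vertices for n in nets)

    def test_stats_counts(self):
        net = GeneNetwork.from_edges([("A", "B", 1.0), ("B", "C", 1.0)],
                                     Method.MI, vertices=["A", "B", "C", "D"])
        s = network_stats(net)
        assert s == {"vertices": 4, "nonisolated_vertices": 3, "edges": 2}
        empty = GeneNetwork.from_edges([], Method.MI)
        assert network_stats(empty) == {"vertices": 0, "nonisolated_vertices": 0,
                                        "edges": 0}

    def test_disjoint_union_edge_additivity(self):
        n1 = GeneNetwork.from_edges([("A", "B", 1.0), ("B", "C", 1.0)], Method.MI)
        n2 = GeneNetwork.from_edges([("D", "E", 1.0), ("E", "F", 1.0)], Method.MI)
        assert union_networks([n1, n2]).n_edges == 4
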