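"""Duplicate detection, scale-factor/spike-in rules, probe-level model QC."""

import numpy as np
import pytest

from coexpipe.core import ExpressionMatrix, Space, ValidationError
from coexpipe.dedup_qc import (
    QCReport,
    compute_scale_factors,
    detect_spikeins,
    filter_scale_and_spikein,
    find_exact_duplicates,
    fit_probe_level_model,
    mark_duplicates,
    match_descriptions,
    median_polish,
    qc_outliers,
)
from conftest import make_submission


class TestExactDuplicates:
    def test_identical_columns_reported_once(self):
        subs = [
            make_submission("S1", ["a1"], hashes={"a1": "h1"}),
            make_submission("S2", ["a2"], hashes={"a2": "h1"}),
        ]
        assert find_exact_duplicates(subs) == [("a1", "a2")]

    def test_no_collisions(self):
        subs = [make_submission("S1", ["a1", "a2"],
                                hashes={"a1": "h1", "a2": "h2"})]
        assert find_exact_duplicates(subs) == []

    def test_missing_hash_rejected(self):
        subs = [make_submission("S1", ["a1"])]
        with pytest.raises(ValidationError):
            find_exact_duplicates(subs)

    def test_truth_pairs_recovered_exactly(self, small_compendium):
        cfg, (mat, subs, ann, truth) = small_compendium
        found = find_exact_duplicates(subs)
        assert sorted(found) == sorted(truth.duplicate_pairs)  # recall & precision 1

    def test_idempotent_after_removal(self, small_compendium):
        _, (mat, subs, ann, truth) = small_compendium
        dups = {d for _, d in find_exact_duplicates(subs)}
        remaining = []
        for s in subs:
            arrays = [a for a in s.array_ids if a not in dups]
            if arrays:
                remaining.append(
                    make_submission(s.submission_id, arrays,
                                    hashes={a: s.content_hashes[a] for a in arrays})
                )
        assert find_exact_duplicates(remaining) == []


class TestDescriptionMatching:
    def test_identical_descriptions_auto_flagged(self):
        subs = [make_submission("S1", ["a"], "drought stress leaves"),
                make_submission("S2", ["b"], "drought stress leaves")]
        auto, flagged = match_descriptions(subs)
        assert auto == [("S1", "S2")]

    def test_nine_of_ten_shared_tokens_flagged(self):
        t = "one two three four five six seven eight nine"
        subs = [make_submission("S1", ["a"], t + " ten"),
                make_submission("S2", ["b"], t + " eleven")]
        auto, flagged = match_descriptions(subs, similarity_cutoff=0.8)
        assert auto == []
        assert len(flagged) == 1
        assert flagged[0][2] == pytest.approx(9 / 11)

    def test_disjoint_descriptions_silent(self):
        subs = [make_submission("S1", ["a"], "alpha beta"),
                make_submission("S2", ["b"], "gamma delta")]
        assert match_descriptions(subs) == ([], [])

    def test_empty_descriptions_silent(self):
        subs = [make_submission("S1", ["a"], ""),
                make_submission("S2", ["b"], "")]
        assert match_descriptions(subs) == ([], [])


class TestScaleFactors:
    def _col(self, *values):
        vals = np.array(values, float).reshape(-1, 1)
        return ExpressionMatrix(vals, [f"g{i}" for i in range(len(values))],
                                ["a"], Space.RAW)

    def test_trimmed_mean_500_gives_factor_2(self):
        m = self._col(*([500.0] * 10))
        assert compute_scale_factors(m)["a"] == pytest.approx(2.0)

    def test_trimmed_mean_1000_gives_factor_1(self):
        m = self._col(*([1000.0] * 10))
        assert compute_scale_factors(m)["a"] == pytest.approx(1.0)

    def test_zero_column_reported_none(self):
        m = self._col(*([0.0] * 10))
        assert compute_scale_factors(m)["a"] is None

    def test_three_times_mean_rule(self):
        subs = [make_submission("S1", [f"a{i}" for i in range(10)])]
        factors = {f"a{i}": 1.0 for i in range(9)} | {"a9": 4.0}
        rep = filter_scale_and_spikein(subs, factors, {})
        # mean 1.3, threshold 3.9: the 4.0 array fails, others pass
        assert rep.records["a9"].verdict == "fail_scale"
        assert all(rep.records[f"a{i}"].verdict == "pass" for i in range(9))

    def test_three_times_mean_rule_no_failures(self):
        subs = [make_submission("S1", ["a0", "a1", "a2"])]
        factors = {"a0": 1.0, "a1": 1.0, "a2": 2.0}
        rep = filter_scale_and_spikein(subs, factors, {})
        assert rep.failed() == []

    def test_single_array_submission_cannot_fail_scale(self):
        subs = [make_submission("S1", ["a0"])]
        rep = filter_scale_and_spikein(subs, {"a0": 50.0}, {})
        assert rep.records["a0"].verdict == "pass"

    def test_absent_spikein_fails_regardless(self):
        subs = [make_submission("S1", ["a0", "a1"])]
        rep = filter_scale_and_spikein(subs, {"a0": 1.0, "a1": 1.0},
                                       {"a0": False, "a1": True})
        assert rep.records["a0"].verdict == "fail_spikein"
        assert rep.records["a1"].verdict == "pass"

    def test_spikein_detection_on_controls(self, small_compendium):
        from coexpipe.normalize import summarize_probesets
        _, (mat, subs, ann, truth) = small_compendium
        ps = summarize_probesets(mat)
        flags = detect_spikeins(ps)
        for a in truth.spikein_absent_arrays:
            assert flags[a] is False
        ok = [a for a in mat.col_ids if a not in truth.spikein_absent_arrays
              and not any(a == d for _, d in truth.duplicate_pairs)]
        assert all(flags[a] for a in ok)


def _polish_oracle(table, iters=100):
    """Plain iterative row/column median sweep."""
    t = np.array(table, float)
    overall, row, col = 0.0, np.zeros(t.shape[0]), np.zeros(t.shape[1])
    for _ in range(iters):
        rm = np.median(t, axis=1)
        t -= rm[:, None]
        row += rm
        d = np.median(row)
        row -= d
        overall += d
        cm = np.median(t, axis=0)
        t -= cm[None, :]
        col += cm
        d = np.median(col)
        col -= d
        overall += d
    return overall, row, col, t


class TestMedianPolish:
    @pytest.mark.parametrize("shape,seed", [((2, 3), 0), ((3, 4), 1),
                                            ((5, 5), 2), ((4, 2), 3)])
    def test_matches_sweep_oracle(self, shape, seed):
        rng = np.random.default_rng(seed)
        table = rng.normal(5, 1, shape)
        o, r, c, resid = median_polish(table, max_iter=100)
        oo, ro, co, rr = _polish_oracle(table)
        assert o == pytest.approx(oo, abs=1e-6)
        np.testing.assert_allclose(r, ro, atol=1e-6)
        np.testing.assert_allclose(c, co, atol=1e-6)
        np.testing.assert_allclose(resid, rr, atol=1e-6)

    def test_reconstruction_identity(self):
        rng = np.random.default_rng(4)
        table = rng.normal(0, 1, (3, 5))
        o, r, c, resid = median_polish(table)
        np.testing.assert_allclose(
            o + r[:, None] + c[None, :] + resid, table, atol=1e-12
        )

    def test_stacked_matches_individual(self):
        rng = np.random.default_rng(5)
        stack = rng.normal(0, 1, (4, 3, 6))
        o, r, c, resid = median_polish(stack)
        for k in range(4):
            ok, rk, ck, residk = median_polish(stack[k])
            assert o[k] == pytest.approx(ok, abs=1e-12)
            np.testing.assert_allclose(c[k], ck, atol=1e-12)


def _probe_matrix(values, n_probes, space=Space.LOG2):
    values = np.asarray(values, float)
    rows = [f"PS{i}_p{p}" for i in range(values.shape[0] // n_probes)
            for p in range(n_probes)]
    cols = [f"a{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(values, rows, cols, space)


class TestProbeLevelModel:
    def test_identical_columns_give_rle_zero_nuse_one(self):
        probes = np.array([[5.0], [6.0], [7.0]]) @ np.ones((1, 4))
        mat = _probe_matrix(probes, 3)
        rle, nuse, ps = fit_probe_level_model(mat)
        np.testing.assert_allclose(rle, 0.0, atol=1e-12)
        np.testing.assert_allclose(nuse, 1.0, atol=1e-12)

    def test_global_shift_moves_rle_median(self):
        rng = np.random.default_rng(6)
        base = rng.normal(8, 1, (60, 1)) + 0.3 * rng.standard_normal((60, 10))
        base[:, 3] += 1.0  # one array shifted by +1 log2
        mat = _probe_matrix(base, 3)
        rle, nuse, ps = fit_probe_level_model(mat)
        assert np.median(rle[:, 3]) == pytest.approx(1.0, abs=0.15)
        others = np.median(rle[:, [j for j in range(10) if j != 3]], axis=0)
        assert np.abs(others).max() < 0.15

    def test_verdicts_invariant_to_row_and_column_order(self):
        rng = np.random.default_rng(7)
        vals = rng.normal(7, 1, (30, 6))
        mat = _probe_matrix(vals, 3)
        rle, nuse, _ = fit_probe_level_model(mat)
        rep = qc_outliers(rle, nuse, mat.col_ids)
        perm_rows = rng.permutation(vals.shape[0])
        perm_cols = rng.permutation(6)
        mat2 = ExpressionMatrix(vals[np.ix_(perm_rows, perm_cols)],
                                [mat.row_ids[i] for i in perm_rows],
                                [mat.col_ids[j] for j in perm_cols], Space.LOG2)
        rle2, nuse2, _ = fit_probe_level_model(mat2)
        rep2 = qc_outliers(rle2, nuse2, mat2.col_ids)
        assert {a: r.verdict for a, r in rep.records.items()} == \
               {a: r.verdict for a, r in rep2.records.items()}


class TestQCOutliers:
    def _report(self, rle_med, rle_iqr, nuse_med, nuse_iqr):
        # craft per-array RLE/NUSE distributions with given stats
        n = 201
        half = (n - 1) // 2
        spread = np.linspace(-1, 1, n)
        rle = (rle_med + spread * rle_iqr).reshape(-1, 1)
        nuse = (nuse_med + spread * nuse_iqr).reshape(-1, 1)
        return qc_outliers(rle, nuse, ["a"])

    def test_centered_tight_array_passes(self):
        rep = self._report(0.0, 0.2, 1.0, 0.1)
        assert rep.records["a"].verdict == "pass"

    def test_rle_median_above_threshold_fails(self):
        rep = self._report(0.10, 0.2, 1.0, 0.1)
        assert rep.records["a"].verdict == "fail_rle"

    def test_rle_iqr_above_threshold_fails(self):
        rep = self._report(0.0, 2.0, 1.0, 0.1)
        assert rep.records["a"].verdict == "fail_rle"

    def test_nuse_median_deviation_fails(self):
        rep = self._report(0.0, 0.2, 1.2, 0.1)
        assert rep.records["a"].verdict == "fail_nuse"

    def test_synthetic_outliers_flagged_clean_arrays_pass(self, small_compendium):
        cfg, (mat, subs, ann, truth) = small_compendium
        log = mat.with_values(np.log2(np.maximum(mat.values, 1e-9)), Space.LOG2)
        rle, nuse, _ = fit_probe_level_model(log, subs)
        rep = qc_outliers(rle, nuse, mat.col_ids)
        flagged = set(rep.failed())
        assert truth.outlier_array_ids <= flagged
        copies = {d for _, d in truth.duplicate_pairs}
        for s in subs:  # near-duplicate copies inherit their source's defects
            if any(s.submission_id == nd for _, nd in truth.near_duplicate_submissions):
                copies.update(s.array_ids)
        clean = (set(mat.col_ids) - truth.outlier_array_ids
                 - copies - truth.spikein_absent_arrays)
        assert flagged & clean == set()


def test_mark_duplicates_sets_verdict():
    rep = QCReport()
    mark_duplicates(rep, [("a1", "a2")])
    assert rep.records["a2"].verdict == "duplicate"
    assert "a1" not in rep.records or rep.records["a1"].verdict == "pass"
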