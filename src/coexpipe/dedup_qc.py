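"""Duplicate removal and array-level quality control.

Duplicate arrays are detected through MD5 digests of the raw column bytes;
near-duplicate submissions through exact and token-set-similar description
matching (similar descriptions are flagged for review, never auto-removed).

Array QC applies four rules:

* scale factor more than 3x its submission's mean scale factor;
* no detectable spike-in controls;
* RLE (relative log expression) per-array distribution off-center (|median|
  above 0.075) or too spread (IQR above 0.75);
* NUSE (normalized unscaled standard error) median away from 1 by more than
  0.075 or IQR above 0.75.

RLE/NUSE come from a probe-level model — a two-way additive model (probe
affinity + array effect) fitted per probe-set by median polish, within each
submission separately, since arrays are only comparable to their own
submission's replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .core import ExpressionMatrix, Space, SubmissionRecord, ValidationError

RLE_NUSE_IQR_MAX = 0.75
CENTER_DEVIATION_MAX = 0.075
SCALE_FACTOR_MULTIPLIER = 3.0


@dataclass
class QCRecord:
    array_id: str
    scale_factor: float | None = None
    spikein_present: bool | None = None
    rle_median: float | None = None
    rle_iqr: float | None = None
    nuse_median: float | None = None
    nuse_iqr: float | None = None
    verdict: str = "pass"  # pass|fail_scale|fail_spikein|fail_rle|fail_nuse|duplicate|excluded


@dataclass
class QCReport:
    records: dict[str, QCRecord] = field(default_factory=dict)

    def record(self, array_id: str) -> QCRecord:
        if array_id not in self.records:
            self.records[array_id] = QCRecord(array_id)
        return self.records[array_id]

    def failed(self) -> list[str]:
        return [a for a, r in self.records.items() if r.verdict != "pass"]

    def passed(self) -> list[str]:
        return [a for a, r in self.records.items() if r.verdict == "pass"]

    def to_rows(self) -> list[dict]:
        return [vars(r).copy() for r in self.records.values()]


# ---------------------------------------------------------------------------
# duplicates
# ---------------------------------------------------------------------------

def find_exact_duplicates(
    submissions: Sequence[SubmissionRecord],
) -> list[tuple[str, str]]:
    """All pairs of arrays with identical content digests.

    Within a digest group the array from the earliest-sorted submission id
    (ties: earliest-sorted array id) is the keeper; every other member is
    reported as ``(keeper, duplicate)``.
    """
    by_digest: dict[str, list[tuple[str, str]]] = {}
    for s in submissions:
        for a in s.array_ids:
            if a not in s.content_hashes:
                raise ValidationError(
                    f"array {a!r} in submission {s.submission_id!r} has no content hash"
                )
            by_digest.setdefault(s.content_hashes[a], []).append(
                (s.submission_id, a)
            )
    pairs: list[tuple[str, str]] = []
    for members in by_digest.values():
        if len(members) < 2:
            continue
        members = sorted(members)
        keeper = members[0][1]
        pairs.extend((keeper, a) for _, a in members[1:])
    return sorted(pairs)


def _tokens(text: str) -> frozenset[str]:
    return frozenset(t for t in "".join(
        c.lower() if c.isalnum() else " " for c in text
    ).split() if t)


def match_descriptions(
    submissions: Sequence[SubmissionRecord], similarity_cutoff: float = 0.8
) -> tuple[list[tuple[str, str]], list[tuple[str, str, float]]]:
    """Exact and near-matching submission descriptions.

    Returns ``(auto_duplicates, flagged)``: pairs with byte-identical
    non-empty descriptions, and pairs whose token-set Jaccard similarity
    reaches ``similarity_cutoff`` (flagged for manual review only).
    """
    auto: list[tuple[str, str]] = []
    flagged: list[tuple[str, str, float]] = []
    subs = sorted(submissions, key=lambda s: s.submission_id)
    for i in range(len(subs)):
        for j in range(i + 1, len(subs)):
            a, b = subs[i], subs[j]
            if not a.description or not b.description:
                continue
            if a.description == b.description:
                auto.append((a.submission_id, b.submission_id))
                continue
            ta, tb = _tokens(a.description), _tokens(b.description)
            if not ta or not tb:
                continue
            jac = len(ta & tb) / len(ta | tb)
            if jac >= similarity_cutoff:
                flagged.append((a.submission_id, b.submission_id, jac))
    return auto, flagged


# ---------------------------------------------------------------------------
# scale factors and spike-ins
# ---------------------------------------------------------------------------

def trimmed_mean(x: np.ndarray, trim: float = 0.02) -> float:
    """Mean after dropping a fraction ``trim`` from each tail."""
    x = np.sort(np.asarray(x, float))
    k = int(np.floor(trim * x.size))
    if 2 * k >= x.size:
        raise ValueError("trim removes all values")
    return float(x[k: x.size - k].mean())


def compute_scale_factors(
    mat: ExpressionMatrix, target: float = 1000.0, trim: float = 0.02
) -> dict[str, float | None]:
    """Per-array multiplier bringing the trimmed mean signal to ``target``.

    An all-zero column has no defined scale factor and is reported as None.
    """
    if mat.space is not Space.RAW:
        raise ValidationError("scale factors are defined on raw intensities")
    out: dict[str, float | None] = {}
    for j, a in enumerate(mat.col_ids):
        tm = trimmed_mean(mat.values[:, j], trim)
        out[a] = (target / tm) if tm > 0 else None
    return out


def detect_spikeins(
    mat: ExpressionMatrix,
    control_prefix: str = "AFFX",
    min_log2_intensity: float = 6.0,
) -> dict[str, bool]:
    """Presence call for spike-in controls, per array.

    A control is "present" when the mean log2 intensity of the control
    probe rows exceeds ``min_log2_intensity``.  Arrays are judged by their
    control rows only; matrices without control rows report all-present.
    """
    ctrl = [i for i, r in enumerate(mat.row_ids) if r.startswith(control_prefix)]
    if not ctrl:
        return {a: True for a in mat.col_ids}
    vals = mat.values[ctrl, :]
    if mat.space is Space.RAW:
        vals = np.log2(np.maximum(vals, 1e-9))
    mean_log2 = vals.mean(axis=0)
    return {a: bool(mean_log2[j] > min_log2_intensity) for j, a in enumerate(mat.col_ids)}


def filter_scale_and_spikein(
    submissions: Sequence[SubmissionRecord],
    scale_factors: dict[str, float | None],
    spikein_flags: dict[str, bool],
    report: QCReport | None = None,
    multiplier: float = SCALE_FACTOR_MULTIPLIER,
) -> QCReport:
    """Fail arrays with extreme scale factors or absent spike-ins.

    An array fails when its scale factor exceeds ``multiplier`` times the
    mean scale factor of its submission, or when its spike-ins are absent.
    A single-array submission is its own mean and cannot fail the
    multiplier rule.
    """
    report = report or QCReport()
    for s in submissions:
        factors = [scale_factors.get(a) for a in s.array_ids]
        valid = [f for f in factors if f is not None]
        mean_f = float(np.mean(valid)) if valid else None
        for a, f in zip(s.array_ids, factors):
            rec = report.record(a)
            rec.scale_factor = f
            rec.spikein_present = spikein_flags.get(a, True)
            if rec.verdict != "pass":
                continue
            if not rec.spikein_present:
                rec.verdict = "fail_spikein"
            elif f is None:
                rec.verdict = "fail_scale"
            elif mean_f is not None and f > multiplier * mean_f:
                rec.verdict = "fail_scale"
    return report


# ---------------------------------------------------------------------------
# probe-level model: median polish, RLE, NUSE
# ---------------------------------------------------------------------------

def median_polish(
    table: np.ndarray, max_iter: int = 20, tol: float = 1e-8
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Additive two-way fit by alternating row/column median sweeps.

    ``table`` may be 2-D (rows x cols) or 3-D (stack x rows x cols); the
    3-D form fits every probe-set of a stack simultaneously.  Returns
    ``(overall, row_effects, col_effects, residuals)``.
    """
    t = np.array(table, dtype=float)
    squeeze = t.ndim == 2
    if squeeze:
        t = t[None, :, :]
    n, R, C = t.shape
    overall = np.zeros(n)
    row_eff = np.zeros((n, R))
    col_eff = np.zeros((n, C))
    for _ in range(max_iter):
        rmed = np.median(t, axis=2)
        t -= rmed[:, :, None]
        row_eff += rmed
        cmed_of_row = np.median(row_eff, axis=1)
        row_eff -= cmed_of_row[:, None]
        overall += cmed_of_row

        cmed = np.median(t, axis=1)
        t -= cmed[:, None, :]
        col_eff += cmed
        rmed_of_col = np.median(col_eff, axis=1)
        col_eff -= rmed_of_col[:, None]
        overall += rmed_of_col
        if max(np.abs(rmed).max(), np.abs(cmed).max()) < tol:
            break
    if squeeze:
        return overall[0], row_eff[0], col_eff[0], t[0]
    return overall, row_eff, col_eff, t


def _group_probesets(row_ids: Sequence[str]) -> dict[str, list[int]]:
    """Group probe row indices by probe-set id (``<set>_p<k>`` convention)."""
    groups: dict[str, list[int]] = {}
    for i, r in enumerate(row_ids):
        ps = r.rsplit("_p", 1)[0] if "_p" in r else r
        groups.setdefault(ps, []).append(i)
    return groups


def fit_probe_level_model(
    mat: ExpressionMatrix,
    submissions: Sequence[SubmissionRecord] | None = None,
    probe_map: dict[str, list[int]] | None = None,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Fit the probe-level model and return RLE and NUSE tables.

    The matrix must hold log2 probe-level values.  Within each submission
    (or globally when ``submissions`` is None) each probe-set's probes x
    arrays table is decomposed as overall + probe effect + array effect by
    median polish.  For probe-set g on array a:

    * RLE(g, a) = fitted expression (overall + array effect) minus its
      median over the submission's arrays;
    * NUSE(g, a) = unscaled standard error of the array effect divided by
      the median standard error over arrays.  A zero median SE (perfect
      fit) yields NUSE = 1 by convention.

    Returns ``(rle, nuse, probeset_ids)`` with shape
    (n_probesets, n_arrays), columns ordered as in ``mat``.
    """
    if mat.space not in (Space.LOG2, Space.LOG2_CENTERED):
        raise ValidationError("probe-level model expects log2 values")
    groups = probe_map or _group_probesets(mat.row_ids)
    ps_ids = sorted(groups)
    sizes = {len(v) for v in groups.values()}
    col_index = {a: j for j, a in enumerate(mat.col_ids)}
    if submissions is None:
        blocks = [list(range(len(mat.col_ids)))]
    else:
        blocks = [
            [col_index[a] for a in s.array_ids if a in col_index]
            for s in submissions
        ]
        blocks = [b for b in blocks if b]
    n_ps, n_arr = len(ps_ids), len(mat.col_ids)
    rle = np.full((n_ps, n_arr), np.nan)
    nuse = np.full((n_ps, n_arr), np.nan)

    for P in sorted(sizes):
        idx = [groups[ps] for ps in ps_ids if len(groups[ps]) == P]
        which = [k for k, ps in enumerate(ps_ids) if len(groups[ps]) == P]
        stack_rows = np.array(idx)  # (m, P)
        for cols in blocks:
            sub = mat.values[np.ix_(stack_rows.ravel(), cols)]
            sub = sub.reshape(len(idx), P, len(cols))
            overall, _, col_eff, resid = median_polish(sub)
            expr = overall[:, None] + col_eff  # (m, n_cols)
            rle_block = expr - np.median(expr, axis=1, keepdims=True)
            # unscaled SE of the array effect from residual spread
            if P > 1:
                se = np.sqrt(np.sum(resid**2, axis=1) / (P - 1) / P)
            else:
                # single-probe set: no residual df; flat zero SE (low confidence)
                se = np.zeros((len(idx), len(cols)))
            med_se = np.median(se, axis=1, keepdims=True)
            with np.errstate(invalid="ignore", divide="ignore"):
                nuse_block = np.where(med_se > 0, se / np.where(med_se > 0, med_se, 1.0), 1.0)
            nuse_block = np.where((med_se == 0) & (se > 0), np.inf, nuse_block)
            rle[np.ix_(which, cols)] = rle_block
            nuse[np.ix_(which, cols)] = nuse_block
    return rle, nuse, ps_ids


def qc_outliers(
    rle: np.ndarray,
    nuse: np.ndarray,
    col_ids: Sequence[str],
    report: QCReport | None = None,
    iqr_max: float = RLE_NUSE_IQR_MAX,
    center_max: float = CENTER_DEVIATION_MAX,
) -> QCReport:
    """Flag arrays whose RLE/NUSE distributions are off-center or too wide.

    An array fails when |median RLE| > ``center_max``, |median NUSE − 1| >
    ``center_max``, or either IQR exceeds ``iqr_max``.
    """
    report = report or QCReport()
    for j, a in enumerate(col_ids):
        r = rle[:, j]
        u = nuse[:, j]
        r = r[np.isfinite(r)]
        u = u[np.isfinite(u)]
        rec = report.record(a)
        rec.rle_median = float(np.median(r)) if r.size else 0.0
        q1, q3 = (np.quantile(r, [0.25, 0.75]) if r.size else (0.0, 0.0))
        rec.rle_iqr = float(q3 - q1)
        rec.nuse_median = float(np.median(u)) if u.size else 1.0
        q1, q3 = (np.quantile(u, [0.25, 0.75]) if u.size else (0.0, 0.0))
        rec.nuse_iqr = float(q3 - q1)
        if rec.verdict != "pass":
            continue
        if abs(rec.rle_median) > center_max or rec.rle_iqr > iqr_max:
            rec.verdict = "fail_rle"
        elif abs(rec.nuse_median - 1.0) > center_max or rec.nuse_iqr > iqr_max:
            rec.verdict = "fail_nuse"
    return report


def mark_duplicates(report: QCReport, pairs: Iterable[tuple[str, str]]) -> QCReport:
    for _, dup in pairs:
        report.record(dup).verdict = "duplicate"
    return report
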