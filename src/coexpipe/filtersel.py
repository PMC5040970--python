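"""Variance filtering by inter-quartile range and threshold selection.

Genes whose expression varies too little across arrays carry no usable
co-expression signal; they are removed by thresholding the per-gene IQR
(Q3 − Q1, linear-interpolation quantiles) at a threshold q.  Two selectors
for q are provided:

* **derivative minimum** — build the IQR profile (number of genes
  surviving each candidate threshold) and take the grid point where its
  first derivative is most negative, i.e. the steepest drop;
* **histogram mode** — bin the IQR values (bins anchored at 0) and take
  the center of the fullest bin, i.e. the dataset's most common IQR.

The histogram mode selects the dataset's characteristic variability and in
practice sits at or to the right of the derivative minimum, which latches
onto the steepest pile-up of low-variance genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import ExpressionMatrix


class ConfigError(ValueError):
    pass


@dataclass
class IQRProfile:
    grid: np.ndarray          # ascending thresholds (log2 units)
    survivors: np.ndarray     # genes with IQR >= grid point
    derivative: np.ndarray    # central differences, NaN at the endpoints

    def to_rows(self) -> list[tuple[float, int, float]]:
        return [
            (float(t), int(s), float(d))
            for t, s, d in zip(self.grid, self.survivors, self.derivative)
        ]


@dataclass
class IQRHistogram:
    bin_width: float
    bin_edges: np.ndarray
    counts: np.ndarray
    mode_bin_center: float


@dataclass
class FilterReport:
    q: float
    method: str
    n_input: int
    retained: list[str]
    eliminated: dict[str, float] = field(default_factory=dict)  # gene -> IQR

    @property
    def n_retained(self) -> int:
        return len(self.retained)


def gene_iqr(mat: ExpressionMatrix) -> dict[str, float]:
    """Per-gene IQR across arrays (linear-interpolation quantiles)."""
    if len(mat.col_ids) < 2:
        raise ValueError("IQR requires at least 2 arrays")
    if len(mat.col_ids) < 4:
        warnings.warn("IQR on fewer than 4 arrays is poorly determined")
    q1, q3 = np.quantile(mat.values, [0.25, 0.75], axis=1, method="linear")
    iqr = q3 - q1
    return {g: float(v) for g, v in zip(mat.row_ids, iqr)}


def build_iqr_profile(
    iqrs: dict[str, float] | np.ndarray, grid_step: float = 0.01
) -> IQRProfile:
    """Survivor counts over an ascending threshold grid starting at 0."""
    if grid_step <= 0:
        raise ConfigError("grid_step must be > 0")
    vals = np.asarray(
        list(iqrs.values()) if isinstance(iqrs, dict) else iqrs, float
    )
    if vals.size == 0:
        raise ValueError("no IQR values")
    n_steps = int(np.floor(vals.max() / grid_step)) + 2
    grid = np.arange(n_steps) * grid_step
    # survivors(t) = #{g : IQR_g >= t}; vectorized via sorted search
    s = np.sort(vals)
    survivors = vals.size - np.searchsorted(s, grid, side="left")
    deriv = np.full(grid.size, np.nan)
    if grid.size >= 3:
        deriv[1:-1] = (survivors[2:] - survivors[:-2]) / (2 * grid_step)
    return IQRProfile(grid, survivors, deriv)


def derivative_threshold(profile: IQRProfile) -> float:
    """Threshold at the steepest drop of the IQR profile.

    Ties break toward the smallest grid value; a flat profile returns the
    first interior grid point with a warning.
    """
    if profile.grid.size < 3:
        raise ValueError("profile needs at least 3 grid points")
    d = profile.derivative[1:-1]
    lo = np.nanmin(d)
    if np.nanmax(d) == lo:
        warnings.warn("flat IQR profile derivative; threshold poorly determined")
    idx = int(np.argmax(d == lo))  # first index attaining the minimum
    return float(profile.grid[1 + idx])


def histogram_threshold(
    iqrs: dict[str, float] | np.ndarray, bin_width: float = 0.025
) -> float:
    """Threshold at the center of the fullest IQR histogram bin.

    Bins are anchored at 0; ties break toward the lowest-IQR bin.
    """
    hist = iqr_histogram(iqrs, bin_width)
    return hist.mode_bin_center


def iqr_histogram(
    iqrs: dict[str, float] | np.ndarray, bin_width: float = 0.025
) -> IQRHistogram:
    if bin_width <= 0:
        raise ConfigError("bin_width must be > 0")
    vals = np.asarray(
        list(iqrs.values()) if isinstance(iqrs, dict) else iqrs, float
    )
    if vals.size == 0:
        raise ValueError("no IQR values")
    # assign bins as floor(v / width) with a tiny epsilon so a value sitting
    # exactly on a bin edge (up to float error) goes to the upper bin
    idx = np.floor(vals / bin_width + 1e-9).astype(int)
    n_bins = int(idx.max()) + 1
    edges = np.arange(n_bins + 1) * bin_width
    counts = np.bincount(idx, minlength=n_bins)
    mode = int(np.argmax(counts))  # argmax takes the first (lowest) maximal bin
    center = float((edges[mode] + edges[mode + 1]) / 2)
    return IQRHistogram(bin_width, edges, counts, center)


def apply_filter(
    mat: ExpressionMatrix, q: float, method: str = "fixed",
    iqrs: dict[str, float] | None = None,
) -> tuple[ExpressionMatrix, FilterReport]:
    """Keep genes with IQR >= q (IQR < q is eliminated)."""
    if q < 0:
        raise ConfigError("q must be >= 0")
    iqrs = iqrs if iqrs is not None else gene_iqr(mat)
    retained = [g for g in mat.row_ids if iqrs[g] >= q]
    eliminated = {g: iqrs[g] for g in mat.row_ids if iqrs[g] < q}
    if not retained:
        warnings.warn(f"threshold q={q} eliminates every gene")
        out = ExpressionMatrix(
            np.empty((0, len(mat.col_ids))), [], list(mat.col_ids), mat.space
        )
    else:
        out = mat.subset_rows(retained)
    return out, FilterReport(q, method, len(mat.row_ids), retained, eliminated)


def select_threshold(
    mat: ExpressionMatrix,
    method: str = "histogram",
    fixed_q: float | None = None,
    bin_width: float = 0.025,
    grid_step: float = 0.01,
    iqrs: dict[str, float] | None = None,
) -> float:
    """Dispatch to one of the selectors: histogram | derivative | fixed."""
    iqrs = iqrs if iqrs is not None else gene_iqr(mat)
    if method == "histogram":
        return histogram_threshold(iqrs, bin_width)
    if method == "derivative":
        return derivative_threshold(build_iqr_profile(iqrs, grid_step))
    if method == "fixed":
        if fixed_q is None:
            raise ConfigError("fixed method requires a q value")
        return float(fixed_q)
    raise ConfigError(f"unknown threshold method {method!r}")
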