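"""Spatial correlation of marker expression and grid-based smoothing.

The spatial correlation coefficient of proteins i and j is the weighted
inner product

    SpatialCorCoef_ij = v_i^T W v_j,

where v_i is the vector of scaled (z-scored) expression of protein i over
all cells and W is the globally normalised inverse-square-distance weight
matrix

    A_kl = (1 / d_kl)^2 for k != l (0 on the diagonal),
    W = A / sum_{k,l} A_kl,

with d_kl the Euclidean distance between the centroids of cells k and l.
Because W is normalised by its total, the statistic is invariant to a
global rescaling of the coordinate units.

For visualisation, per-cell expression is averaged on a 50 x 50 grid over
the spatial bounding box and smoothed by three passes of a 5 x 5 moving
average; grid cells containing no cells are treated as missing, not zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter
from scipy.spatial.distance import pdist, squareform

__all__ = ["SpatialWeights", "build_weights", "spatial_corr", "grid_smooth", "GridField"]

log = logging.getLogger(__name__)


@dataclass
class SpatialWeights:
    """Inverse-square-distance weights of a set of cells."""

    distances: np.ndarray  # n x n Euclidean distances
    A: np.ndarray          # raw weights, (1/d)^2 off-diagonal, 0 diagonal
    W: np.ndarray          # A / A.sum(); sums to 1


def build_weights(coords: np.ndarray) -> SpatialWeights:
    """Build W from cell coordinates (n x 2, any consistent length unit).

    Raises ``ValueError`` naming the first offending pair if two cells share
    a coordinate (the weight would be infinite).
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[0] < 2:
        raise ValueError("need at least 2 cells with 2-D coordinates")
    d = squareform(pdist(coords))
    off = ~np.eye(len(d), dtype=bool)
    if np.any(d[off] == 0):
        k, l = np.argwhere((d == 0) & off)[0]
        raise ValueError(f"cells {k} and {l} share coordinates (zero distance)")
    A = np.zeros_like(d)
    A[off] = 1.0 / d[off] ** 2
    return SpatialWeights(distances=d, A=A, W=A / A.sum())


def spatial_corr(expr: np.ndarray | pd.DataFrame, weights: SpatialWeights) -> pd.DataFrame:
    """All pairwise spatial correlation coefficients v_i^T W v_j.

    ``expr`` is cells x proteins with each column already scaled (z-scored).
    Columns whose sd strays from 1 trigger a warning but are still used.
    """
    if isinstance(expr, pd.DataFrame):
        names = list(expr.columns)
        V = expr.to_numpy(dtype=float)
    else:
        V = np.asarray(expr, dtype=float)
        names = [f"v{i}" for i in range(V.shape[1])]
    if V.shape[0] != weights.W.shape[0]:
        raise ValueError("expression rows and weight matrix size disagree")
    sds = V.std(axis=0)
    if np.any(np.abs(sds - 1.0) > 0.1) and V.shape[0] > 1:
        log.warning(
            "expression columns do not look z-scored (sd range %.3f-%.3f); "
            "computing anyway", sds.min(), sds.max(),
        )
    M = V.T @ weights.W @ V
    return pd.DataFrame(M, index=names, columns=names)


@dataclass
class GridField:
    """Gridded per-cell-average expression with missing-aware smoothing."""

    raw: np.ndarray       # grid means; NaN where the grid cell is empty
    smoothed: np.ndarray  # after the moving-average passes; NaN stays NaN
    edges_row: np.ndarray
    edges_col: np.ndarray


def _nan_moving_average(field: np.ndarray, kernel: int) -> np.ndarray:
    """One kernel x kernel moving-average pass.

    The kernel is renormalised over in-bounds, non-missing entries, so
    borders get unbiased averages and empty grid cells neither receive nor
    contribute values.
    """
    filled = np.where(np.isnan(field), 0.0, field)
    valid = (~np.isnan(field)).astype(float)
    size = kernel
    num = uniform_filter(filled, size=size, mode="constant", cval=0.0)
    den = uniform_filter(valid, size=size, mode="constant", cval=0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[np.isnan(field)] = np.nan  # missing cells stay missing
    return out


def grid_smooth(
    values: np.ndarray,
    coords: np.ndarray,
    grid_n: int = 50,
    kernel: int = 5,
    passes: int = 3,
) -> GridField:
    """Average per-cell values on a grid_n x grid_n grid and smooth.

    The grid spans the bounding box of ``coords``; each grid cell takes the
    mean of its member cells and the field is then smoothed ``passes`` times
    with a ``kernel`` x ``kernel`` moving average.
    """
    values = np.asarray(values, dtype=float)
    coords = np.asarray(coords, dtype=float)
    if len(values) != len(coords):
        raise ValueError("values and coords disagree in length")
    r, c = coords[:, 0], coords[:, 1]
    edges_row = np.linspace(r.min(), r.max(), grid_n + 1)
    edges_col = np.linspace(c.min(), c.max(), grid_n + 1)
    ri = np.clip(np.searchsorted(edges_row, r, side="right") - 1, 0, grid_n - 1)
    ci = np.clip(np.searchsorted(edges_col, c, side="right") - 1, 0, grid_n - 1)
    sums = np.zeros((grid_n, grid_n))
    counts = np.zeros((grid_n, grid_n))
    np.add.at(sums, (ri, ci), values)
    np.add.at(counts, (ri, ci), 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = sums / counts
    raw[counts == 0] = np.nan
    smoothed = raw.copy()
    for _ in range(passes):
        smoothed = _nan_moving_average(smoothed, kernel)
    return GridField(raw=raw, smoothed=smoothed,
                     edges_row=edges_row, edges_col=edges_col)
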