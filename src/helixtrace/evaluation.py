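"""Precision/recall/F1 of tracing results against ground-truth traces.

Both trace sets are rasterized onto coarse binary grids of 25 A pixel
size.  Because interactively picked ground truth is usually straight
and slightly off-axis, each side is compared against a version of the
other that has been morphologically inflated by the helix width:

    P  = |result AND inflate(truth)|  / |result|
    R  = |truth  AND inflate(result)| / |truth|
    F1 = 2 P R / (P + R)

A 400 A margin around the micrograph boundary and discs of one helix
width (two helix radii) around every trace endpoint are excluded from
both grids, removing boundary effects and the ambiguity of where a
trace should end.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
from scipy import ndimage
from skimage import morphology

__all__ = [
    "GRID_PIXEL_A",
    "MARGIN_A",
    "EvaluationGrid",
    "EvaluationResult",
    "traces_to_grid",
    "evaluate",
    "grid_search",
]

GRID_PIXEL_A = 25.0
MARGIN_A = 400.0


@dataclasses.dataclass
class EvaluationGrid:
    grid: np.ndarray  # boolean, 25 A cells, origin at micrograph (0,0)
    grid_pixel_A: float = GRID_PIXEL_A
    inflation_width_A: float = 0.0
    margin_A: float = MARGIN_A


@dataclasses.dataclass
class EvaluationResult:
    precision_P: float
    recall_R: float
    f1: float
    n_result_cells: int
    n_truth_cells: int
    n_result_hits: int
    n_truth_hits: int


def _coords(trace) -> np.ndarray:
    return np.asarray(getattr(trace, "coords_A", trace), dtype=float)


def _grid_shape(extent_A: tuple[float, float]) -> tuple[int, int]:
    w, h = extent_A
    return int(np.ceil(h / GRID_PIXEL_A)), int(np.ceil(w / GRID_PIXEL_A))


def _rasterize(traces, shape: tuple[int, int]) -> np.ndarray:
    """Set every grid cell intersected by any trace polyline.

    Cells are half-open squares; segments are sampled densely (a
    quarter cell) which also sets cells only touched at a boundary via
    the floor rule (lexicographically smaller cell).
    """
    grid = np.zeros(shape, dtype=bool)
    step = GRID_PIXEL_A / 4.0
    for trace in traces:
        pts = _coords(trace)
        if len(pts) < 2:
            continue
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        total = seg.sum()
        n = max(2, int(np.ceil(total / step)) + 1)
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        s = np.linspace(0.0, total, n)
        x = np.interp(s, cum, pts[:, 0])
        y = np.interp(s, cum, pts[:, 1])
        cols = np.floor(x / GRID_PIXEL_A).astype(int)
        rows = np.floor(y / GRID_PIXEL_A).astype(int)
        ok = (rows >= 0) & (rows < shape[0]) & (cols >= 0) & (cols < shape[1])
        grid[rows[ok], cols[ok]] = True
    return grid


def _exclusion_mask(
    shape: tuple[int, int], endpoint_sets, helix_width_A: float, margin_A: float
) -> np.ndarray:
    """True where grid cells take part in the comparison."""
    keep = np.zeros(shape, dtype=bool)
    m = int(np.ceil(margin_A / GRID_PIXEL_A))
    if shape[0] > 2 * m and shape[1] > 2 * m:
        keep[m : shape[0] - m, m : shape[1] - m] = True
    radius = helix_width_A / GRID_PIXEL_A  # two helix radii = one width
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    for traces in endpoint_sets:
        for trace in traces:
            pts = _coords(trace)
            if len(pts) == 0:
                continue
            for pt in (pts[0], pts[-1]):
                pc = pt[0] / GRID_PIXEL_A
                pr = pt[1] / GRID_PIXEL_A
                keep &= (yy - pr) ** 2 + (xx - pc) ** 2 > radius**2
    return keep


def _inflate(grid: np.ndarray, width_A: float) -> np.ndarray:
    r = int(round(width_A / GRID_PIXEL_A))
    if r < 1:
        return grid
    return ndimage.binary_dilation(grid, structure=morphology.disk(r))


def traces_to_grid(
    traces,
    micrograph_extent_A: tuple[float, float],
    helix_width_A: float,
    inflate: bool = False,
    margin_A: float = MARGIN_A,
) -> EvaluationGrid:
    """Rasterize traces to the 25 A evaluation grid.

    Applies (in order) optional inflation by the helix width, the
    boundary margin, and endpoint exclusion discs for the traces given.
    """
    shape = _grid_shape(micrograph_extent_A)
    grid = _rasterize(traces, shape)
    width = helix_width_A if inflate else 0.0
    if inflate:
        grid = _inflate(grid, helix_width_A)
    keep = _exclusion_mask(shape, [traces], helix_width_A, margin_A)
    return EvaluationGrid(grid & keep, GRID_PIXEL_A, width, margin_A)


def evaluate(
    result_traces,
    truth_traces,
    helix_width_A: float,
    extent_A: tuple[float, float],
    margin_A: float = MARGIN_A,
) -> EvaluationResult:
    """Precision, recall and F1 of a tracing result against ground truth.

    An empty result yields P = R = F1 = 0 by convention (the precision
    ratio is 0/0).
    """
    shape = _grid_shape(extent_A)
    keep = _exclusion_mask(
        shape, [result_traces, truth_traces], helix_width_A, margin_A
    )
    res = _rasterize(result_traces, shape)
    tru = _rasterize(truth_traces, shape)
    res_infl = _inflate(res, helix_width_A) & keep
    tru_infl = _inflate(tru, helix_width_A) & keep
    res &= keep
    tru &= keep
    n_res = int(res.sum())
    n_tru = int(tru.sum())
    res_hits = int((res & tru_infl).sum())
    tru_hits = int((tru & res_infl).sum())
    P = res_hits / n_res if n_res else 0.0
    R = tru_hits / n_tru if n_tru else 0.0
    f1 = 2 * P * R / (P + R) if P + R > 0 else 0.0
    return EvaluationResult(P, R, f1, n_res, n_tru, res_hits, tru_hits)


def grid_search(
    prepared,
    truth_sets,
    alpha_grid,
    minlen_grid,
    extract_fn,
    helix_width_A: float,
    extents_A,
    margin_A: float = MARGIN_A,
):
    """F1-maximizing (alpha, min-length) over a Cartesian parameter grid.

    ``prepared`` is a list of per-micrograph objects holding the
    already-computed correlation map (the expensive part); only the
    extraction steps are re-run per cell via
    ``extract_fn(prepared_item, alpha, min_len_A) -> traces``.
    Counts are pooled over micrographs before forming P/R/F1.  Ties
    are broken toward larger alpha, then smaller minimum length.

    Returns ``(best_alpha, best_minlen, f1_matrix)`` with the matrix
    indexed ``[i_minlen, j_alpha]``.
    """
    alpha_grid = list(alpha_grid)
    minlen_grid = list(minlen_grid)
    if not alpha_grid or not minlen_grid:
        raise ValueError("parameter grids must be non-empty")
    f1 = np.zeros((len(minlen_grid), len(alpha_grid)))
    for (i, minlen), (j, alpha) in itertools.product(
        enumerate(minlen_grid), enumerate(alpha_grid)
    ):
        tot = np.zeros(4)  # res_hits, n_res, tru_hits, n_tru
        for prep, truth, extent in zip(prepared, truth_sets, extents_A):
            traces = extract_fn(prep, alpha, minlen)
            r = evaluate(traces, truth, helix_width_A, extent, margin_A)
            tot += (r.n_result_hits, r.n_result_cells, r.n_truth_hits, r.n_truth_cells)
        P = tot[0] / tot[1] if tot[1] else 0.0
        R = tot[2] / tot[3] if tot[3] else 0.0
        f1[i, j] = 2 * P * R / (P + R) if P + R > 0 else 0.0
    best = np.max(f1)
    candidates = [
        (i, j)
        for i in range(len(minlen_grid))
        for j in range(len(alpha_grid))
        if f1[i, j] == best
    ]
    # larger alpha first, then smaller min-length
    i_best, j_best = min(candidates, key=lambda ij: (-alpha_grid[ij[1]], minlen_grid[ij[0]]))
    return alpha_grid[j_best], minlen_grid[i_best], f1
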