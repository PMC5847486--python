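"""From pixel paths to helix traces: fitting, flexibility, pruning.

A raw skeleton path is noisy at the pixel level; fitting a low-order
polynomial in the path's principal-axis frame and resampling the fit at
equal arc-length steps yields the equidistant segment coordinates used
by helical reconstruction workflows.  Per-trace straightness is
quantified by the flexibility

    lambda = -ln(2 (R/L)^2 - 1) / L        [1/Angstrom]

from the end-to-end distance R and contour length L, and the
persistence length p = 1 / lambda.  Over a micrograph set the p values
follow a log-normal distribution; traces far below the population
median (kinked helices, elongated contamination) are pruned using
robust location/scale estimates on ln p.
"""

from __future__ import annotations

import dataclasses
import logging
import math
import warnings

import numpy as np

__all__ = [
    "HelixTrace",
    "TraceSet",
    "filter_and_split",
    "fit_trace",
    "flexibility_and_persistence",
    "prune_population",
    "contour_length",
]

log = logging.getLogger(__name__)

#: persistence-length sentinel for traces with R/L <= 1/sqrt(2), where
#: the flexibility formula leaves its domain ("maximally flexible")
MAX_FLEXIBLE_P = 0.0


@dataclasses.dataclass
class HelixTrace:
    """One traced helix: equidistant segment coordinates plus shape stats."""

    coords_A: np.ndarray  # (n, 2) of (x, y) in Angstrom
    contour_length_L_A: float
    end_to_end_R_A: float
    flexibility_lambda: float  # 1/Angstrom; nan when out of domain
    persistence_p_A: float  # inf = rigid rod, MAX_FLEXIBLE_P = out of domain
    poly_order: int
    micrograph_id: str = ""

    def __post_init__(self):
        self.coords_A = np.asarray(self.coords_A, dtype=float)
        if len(self.coords_A) < 2:
            raise ValueError("a trace needs at least two coordinates")
        if self.end_to_end_R_A > self.contour_length_L_A * (1 + 1e-9):
            raise ValueError("end-to-end distance exceeds contour length")

    @property
    def maximally_flexible(self) -> bool:
        return self.persistence_p_A == MAX_FLEXIBLE_P


@dataclasses.dataclass
class TraceSet:
    traces: list
    population_median_log_p: float = math.nan
    population_mad_log_p: float = math.nan

    def __post_init__(self):
        self.refresh_statistics()

    def refresh_statistics(self):
        lp = self._log_p()
        if lp.size:
            self.population_median_log_p = float(np.median(lp))
            self.population_mad_log_p = float(np.median(np.abs(lp - np.median(lp))))
        else:
            self.population_median_log_p = math.nan
            self.population_mad_log_p = math.nan

    def _log_p(self) -> np.ndarray:
        p = np.array(
            [
                t.persistence_p_A
                for t in self.traces
                if t.persistence_p_A > 0 and np.isfinite(t.persistence_p_A)
            ]
        )
        return np.log(p) if p.size else p


def contour_length(path_A: np.ndarray) -> float:
    """Polyline length in Angstrom."""
    path_A = np.asarray(path_A, dtype=float)
    if len(path_A) < 2:
        return 0.0
    return float(np.linalg.norm(np.diff(path_A, axis=0), axis=1).sum())


def filter_and_split(
    paths: list[np.ndarray], min_len_A: float, max_len_A: float
) -> list[np.ndarray]:
    """Drop short paths, split long ones into near-equal pieces.

    Paths are (n, 2) coordinate polylines in Angstrom.  A path longer
    than ``max_len_A`` is cut into the smallest number of near-equal
    pieces each at most ``max_len_A``; pieces below ``min_len_A``
    (possible only for heavily split borderline paths) are dropped as
    well.  The minimum-length bound is inclusive.
    """
    if not min_len_A < max_len_A:
        raise ValueError("min_len_A must be below max_len_A")
    out = []
    for path in paths:
        path = np.asarray(path, dtype=float)
        L = contour_length(path)
        if L < min_len_A:
            continue
        if L <= max_len_A:
            out.append(path)
            continue
        n_pieces = int(np.ceil(L / max_len_A))
        seg = np.linalg.norm(np.diff(path, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        cut_idx = [0]
        for k in range(1, n_pieces):
            cut_idx.append(int(np.searchsorted(cum, L * k / n_pieces)))
        cut_idx.append(len(path) - 1)
        for a, b in zip(cut_idx[:-1], cut_idx[1:]):
            piece = path[a : b + 1]
            if len(piece) >= 2 and contour_length(piece) >= min_len_A:
                out.append(piece)
    return out


def _auto_order(length_A: float) -> int:
    # a quadratic suffices for 500-2000 A traces; shorter ones are
    # nearly straight within a tile, longer ones may bend twice
    if length_A < 500:
        return 1
    if length_A <= 2000:
        return 2
    return 3


def fit_trace(
    path_A: np.ndarray,
    order: int | None = None,
    segment_spacing_A: float = 70.0,
    micrograph_id: str = "",
) -> HelixTrace:
    """Polynomial fit of one path, resampled at equal arc-length steps.

    The path is rotated into its principal-axis frame so the fitted
    function is single-valued even for near-vertical traces, fitted by
    least squares, densely evaluated, and resampled at
    ``segment_spacing_A`` along the fitted curve (the final point is
    the curve end, so the last interval may be shorter).
    """
    path_A = np.asarray(path_A, dtype=float)
    if order is None:
        order = _auto_order(contour_length(path_A))
    order = int(order)
    if not 1 <= order <= 3:
        raise ValueError("polynomial order must be 1-3")
    if len(path_A) < order + 1:
        raise ValueError(
            f"path has {len(path_A)} points; order-{order} fit needs {order + 1}"
        )
    centre = path_A.mean(axis=0)
    centred = path_A - centre
    # principal axis via SVD; rotate so the long direction is 'u'
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    rot = vt  # rows: principal directions
    uw = centred @ rot.T
    u, w = uw[:, 0], uw[:, 1]
    srt = np.argsort(u)
    u, w = u[srt], w[srt]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", np.exceptions.RankWarning)
        coeff = np.polyfit(u, w, order)
    poly = np.poly1d(coeff)
    u_dense = np.linspace(u[0], u[-1], max(2000, 10 * len(u)))
    w_dense = poly(u_dense)
    d = np.hypot(np.diff(u_dense), np.diff(w_dense))
    s = np.concatenate([[0.0], np.cumsum(d)])
    L = float(s[-1])
    n_seg = max(1, int(np.floor(L / segment_spacing_A)))
    s_target = np.arange(0, n_seg + 1) * segment_spacing_A
    if L - s_target[-1] > 1e-9:
        s_target = np.append(s_target, L)
    u_s = np.interp(s_target, s, u_dense)
    w_s = np.interp(s_target, s, w_dense)
    coords = np.column_stack([u_s, w_s]) @ rot + centre
    R = float(np.linalg.norm(coords[-1] - coords[0]))
    R = min(R, L)
    lam, p = flexibility_and_persistence(R, L)
    return HelixTrace(coords, L, R, lam, p, order, micrograph_id)


def flexibility_and_persistence(R_A: float, L_A: float) -> tuple[float, float]:
    """Flexibility lambda and persistence length p from R and L.

    ``lambda = -ln(2 (R/L)^2 - 1) / L`` and ``p = 1/lambda``.  A
    perfectly straight trace (R = L) returns ``(0, inf)``; a trace with
    R/L <= 1/sqrt(2) is outside the domain of the formula and returns
    ``(nan, 0)``, the maximally-flexible sentinel that is always
    prunable.
    """
    if not 0 < R_A <= L_A * (1 + 1e-12):
        raise ValueError(f"need 0 < R <= L, got R={R_A}, L={L_A}")
    ratio = min(R_A / L_A, 1.0)
    arg = 2.0 * ratio * ratio - 1.0
    if arg <= 0:
        return math.nan, MAX_FLEXIBLE_P
    lam = -math.log(arg) / L_A
    if lam == 0:
        return 0.0, math.inf
    return lam, 1.0 / lam


def prune_population(ts: TraceSet, n_sigma: float = 2.0) -> TraceSet:
    """Remove kinked/overly bent traces from the population.

    On ln p the population is modelled as normal with location = median
    and scale = 1.4826 * MAD; traces more than ``n_sigma`` scales below
    the location are discarded, as are maximally-flexible-flagged ones.
    With fewer than five defined persistence lengths pruning is skipped.
    """
    defined = [t for t in ts.traces if t.persistence_p_A > 0]
    if len(defined) < 5:
        log.warning("only %d traces with defined p; pruning skipped", len(defined))
        return TraceSet(list(ts.traces))
    lp = np.log([t.persistence_p_A for t in defined])  # inf allowed (rigid)
    loc = float(np.median(lp))
    mad = float(np.median(np.abs(lp - loc)))
    scale = 1.4826 * mad
    cut = loc - n_sigma * scale
    kept = [
        t
        for t in ts.traces
        if t.persistence_p_A > 0 and np.log(t.persistence_p_A) >= cut
    ]
    n_removed = len(ts.traces) - len(kept)
    if n_removed:
        log.info("pruned %d of %d traces below ln p = %.3f", n_removed, len(ts.traces), cut)
    return TraceSet(kept)
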