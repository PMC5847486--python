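"""Ensemble persistence length: worm-like-chain simulation and tangent fit.

The persistence length p of a polymer is the decay length of the
correlation between unit tangent vectors along its contour,

    <t(u) . t(u + s)> = exp(-s / p).

This module provides the two halves of that definition as exact
inverses of each other:

* a discrete planar worm-like-chain simulator whose successive tangent
  angles receive i.i.d. normal increments of variance
  ``2 * segment / p`` so that the expected tangent correlation is
  exactly ``exp(-s/p)``, and
* the estimator: mean tangent-tangent dot products as a function of
  separation, fitted by an exponential decay.

Separate per-trace flexibility from end-to-end distances lives in
:mod:`helixtrace.trace_geometry`; the two estimators are deliberately
exposed side by side.
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np

__all__ = [
    "WLCEnsemble",
    "TangentCorrelation",
    "simulate_wlc",
    "tangent_correlation",
    "fit_persistence",
    "RIGID",
]

#: sentinel for perfectly straight ensembles (no measurable decay)
RIGID = math.inf


@dataclasses.dataclass
class WLCEnsemble:
    chains: list  # each an (n, 2) array of (x, y) in Angstrom
    segment_len_A: float
    generating_p_A: float
    seed: int


@dataclasses.dataclass
class TangentCorrelation:
    separations_A: np.ndarray  # increasing, multiples of the sampling step
    mean_cos: np.ndarray
    n_pairs: np.ndarray

    def __post_init__(self):
        if np.any(self.mean_cos > 1 + 1e-9) or np.any(self.mean_cos < -1 - 1e-9):
            raise ValueError("mean tangent correlation must lie in [-1, 1]")


def simulate_wlc(
    n_chains: int,
    contour_A: float,
    segment_A: float,
    p_A: float,
    seed: int = 0,
) -> WLCEnsemble:
    """Simulate planar discrete worm-like chains.

    Each chain starts at the origin with a uniformly random direction;
    successive segment angles differ by normal increments of variance
    ``2 * segment_A / p_A``, giving ``<t(u).t(u+s)> = exp(-s/p)``.
    ``p_A = inf`` produces perfectly straight chains.
    """
    if contour_A <= 0 or segment_A <= 0 or segment_A > contour_A:
        raise ValueError("need 0 < segment_A <= contour_A")
    if not p_A > 0:
        raise ValueError("persistence length must be positive (inf = rigid)")
    rng = np.random.default_rng(seed)
    n_seg = int(round(contour_A / segment_A))
    sd = 0.0 if math.isinf(p_A) else math.sqrt(2.0 * segment_A / p_A)
    chains = []
    for _ in range(n_chains):
        theta0 = rng.uniform(0.0, 2.0 * math.pi)
        increments = rng.normal(0.0, sd, n_seg - 1) if n_seg > 1 else np.empty(0)
        angles = theta0 + np.concatenate([[0.0], np.cumsum(increments)])
        steps = segment_A * np.column_stack([np.cos(angles), np.sin(angles)])
        pts = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
        chains.append(pts)
    return WLCEnsemble(chains, segment_A, p_A, seed)


def _as_chains(obj) -> list:
    if hasattr(obj, "chains"):
        return obj.chains
    if hasattr(obj, "traces"):
        return [t.coords_A for t in obj.traces]
    return list(obj)


def tangent_correlation(ensemble, max_sep_A: float) -> TangentCorrelation:
    """Mean tangent-tangent correlation versus contour separation.

    Accepts a :class:`WLCEnsemble`, a trace set, or a plain list of
    equidistant coordinate arrays.  Unit tangents are formed from
    consecutive segment coordinates; separations are multiples of the
    sampling step (taken from the first chain) up to ``max_sep_A``.
    """
    chains = [np.asarray(c, dtype=float) for c in _as_chains(obj=ensemble)]
    chains = [c for c in chains if len(c) >= 3]
    if not chains:
        raise ValueError("need at least one chain with >= 3 points")
    step = float(np.linalg.norm(chains[0][1] - chains[0][0]))
    max_k = int(np.floor(max_sep_A / step))
    sums = np.zeros(max_k + 1)
    counts = np.zeros(max_k + 1, dtype=np.int64)
    for c in chains:
        tangents = np.diff(c, axis=0)
        norms = np.linalg.norm(tangents, axis=1)
        tangents = tangents / norms[:, None]
        n = len(tangents)
        for k in range(0, min(max_k, n - 1) + 1):
            dots = np.einsum("ij,ij->i", tangents[: n - k], tangents[k:])
            sums[k] += dots.sum()
            counts[k] += dots.size
    valid = counts > 0
    return TangentCorrelation(
        separations_A=np.arange(max_k + 1)[valid] * step,
        mean_cos=sums[valid] / counts[valid],
        n_pairs=counts[valid],
    )


def fit_persistence(tc: TangentCorrelation, min_pairs: int = 10) -> float:
    """Persistence length from an exponential fit of the tangent correlation.

    Separations with fewer than ``min_pairs`` contributing pairs are
    excluded.  When all retained correlations are positive the fit is
    performed on the linearized form ``ln c = -s/p`` (no intercept,
    weighted by pair counts); otherwise a nonlinear least-squares fit
    of ``exp(-s/p)`` is used.  Returns ``RIGID`` (inf) for ensembles
    without measurable decay; a non-decaying noisy correlation yields a
    warning and a best-effort estimate.
    """
    keep = (tc.n_pairs >= min_pairs) & (tc.separations_A > 0)
    s = tc.separations_A[keep]
    c = tc.mean_cos[keep]
    w = tc.n_pairs[keep].astype(float)
    if s.size < 3:
        raise ValueError("need at least 3 separations with enough pairs")
    if np.all(c >= 1.0 - 1e-12):
        return RIGID
    if np.all(c > 0):
        slope = float(np.sum(w * s * np.log(c)) / np.sum(w * s * s))
        if slope >= 0:
            warnings.warn("tangent correlation does not decay; estimate unreliable")
            return RIGID
        return -1.0 / slope
    from scipy.optimize import curve_fit

    start = s[c > 0]
    p0 = float(start[-1]) if start.size else float(s[-1])
    try:
        popt, _ = curve_fit(
            lambda x, p: np.exp(-x / p),
            s,
            c,
            p0=max(p0, 1.0),
            sigma=1.0 / np.sqrt(w),
            bounds=(1e-6, np.inf),
            maxfev=10000,
        )
    except RuntimeError:
        warnings.warn("exponential fit did not converge; returning crossing estimate")
        return max(p0, 1.0)
    return float(popt[0])
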