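"""Pipeline driver, synthetic micrograph generation and coordinate I/O.

``trace_micrograph`` chains the full workflow: preprocessing, per-tile
angle/shift correlation, correlation-map accumulation, statistical
thresholding, skeletonization and branch splitting, length filtering,
polynomial fitting and population pruning.  Trace coordinates are kept
in Angstrom throughout and converted to unbinned pixels only on
export.

``generate_synthetic_scene`` renders micrographs with known
ground-truth filament paths: worm-like-chain centrelines, a soft-edged
ribbon density with a sinusoidal axial modulation (which produces the
layer lines the rotational search relies on), and additive Gaussian
white noise at a controllable signal-to-noise ratio.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from . import trace_geometry, trace_map
from .flexibility import simulate_wlc
from .preprocess import (
    Micrograph,
    ReferenceHelix,
    TracingParams,
    highpass,
    make_tile_grid,
    normalize_and_bin,
    prepare_reference,
    suppress_outliers,
)
from .tile_correlation import match_all_tiles
from .trace_geometry import TraceSet

__all__ = [
    "SyntheticScene",
    "PreparedMicrograph",
    "prepare_micrograph",
    "extract_traces",
    "trace_micrograph",
    "generate_synthetic_scene",
    "render_reference",
    "write_box",
    "read_box",
    "write_relion_coords",
    "load_config",
]

log = logging.getLogger(__name__)


@dataclasses.dataclass
class SyntheticScene:
    truth_traces: list  # ground-truth centrelines, (n, 2) of (x, y) in A
    helix_width_A: float
    axial_repeat_A: float
    snr: float
    seed: int
    rendered: Micrograph


@dataclasses.dataclass
class PreparedMicrograph:
    """Correlation map plus the context needed to re-run extraction.

    Computing the map is the expensive step; holding it here lets the
    parameter grid search repeat only the cheap extraction stages.
    """

    cmap: trace_map.CorrelationMap
    null: trace_map.ExponentialNull
    params: TracingParams
    pixel_size_A: float  # of the binned working image
    shape: tuple[int, int]
    source_id: str = ""


def prepare_micrograph(
    m: Micrograph, ref: ReferenceHelix, params: TracingParams
) -> PreparedMicrograph:
    """Run all stages up to (and including) the correlation map."""
    work = normalize_and_bin(m, params.binning_factor)
    work = highpass(work)
    work = suppress_outliers(work)
    grid = make_tile_grid(work.shape, params, work.pixel_size_A)
    ref_img, ref_ps = prepare_reference(ref, grid, work.pixel_size_A)
    matches = match_all_tiles(work, grid, ref_img, ref_ps, params.angular_step_deg)
    cmap = trace_map.accumulate_map(matches, grid, work.shape)
    null = trace_map.fit_null(cmap)
    log.info(
        "%s: %d tiles, null lambda=%.4g, alpha=%.3g -> threshold=%.4g",
        m.source_id,
        len(matches),
        null.lambda_scale,
        params.alpha,
        null.threshold(params.alpha),
    )
    return PreparedMicrograph(
        cmap, null, params, work.pixel_size_A, work.shape, m.source_id
    )


def extract_traces(
    prep: PreparedMicrograph,
    alpha: float | None = None,
    min_len_A: float | None = None,
) -> list:
    """Threshold -> skeleton -> branch split -> length filter -> fit.

    Returns unpruned traces (population pruning is a per-dataset step);
    ``alpha`` and ``min_len_A`` override the stored parameters, which
    is what the optimization grid search uses.
    """
    p = prep.params
    alpha = p.alpha if alpha is None else alpha
    min_len = p.min_helix_len_A if min_len_A is None else min_len_A
    binary = trace_map.threshold_map(prep.cmap, prep.null, alpha)
    skel = trace_map.skeletonize(binary, provenance=prep.source_id)
    points = trace_map.detect_branch_points(skel)
    skel = trace_map.erase_branch_regions(
        skel, points, p.helix_width_A, prep.pixel_size_A
    )
    skel = trace_map.remove_junction_pixels(skel)
    paths = trace_map.extract_paths(skel)
    apix = prep.pixel_size_A
    paths_A = [p_.rc[:, ::-1].astype(float) * apix for p_ in paths]  # (row,col)->(x,y)
    kept = trace_geometry.filter_and_split(paths_A, min_len, p.max_helix_len_A)
    traces = []
    for path in kept:
        try:
            traces.append(
                trace_geometry.fit_trace(
                    path,
                    order=None,
                    segment_spacing_A=p.segment_spacing_A,
                    micrograph_id=prep.source_id,
                )
            )
        except ValueError as exc:
            log.warning("%s: trace dropped (%s)", prep.source_id, exc)
    log.info(
        "%s: %d skeleton paths -> %d traces after length filter",
        prep.source_id,
        len(paths),
        len(traces),
    )
    return traces


def trace_micrograph(
    m: Micrograph, ref: ReferenceHelix, params: TracingParams
) -> TraceSet:
    """Full tracing pipeline for a single micrograph.

    Deterministic for fixed inputs.  Coordinates of the returned traces
    are in Angstrom of the original (unbinned) micrograph frame.
    """
    prep = prepare_micrograph(m, ref, params)
    traces = extract_traces(prep)
    ts = TraceSet(traces)
    return trace_geometry.prune_population(ts, params.prune_n_sigma)


# ---------------------------------------------------------------------------
# synthetic scenes


def _render_paths(
    shape: tuple[int, int],
    pixel_size_A: float,
    paths_A: list,
    helix_width_A: float,
    axial_repeat_A: float,
) -> np.ndarray:
    """Render filament centrelines as modulated soft ribbons.

    The transverse profile is Gaussian with sigma = width/4 (so the
    ribbon spans roughly one helix width); the axial modulation
    ``0.5 + 0.5 cos(2 pi s / repeat)`` imprints the periodicity that
    gives rise to layer lines in the power spectrum.
    """
    img = np.zeros(shape)
    sigma = helix_width_A / 4.0 / pixel_size_A
    reach = int(np.ceil(3 * sigma)) + 1
    sample_A = min(pixel_size_A / 2.0, axial_repeat_A / 8.0)
    for path in paths_A:
        path = np.asarray(path, dtype=float)
        seg = np.linalg.norm(np.diff(path, axis=0), axis=1)
        total = seg.sum()
        if total <= 0:
            continue
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        s = np.arange(0.0, total + sample_A / 2, sample_A)
        dense = np.column_stack(
            [np.interp(s, cum, path[:, 0]), np.interp(s, cum, path[:, 1])]
        )
        tree = cKDTree(dense / pixel_size_A)
        c_lo = max(0, int(dense[:, 0].min() / pixel_size_A) - reach)
        c_hi = min(shape[1], int(dense[:, 0].max() / pixel_size_A) + reach + 1)
        r_lo = max(0, int(dense[:, 1].min() / pixel_size_A) - reach)
        r_hi = min(shape[0], int(dense[:, 1].max() / pixel_size_A) + reach + 1)
        if r_lo >= r_hi or c_lo >= c_hi:
            continue
        yy, xx = np.mgrid[r_lo:r_hi, c_lo:c_hi]
        pts = np.column_stack([xx.ravel(), yy.ravel()])
        d, idx = tree.query(pts, distance_upper_bound=3 * sigma)
        ok = np.isfinite(d)
        amp = np.zeros(len(pts))
        s_axial = s[np.clip(idx[ok], 0, len(s) - 1)]
        modulation = 0.5 + 0.5 * np.cos(2 * np.pi * s_axial / axial_repeat_A)
        amp[ok] = np.exp(-(d[ok] ** 2) / (2 * sigma**2)) * modulation
        img[r_lo:r_hi, c_lo:c_hi] += amp.reshape(yy.shape)
    return img


def render_reference(
    helix_width_A: float,
    axial_repeat_A: float,
    size_px: int,
    pixel_size_A: float,
) -> ReferenceHelix:
    """Clean vertical synthetic filament to act as the tracing reference."""
    size_A = size_px * pixel_size_A
    path = np.array([[size_A / 2, -size_A], [size_A / 2, 2 * size_A]])
    img = _render_paths(
        (size_px, size_px), pixel_size_A, [path], helix_width_A, axial_repeat_A
    )
    return ReferenceHelix(img, pixel_size_A, helix_width_A)


def generate_synthetic_scene(
    n_filaments: int,
    persistence_p_A: float,
    helix_width_A: float,
    axial_repeat_A: float,
    snr: float,
    image_A: float,
    pixel_size_A: float,
    seed: int = 0,
    contour_A: float = 1500.0,
    segment_A: float = 25.0,
    margin_A: float = 500.0,
) -> SyntheticScene:
    """Render a micrograph of worm-like-chain filaments plus white noise.

    ``snr`` is the ratio of the variance of the rendered signal layer
    (over the whole image) to the noise variance; ``snr = inf`` gives a
    noiseless image.  Ground-truth centrelines are returned alongside.
    """
    if contour_A + 2 * margin_A > image_A * 1.5:
        raise ValueError("filaments do not plausibly fit in the image")
    rng = np.random.default_rng(seed)
    shape = (int(round(image_A / pixel_size_A)),) * 2
    lo, hi = margin_A, image_A - margin_A
    if hi <= lo:
        raise ValueError("margin leaves no room for filaments")
    paths = []
    attempts = 0
    while len(paths) < n_filaments:
        attempts += 1
        if attempts > 200 * n_filaments:
            raise ValueError("could not place filaments inside the image")
        chain = simulate_wlc(
            1, contour_A, segment_A, persistence_p_A,
            seed=int(rng.integers(1 << 31)),
        ).chains[0]
        chain = chain - chain.mean(axis=0)
        offset = rng.uniform(lo, hi, size=2)
        cand = chain + offset
        if cand.min() >= lo and cand.max() <= hi:
            paths.append(cand)
    signal = _render_paths(shape, pixel_size_A, paths, helix_width_A, axial_repeat_A)
    var_sig = signal.var()
    if math.isinf(snr):
        pixels = signal
    else:
        if snr <= 0:
            raise ValueError("snr must be positive (inf = noiseless)")
        noise_sd = math.sqrt(var_sig / snr)
        pixels = signal + rng.normal(0.0, noise_sd, shape)
    m = Micrograph(pixels, pixel_size_A, source_id=f"synthetic_seed{seed}")
    return SyntheticScene(paths, helix_width_A, axial_repeat_A, snr, seed, m)


# ---------------------------------------------------------------------------
# coordinate files


def write_box(
    ts: TraceSet,
    path,
    box_size_px: int,
    pixel_size_A: float,
    segments: bool = False,
) -> None:
    """Write traces in the EMAN helix-box dialect.

    One line per coordinate: ``x y box box flag`` with corner-based
    x/y in unbinned pixels (centre minus half a box), flag -1 for the
    helix start and -2 for the end.  With ``segments=True`` every
    equidistant coordinate is written (intermediate flag 0).
    """
    half = box_size_px / 2.0
    lines = ["# EMAN helix box coordinates: x y box box flag"]
    for t in ts.traces:
        px = t.coords_A / pixel_size_A - half
        if segments:
            flags = [0] * len(px)
            flags[0], flags[-1] = -1, -2
            rows = zip(px, flags)
        else:
            rows = [(px[0], -1), (px[-1], -2)]
        for (x, y), flag in rows:
            lines.append(f"{x:.0f}\t{y:.0f}\t{box_size_px}\t{box_size_px}\t{flag}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_box(path, pixel_size_A: float, box_size_px: int | None = None) -> list:
    """Read EMAN helix-box coordinates back into Angstrom polylines.

    Consecutive runs from a start flag (-1) to an end flag (-2) become
    one trace; intermediate flag-0 coordinates are kept in order.
    """
    traces = []
    current = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        x, y, bx = float(parts[0]), float(parts[1]), float(parts[2])
        flag = int(parts[4]) if len(parts) > 4 else 0
        centre = (np.array([x, y]) + bx / 2.0) * pixel_size_A
        if flag == -1:
            current = [centre]
        else:
            current.append(centre)
            if flag == -2:
                traces.append(np.array(current))
                current = []
    return traces


def write_relion_coords(ts: TraceSet, path, pixel_size_A: float) -> None:
    """RELION-readable STAR file of per-segment coordinates in unbinned pixels."""
    lines = [
        "",
        "data_",
        "",
        "loop_",
        "_rlnCoordinateX #1",
        "_rlnCoordinateY #2",
        "_rlnHelicalTubeID #3",
    ]
    for tube_id, t in enumerate(ts.traces, start=1):
        for x, y in t.coords_A / pixel_size_A:
            lines.append(f"{x:12.4f} {y:12.4f} {tube_id:6d}")
    Path(path).write_text("\n".join(lines) + "\n")


_PARAM_KEYS = {
    "tile_size_A",
    "overlap_pct",
    "binning_factor",
    "helix_width_A",
    "min_helix_len_A",
    "max_helix_len_A",
    "alpha",
    "prune_n_sigma",
    "segment_spacing_A",
    "angular_step_deg",
    "seed",
}

# warn-only plausibility ranges derived from typical helical specimens
_PARAM_RANGES = {
    "tile_size_A": (200.0, 1000.0),
    "overlap_pct": (0.0, 95.0),
    "binning_factor": (1, 16),
    "alpha": (1e-8, 0.5),
}


def load_config(path) -> TracingParams:
    """Read a ``key: value`` (YAML) tracing configuration file."""
    import yaml

    raw = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(raw) - _PARAM_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key, (lo, hi) in _PARAM_RANGES.items():
        if key in raw and not lo <= raw[key] <= hi:
            log.warning("config %s=%r outside the typical range [%s, %s]",
                        key, raw[key], lo, hi)
    return TracingParams(**raw)
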