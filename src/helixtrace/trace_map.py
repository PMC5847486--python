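"""Continuous correlation map, thresholding, skeleton and branch handling.

Per-tile matches are accumulated additively into a micrograph-shaped
map: each tile contributes a line of its cc-intensity at angle theta,
displaced by delta from the tile centre along the normal, with a
Gaussian falloff of sigma = 2 * tile step both across the line and
beyond its ends.  Tiles that contain a helix reinforce each other into
a continuous ridge; helix-free tiles have low scores and incoherent
angles and stay near the background.

The background values of the map follow an exponential distribution
whose scale is estimated robustly from the median (median of an
exponential with scale lambda is lambda * ln 2).  Thresholding keeps
pixels whose upper-tail p-value under that null is below the
user-chosen significance level alpha.  The binary map is thinned to a
one-pixel skeleton, crossing helices are split by erasing the
neighbourhood of branch points, and ordered pixel paths are extracted.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage
from skimage import morphology

from .preprocess import TileGrid
from .tile_correlation import TileMatch

__all__ = [
    "CorrelationMap",
    "ExponentialNull",
    "SkeletonMap",
    "PixelPath",
    "accumulate_map",
    "fit_null",
    "threshold_map",
    "skeletonize",
    "branch_templates",
    "branch_ring_configs",
    "detect_branch_points",
    "erase_branch_regions",
    "extract_paths",
]


@dataclasses.dataclass
class CorrelationMap:
    values: np.ndarray  # non-negative, binned-micrograph shape
    line_sigma_px: float

    def __post_init__(self):
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise ValueError("correlation map must be finite and non-negative")


@dataclasses.dataclass
class ExponentialNull:
    lambda_scale: float

    def __post_init__(self):
        if not self.lambda_scale > 0:
            raise ValueError("lambda_scale must be positive")

    def threshold(self, alpha: float) -> float:
        """Map value whose upper-tail p-value equals alpha."""
        return self.lambda_scale * np.log(1.0 / alpha)


@dataclasses.dataclass
class SkeletonMap:
    mask: np.ndarray  # boolean, one pixel thin
    provenance: str = ""


@dataclasses.dataclass
class PixelPath:
    """Ordered skeleton pixels of one trace, as (row, col) pairs."""

    rc: np.ndarray
    loop: bool = False

    def contour_length_px(self) -> float:
        if len(self.rc) < 2:
            return 0.0
        steps = np.diff(self.rc.astype(float), axis=0)
        return float(np.hypot(steps[:, 0], steps[:, 1]).sum())


#: transverse standard deviation of a drawn cc-intensity line, pixels.
#: The line marks the helix axis and must stay sharp so that adjacent
#: helices remain separable and thinning recovers the axis; the
#: longitudinal falloff (sigma = 2 * tile step) is what blends the
#: per-tile contributions into a continuous ridge.
LINE_TRANSVERSE_SIGMA_PX = 2.0


def accumulate_map(
    matches: list[TileMatch], grid: TileGrid, shape: tuple[int, int]
) -> CorrelationMap:
    """Draw every tile's cc-intensity line into a single additive map.

    Each line runs at the matched angle through the tile centre
    displaced by delta along the normal; its intensity is the cc-score
    with a Gaussian falloff of sigma = 2 * tile step along the line
    from the adjusted centre (so helix ends fade out rather than
    overshoot) and a sharp transverse profile.  Contributions add, so
    tiles that agree on a helix path reinforce into a continuous ridge
    while incoherent noise tiles do not.
    """
    values = np.zeros(shape)
    t = grid.tile_size_px
    sigma_l = 2.0 * grid.step_px
    sigma_t = LINE_TRANSVERSE_SIGMA_PX
    reach = int(np.ceil(3.0 * sigma_l))
    for match in matches:
        cc = match.cc_score
        if cc <= 0:
            continue
        r0, c0 = grid.origins[match.tile_index]
        cy = r0 + (t - 1) / 2.0
        cx = c0 + (t - 1) / 2.0
        th = np.radians(match.theta_deg)
        dx_axis, dy_axis = np.sin(th), np.cos(th)  # helix axis direction
        nx_, ny_ = np.cos(th), -np.sin(th)  # normal (rotated-frame +x)
        lx = cx + match.delta_px * nx_
        ly = cy + match.delta_px * ny_
        r_lo = max(0, int(ly) - reach)
        r_hi = min(shape[0], int(ly) + reach + 1)
        c_lo = max(0, int(lx) - reach)
        c_hi = min(shape[1], int(lx) + reach + 1)
        if r_lo >= r_hi or c_lo >= c_hi:
            continue
        yy, xx = np.mgrid[r_lo:r_hi, c_lo:c_hi]
        u = (xx - lx) * dx_axis + (yy - ly) * dy_axis  # along the axis
        v = (xx - lx) * nx_ + (yy - ly) * ny_  # normal to the axis
        values[r_lo:r_hi, c_lo:c_hi] += cc * np.exp(
            -u * u / (2.0 * sigma_l * sigma_l) - v * v / (2.0 * sigma_t * sigma_t)
        )
    return CorrelationMap(values, line_sigma_px=sigma_l)


def fit_null(cmap: CorrelationMap) -> ExponentialNull:
    """Exponential background scale from the median of non-zero map values.

    The median is robust to the minority of high values contributed by
    actual helix paths, so the fit holds even on helix-rich maps.
    """
    nz = cmap.values[cmap.values > 0]
    if nz.size <= 100:
        raise ValueError(f"only {nz.size} non-zero map values; cannot fit null")
    return ExponentialNull(float(np.median(nz)) / np.log(2.0))


def threshold_map(
    cmap: CorrelationMap, null: ExponentialNull, alpha: float
) -> np.ndarray:
    """Binary map of pixels significant at level alpha under the null."""
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    return cmap.values > null.threshold(alpha)


def skeletonize(binary: np.ndarray, provenance: str = "") -> SkeletonMap:
    """Morphological thinning to a one-pixel-wide, connectivity-preserving skeleton."""
    return SkeletonMap(morphology.thin(np.asarray(binary, dtype=bool)), provenance)


# Ring of the eight neighbours of a 3x3 centre, in cyclic order.
_RING = [(-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1)]


def _ring_runs(bits: int) -> int:
    """Number of maximal runs of cyclically consecutive set ring positions."""
    ring = [(bits >> i) & 1 for i in range(8)]
    if all(ring):
        return 1
    runs = 0
    for i in range(8):
        if ring[i] and not ring[i - 1]:
            runs += 1
    return runs


def _is_branch_ring(bits: int) -> bool:
    # each run of adjacent set neighbours is one emanating branch; a
    # branch point has >= 3 of them, and a thinned skeleton cannot
    # retain a centre with 5+ set neighbours
    n_set = bin(bits).count("1")
    return n_set <= 4 and _ring_runs(bits) >= 3


def _rotate_ring(bits: int, quarter_turns: int) -> int:
    shift = (2 * quarter_turns) % 8
    return ((bits << shift) | (bits >> (8 - shift))) & 0xFF


def _mirror_ring(bits: int) -> int:
    """Reflection across the vertical axis: ring position i -> 2 - i."""
    out = 0
    for i in range(8):
        if (bits >> i) & 1:
            out |= 1 << ((2 - i) % 8)
    return out


def branch_ring_configs() -> set[int]:
    """All 8-neighbour configurations (bitmasks) that form a branch point."""
    return {bits for bits in range(256) if _is_branch_ring(bits)}


def _bits_to_pattern(bits: int) -> np.ndarray:
    pat = np.zeros((3, 3), dtype=bool)
    pat[1, 1] = True
    for i, (dr, dc) in enumerate(_RING):
        if (bits >> i) & 1:
            pat[1 + dr, 1 + dc] = True
    return pat


def branch_templates() -> list[np.ndarray]:
    """The seven canonical 3x3 junction patterns.

    Exhaustive enumeration over all 256 centre-set neighbourhoods:
    a junction template has exactly three emanating branches (three
    maximal runs of cyclically consecutive set ring neighbours) and at
    most four set neighbours.  Reduced under the four 90-degree
    rotations and the mirror reflections this yields exactly seven
    classes; the full detection lookup expands them by those rotations
    and mirrors and adds the two perfectly symmetric four-branch
    crossings ('+' and 'X'), which are each invariant under every
    rotation and mirror and therefore form no additional classes.
    """
    canonical = set()
    for bits in sorted(branch_ring_configs()):
        if _ring_runs(bits) != 3:
            continue  # the symmetric 4-branch crossings are handled apart
        orbit = set()
        for q in range(4):
            rot = _rotate_ring(bits, q)
            orbit.add(rot)
            orbit.add(_mirror_ring(rot))
        canonical.add(min(orbit))
    return [_bits_to_pattern(bits) for bits in sorted(canonical)]


def _response_kernel() -> np.ndarray:
    """3x3 kernel of powers of two: ring bits 0..7, centre bit 8."""
    k = np.zeros((3, 3))
    for i, (dr, dc) in enumerate(_RING):
        k[1 + dr, 1 + dc] = 1 << i
    k[1, 1] = 1 << 8
    return k


_KERNEL = _response_kernel()
# precomputed convolution responses of all branch configurations
# (centre set), covering every rotation and mirror of the templates
_BRANCH_CODES = frozenset((1 << 8) | bits for bits in branch_ring_configs())


def detect_branch_points(skel: SkeletonMap) -> list[tuple[int, int]]:
    """Locate branch points via the power-of-two convolution response.

    Convolving the binary skeleton with the 2^n kernel assigns every
    pixel a unique code in [0, 511]; pixels whose code is in the
    precomputed branch set are reported.
    """
    codes = ndimage.convolve(
        skel.mask.astype(np.int32), _KERNEL.astype(np.int32), mode="constant"
    )
    lookup = np.zeros(512, dtype=bool)
    lookup[list(_BRANCH_CODES)] = True
    branch = lookup[codes] & skel.mask
    return [tuple(p) for p in np.argwhere(branch)]


def erase_branch_regions(
    skel: SkeletonMap,
    points: list[tuple[int, int]],
    helix_width_A: float,
    pixel_size_A: float,
) -> SkeletonMap:
    """Clear a disc around every branch point, splitting crossing helices."""
    if not points:
        return skel
    radius = helix_width_A / pixel_size_A
    mask = skel.mask.copy()
    r_int = int(np.ceil(radius))
    ny, nx = mask.shape
    for pr, pc in points:
        r_lo, r_hi = max(0, pr - r_int), min(ny, pr + r_int + 1)
        c_lo, c_hi = max(0, pc - r_int), min(nx, pc + r_int + 1)
        yy, xx = np.mgrid[r_lo:r_hi, c_lo:c_hi]
        mask[r_lo:r_hi, c_lo:c_hi] &= (yy - pr) ** 2 + (xx - pc) ** 2 > radius**2
    return SkeletonMap(mask, skel.provenance)


_EIGHT = np.ones((3, 3), dtype=int)


def remove_junction_pixels(skel: SkeletonMap) -> SkeletonMap:
    """Drop any residual pixels with more than two skeleton neighbours.

    After branch erasure the skeleton should be a union of open chains;
    rare junction remnants (e.g. at the rim of an erased disc) are
    removed so that path extraction sees clean chains.  The resulting
    extra fragmentation is handled by the minimum-length filter.
    """
    mask = skel.mask.copy()
    while True:
        neigh = ndimage.convolve(mask.astype(int), _EIGHT, mode="constant") - mask
        bad = mask & (neigh > 2)
        if not bad.any():
            return SkeletonMap(mask, skel.provenance)
        mask &= ~bad


def extract_paths(skel: SkeletonMap) -> list[PixelPath]:
    """Ordered pixel paths of all 8-connected skeleton components.

    Requires a branch-free skeleton: a pixel with three or more
    neighbours raises.  Closed loops are cut at their lexicographically
    smallest pixel and flagged.
    """
    mask = skel.mask
    labels, n = ndimage.label(mask, structure=_EIGHT)
    paths = []
    for lab in range(1, n + 1):
        pix = [tuple(p) for p in np.argwhere(labels == lab)]
        pixset = set(pix)
        neigh = {
            p: [
                (p[0] + dr, p[1] + dc)
                for dr, dc in _RING
                if (p[0] + dr, p[1] + dc) in pixset
            ]
            for p in pix
        }
        degrees = {p: len(v) for p, v in neigh.items()}
        if max(degrees.values()) > 2:
            raise ValueError(
                "skeleton contains a junction pixel; run branch removal first"
            )
        endpoints = sorted(p for p, d in degrees.items() if d <= 1)
        loop = not endpoints
        start = min(pix) if loop else endpoints[0]
        ordered = [start]
        seen = {start}
        cur = start
        while True:
            nxt = [q for q in neigh[cur] if q not in seen]
            if not nxt:
                break
            cur = nxt[0]
            ordered.append(cur)
            seen.add(cur)
        paths.append(PixelPath(np.array(ordered, dtype=int), loop=loop))
    return paths
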