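"""Per-tile helix angle and shift determination.

Within a 350-500 A tile a helix is well approximated by a straight
line, so its position is fully described by the in-plane angle theta of
the helix axis and the signed offset delta of the axis from the tile
centre, measured normal to the axis.  The search is split in two:

* theta comes from a rotational correlation between the power spectra
  of the tile and of the reference (layer lines make the spectrum
  orientation-sensitive while the squared modulus is translation
  invariant), and
* delta and the cc-score come from a single real-space normalized
  cross-correlation between the tile rotated by -theta and the
  reference, of which only the component normal to the (now vertical)
  helix axis is kept.

Angle convention: theta in degrees in [0, 180); the helix axis
direction in (x = col, y = row) coordinates is (sin theta, cos theta),
so theta = 0 is a vertical filament.  Power spectra of real images are
Friedel-symmetric, hence theta and theta + 180 are indistinguishable.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy import ndimage

from .preprocess import Micrograph, TileGrid, extract_tile, power_spectrum

__all__ = [
    "TileMatch",
    "RotationalMatcher",
    "rotational_correlation",
    "translational_match",
    "match_all_tiles",
]

log = logging.getLogger(__name__)

#: radius (in Fourier pixels) of the low-frequency disc excluded from
#: the rotational correlation; the central peak carries no orientation.
LOW_FREQ_EXCLUSION_PX = 2


@dataclasses.dataclass
class TileMatch:
    tile_index: int
    theta_deg: float
    delta_px: float
    cc_score: float

    def __post_init__(self):
        if not 0 <= self.theta_deg < 180:
            raise ValueError("theta_deg must lie in [0, 180)")
        if not -1.0 - 1e-9 <= self.cc_score <= 1.0 + 1e-9:
            raise ValueError("cc_score must lie in [-1, 1]")


def _annulus_mask(n: int) -> np.ndarray:
    """Valid Fourier pixels: outside the DC disc, inside Nyquist.

    The outer radius stays one pixel inside n/2 so that the whole ring
    (centred on the DC pixel at n//2) lies inside the array for every
    rotation angle; otherwise the ring would sample the zero padding
    angle-dependently.
    """
    c = n // 2
    yy, xx = np.mgrid[0:n, 0:n]
    r = np.hypot(yy - c, xx - c)
    return (r > LOW_FREQ_EXCLUSION_PX) & (r <= n / 2 - 1)


#: Gaussian blur (Fourier pixels) applied identically to the reference
#: stack and to tile spectra before correlation.  Without it the
#: unrotated (interpolation-free) stack entries are systematically
#: sharper than bilinear-rotated ones, which biases the angle search
#: toward 0/90 degrees on noisy tiles.
SPECTRUM_SMOOTH_SIGMA_PX = 1.0


def _log_scale(ps: np.ndarray) -> np.ndarray:
    # log compression tames the huge dynamic range of power spectra so
    # the correlation is not dominated by a handful of strong pixels
    return ndimage.gaussian_filter(np.log1p(ps), SPECTRUM_SMOOTH_SIGMA_PX)


def _rotate_spectrum(ps: np.ndarray, angle_deg: float) -> np.ndarray:
    """Bilinear rotation about the zero-frequency pixel.

    After fftshift the DC of an even-sized spectrum sits at (n//2,
    n//2), half a pixel off the geometric array centre that
    ``ndimage.rotate`` would use; rotating about the wrong point
    translates the whole spectrum for large angles.
    """
    if angle_deg == 0:
        return ps
    n = ps.shape[0]
    c = np.array([n // 2, n // 2], dtype=float)
    t = np.radians(angle_deg)
    # matches ndimage.rotate's direction for the (row, col) plane
    rot = np.array([[np.cos(t), np.sin(t)], [-np.sin(t), np.cos(t)]])
    return ndimage.affine_transform(
        ps, rot, offset=c - rot @ c, order=1, mode="constant"
    )


class RotationalMatcher:
    """Precomputed rotated reference spectra for fast per-tile angle search."""

    def __init__(self, ref_ps: np.ndarray, angular_step_deg: float = 1.0):
        if ref_ps.shape[0] != ref_ps.shape[1]:
            raise ValueError("power spectra must be square")
        if not np.any(ref_ps):
            raise ValueError("all-zero reference power spectrum: angle undefined")
        n = ref_ps.shape[0]
        self.mask = _annulus_mask(n)
        self.angles = np.arange(0.0, 180.0, angular_step_deg)
        base = _log_scale(ref_ps)
        rows = []
        for a in self.angles:
            rot = _rotate_spectrum(base, a)
            v = rot[self.mask]
            v = v - v.mean()
            norm = np.linalg.norm(v)
            rows.append(v / norm if norm > 0 else v)
        self._stack = np.array(rows)  # (n_angles, n_mask_px)

    def match(self, tile_ps: np.ndarray) -> float:
        """Best-correlating angle of the tile spectrum, degrees in [0, 180)."""
        if not np.any(tile_ps):
            raise ValueError("all-zero tile power spectrum: angle undefined")
        v = _log_scale(tile_ps)[self.mask]
        v = v - v.mean()
        norm = np.linalg.norm(v)
        if norm > 0:
            v = v / norm
        scores = self._stack @ v
        # ties broken toward the smallest angle (argmax returns first max)
        return float(self.angles[int(np.argmax(scores))])


def rotational_correlation(
    tile_ps: np.ndarray, ref_ps: np.ndarray, angular_step_deg: float = 1.0
) -> float:
    """One-shot angle search; see :class:`RotationalMatcher` for batch use."""
    return RotationalMatcher(ref_ps, angular_step_deg).match(tile_ps)


def translational_match(
    tile: np.ndarray, theta_deg: float, ref_image: np.ndarray
) -> tuple[float, float]:
    """Shift normal to the helix axis and cc-score for one tile.

    The tile is rotated by ``-theta`` so its helix axis is vertical
    like the reference, and a normalized cross-correlation is computed
    via FFT.  Only the x component of the peak shift (the component
    normal to the vertical axis) is returned, at integer precision; of
    equal maxima the one with the smallest ``|dx|`` wins.
    """
    if tile.shape != ref_image.shape:
        raise ValueError("tile and reference must have the same shape")
    n = tile.shape[0]
    t = tile if theta_deg == 0 else ndimage.rotate(tile, -theta_deg, reshape=False, order=1)
    t = t - t.mean()
    r = ref_image - ref_image.mean()
    denom = np.linalg.norm(t) * np.linalg.norm(r)
    if denom == 0:
        return 0.0, 0.0
    cc = np.fft.ifft2(np.fft.fft2(t) * np.conj(np.fft.fft2(r))).real / denom
    cc = np.fft.fftshift(cc)  # displacement 0 at the array centre
    peak = cc.max()
    ys, xs = np.nonzero(cc == peak)
    dx = xs - n // 2
    dy = ys - n // 2
    keep = np.abs(dx) <= n / 2
    dx, dy = dx[keep], dy[keep]
    best = int(np.argmin(np.abs(dx)))
    return float(dx[best]), float(min(max(peak, -1.0), 1.0))


#: half-width, in angular steps, of the local real-space refinement
#: around the power-spectrum angle estimate
ANGLE_REFINE_STEPS = 3


def match_tile(
    tile: np.ndarray,
    matcher: RotationalMatcher,
    ref_image: np.ndarray,
    refine_steps: int = ANGLE_REFINE_STEPS,
) -> tuple[float, float, float]:
    """(theta, delta, cc) for one extracted tile.

    The power-spectrum rotational correlation provides a coarse angle;
    the real-space cross-correlation is then evaluated at
    ``2 * refine_steps + 1`` angles around it and the best-scoring one
    is kept, so the factorized search lands on the same optimum as an
    exhaustive joint search over (theta, x, y).
    """
    theta0 = matcher.match(power_spectrum(tile))
    step = float(matcher.angles[1] - matcher.angles[0]) if len(matcher.angles) > 1 else 1.0
    best = (-np.inf, 0.0, 0.0)
    for k in range(-refine_steps, refine_steps + 1):
        theta = (theta0 + k * step) % 180.0
        delta, cc = translational_match(tile, theta, ref_image)
        if cc > best[0] or (cc == best[0] and theta < best[1]):
            best = (cc, theta, delta)
    cc, theta, delta = best
    return theta, delta, cc


def match_all_tiles(
    m: Micrograph,
    grid: TileGrid,
    ref_image: np.ndarray,
    ref_ps: np.ndarray,
    angular_step_deg: float = 1.0,
) -> list[TileMatch]:
    """Angle/shift/score for every tile of the grid.

    Tiles are processed independently; the output does not depend on
    the processing order.  A tile that fails (e.g. zero variance)
    contributes a cc-score of 0 with a logged warning.
    """
    matcher = RotationalMatcher(ref_ps, angular_step_deg)
    matches = []
    for i, origin in enumerate(grid.origins):
        try:
            tile = extract_tile(m, origin, grid)
            theta, delta, cc = match_tile(tile, matcher, ref_image)
        except ValueError as exc:
            log.warning("tile %d at %s skipped: %s", i, origin, exc)
            theta, delta, cc = 0.0, 0.0, 0.0
        matches.append(TileMatch(i, theta, delta, cc))
    return matches
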