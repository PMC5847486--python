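"""Micrograph preparation: normalization, binning, filtering and tiling.

Filaments are located by correlating small overlapping windows (tiles)
of the micrograph against a reference helix image whose axis is
vertical.  This module owns everything that happens before the
correlation itself: reading images, block binning, the Gaussian
high-pass that removes gray-scale ramps, robust suppression of extreme
dark pixels (gold, ice), the overlapping tile grid, and the circular
Gaussian tile mask that improves separation of closely packed helices.

Coordinate convention: 0-based pixel indices, origin at the top-left,
``x`` = column, ``y`` = row.  Physical coordinates in Angstrom are
``pixel index * pixel_size_A`` of the working (possibly binned) image.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
from scipy import stats

from . import mrc

__all__ = [
    "Micrograph",
    "ReferenceHelix",
    "TracingParams",
    "TileGrid",
    "load_micrograph",
    "normalize_and_bin",
    "highpass",
    "suppress_outliers",
    "make_tile_grid",
    "extract_tile",
    "prepare_reference",
]


@dataclasses.dataclass
class Micrograph:
    """A 2-D gray-scale image with its pixel size in Angstrom."""

    pixels: np.ndarray
    pixel_size_A: float
    source_id: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("micrograph must be a 2-D image")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("micrograph contains non-finite pixels")
        if self.pixel_size_A <= 0:
            raise ValueError("pixel_size_A must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclasses.dataclass
class ReferenceHelix:
    """Reference helix image with the helix axis aligned vertically."""

    pixels: np.ndarray
    pixel_size_A: float
    helix_width_A: float

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.helix_width_A <= 0:
            raise ValueError("helix_width_A must be positive")


@dataclasses.dataclass
class TracingParams:
    """User-facing tracing parameters.

    ``tile_size_A`` of 350-500 A with 80 % overlap gives effective tile
    steps of 70-100 A, comparable to the half-width of typical helical
    specimens.  ``alpha`` is the significance level applied to the
    exponential null distribution of the correlation map.
    """

    tile_size_A: float = 500.0
    overlap_pct: float = 80.0
    binning_factor: int = 1
    helix_width_A: float = 100.0
    min_helix_len_A: float = 500.0
    max_helix_len_A: float = 1500.0
    alpha: float = 0.001
    prune_n_sigma: float = 2.0
    segment_spacing_A: float = 70.0
    angular_step_deg: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.overlap_pct < 100:
            raise ValueError("overlap_pct must be in [0, 100)")
        if not self.min_helix_len_A < self.max_helix_len_A:
            raise ValueError("min_helix_len_A must be below max_helix_len_A")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if self.binning_factor < 1:
            raise ValueError("binning_factor must be >= 1")


@dataclasses.dataclass
class TileGrid:
    """Row-major grid of overlapping square tile origins."""

    tile_size_px: int
    step_px: int
    origins: list  # (row, col) of tile top-left corners
    mask_sigma_px: float

    def __post_init__(self):
        if self.step_px < 1:
            raise ValueError("step_px must be >= 1")


def load_micrograph(path, pixel_size_A: float | None = None) -> Micrograph:
    """Read a micrograph from MRC (preferred) or 8/16-bit gray-scale image.

    The pixel size is taken from the MRC header when present, otherwise
    from ``pixel_size_A``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".mrc", ".mrcs", ".map"):
        pixels, header_apix = mrc.read_mrc(path)
        apix = header_apix if header_apix > 0 else pixel_size_A
        if apix is None or apix <= 0:
            raise ValueError(f"{path}: no pixel size in header; pass pixel_size_A")
    else:
        from PIL import Image

        with Image.open(path) as im:
            pixels = np.asarray(im.convert("F"), dtype=np.float64)
        if pixel_size_A is None or pixel_size_A <= 0:
            raise ValueError(f"{path}: pixel_size_A required for non-MRC images")
        apix = pixel_size_A
    return Micrograph(pixels, float(apix), source_id=path.stem)


def _normalize(pixels: np.ndarray) -> np.ndarray:
    sd = pixels.std()
    if sd == 0:
        sd = 1.0  # constant image: define SD = 1, output is all zeros
    return (pixels - pixels.mean()) / sd


def normalize_and_bin(m: Micrograph, binning_factor: int) -> Micrograph:
    """Block-average by an integer factor and normalize to zero mean, unit SD.

    Remainder rows/columns that do not fill a block are dropped.  The
    pixel size grows by the binning factor.
    """
    b = int(binning_factor)
    if b < 1:
        raise ValueError("binning_factor must be >= 1")
    ny, nx = m.pixels.shape
    if b > min(ny, nx):
        raise ValueError("binning factor exceeds image dimensions")
    ny_b, nx_b = ny // b, nx // b
    binned = m.pixels[: ny_b * b, : nx_b * b].reshape(ny_b, b, nx_b, b).mean(axis=(1, 3))
    return Micrograph(_normalize(binned), m.pixel_size_A * b, m.source_id)


def highpass(m: Micrograph) -> Micrograph:
    """Gaussian high-pass with half-maximum gain at 4 % of Nyquist.

    The Fourier gain is ``G(k) = 1 - exp(-k^2 / (2 sigma_f^2))`` with
    ``sigma_f = k0 / sqrt(2 ln 2)`` and ``k0 = 0.04 * k_Nyquist``, so
    that G(0) = 0 (ramps and DC removed) and G(k0) = 1/2 exactly.
    """
    ny, nx = m.pixels.shape
    k_nyq = 0.5  # cycles / pixel
    k0 = 0.04 * k_nyq
    sigma_f = k0 / np.sqrt(2.0 * np.log(2.0))
    ky = np.fft.fftfreq(ny)[:, None]
    kx = np.fft.fftfreq(nx)[None, :]
    k2 = kx * kx + ky * ky
    gain = 1.0 - np.exp(-k2 / (2.0 * sigma_f**2))
    filtered = np.fft.ifft2(np.fft.fft2(m.pixels) * gain).real
    return Micrograph(filtered, m.pixel_size_A, m.source_id)


def suppress_outliers(
    m: Micrograph, p_cut: float = 0.001, symmetric: bool = False
) -> Micrograph:
    """Replace extreme dark pixels (gold particles, ice) by the median.

    A normal model is fitted robustly with location = median and scale
    = 1.4826 * MAD; pixels whose lower-tail p-value under that model is
    below ``p_cut`` are set to the median.  With ``symmetric=True`` the
    bright tail is clipped as well (off by default: the artefacts of
    interest are very dark).  A constant image (MAD = 0) is returned
    unchanged.
    """
    med = float(np.median(m.pixels))
    mad = float(np.median(np.abs(m.pixels - med)))
    if mad == 0:
        return m
    scale = 1.4826 * mad
    z = (m.pixels - med) / scale
    cut = stats.norm.ppf(p_cut)  # negative
    bad = z < cut
    if symmetric:
        bad |= z > -cut
    cleaned = m.pixels.copy()
    cleaned[bad] = med
    return Micrograph(cleaned, m.pixel_size_A, m.source_id)


def make_tile_grid(
    shape: tuple[int, int], params: TracingParams, pixel_size_A: float
) -> TileGrid:
    """Build the overlapping tile grid covering the whole image.

    The last tile of each row/column is clamped so it ends exactly on
    the image edge; partial tiles are never produced and helices near
    edges remain traceable.
    """
    tile_px = int(round(params.tile_size_A / pixel_size_A))
    if tile_px > min(shape):
        raise ValueError(
            f"tile size {tile_px} px exceeds image dimensions {shape}"
        )
    step_px = max(1, int(round(tile_px * (1.0 - params.overlap_pct / 100.0))))

    def _axis_origins(extent: int) -> list[int]:
        origins = list(range(0, extent - tile_px + 1, step_px))
        if origins[-1] != extent - tile_px:
            origins.append(extent - tile_px)
        return origins

    rows = _axis_origins(shape[0])
    cols = _axis_origins(shape[1])
    origins = [(r, c) for r in rows for c in cols]
    return TileGrid(tile_px, step_px, origins, mask_sigma_px=1.41 * step_px)


def gaussian_tile_mask(tile_size_px: int, sigma_px: float) -> np.ndarray:
    """Circular Gaussian mask centred on the tile, value 1 at the centre."""
    c = (tile_size_px - 1) / 2.0
    yy, xx = np.mgrid[0:tile_size_px, 0:tile_size_px]
    r2 = (xx - c) ** 2 + (yy - c) ** 2
    return np.exp(-r2 / (2.0 * sigma_px**2))


def extract_tile(m: Micrograph, origin: tuple[int, int], grid: TileGrid) -> np.ndarray:
    """Cut one tile, subtract its mean and apply the Gaussian mask."""
    r, c = origin
    t = grid.tile_size_px
    tile = m.pixels[r : r + t, c : c + t]
    if tile.shape != (t, t):
        raise ValueError(f"origin {origin} does not yield a full {t}x{t} tile")
    tile = tile - tile.mean()
    return tile * gaussian_tile_mask(t, grid.mask_sigma_px)


def power_spectrum(image: np.ndarray) -> np.ndarray:
    """Squared Fourier modulus, zero frequency at the array centre."""
    return np.abs(np.fft.fftshift(np.fft.fft2(image))) ** 2


def prepare_reference(
    ref: ReferenceHelix, grid: TileGrid, pixel_size_A: float
) -> tuple[np.ndarray, np.ndarray]:
    """Pad/crop the reference into a masked tile and compute its power spectrum.

    The reference is resampled when its pixel size differs from the
    working one, centred in a ``tile_size_px`` square, mean-subtracted
    and masked exactly like micrograph tiles.
    """
    pixels = ref.pixels
    if abs(ref.pixel_size_A - pixel_size_A) > 1e-9:
        from scipy import ndimage

        zoom = ref.pixel_size_A / pixel_size_A
        pixels = ndimage.zoom(pixels, zoom, order=1)
    t = grid.tile_size_px
    if ref.helix_width_A / pixel_size_A > t:
        raise ValueError("reference helix is wider than the tile")
    canvas = np.zeros((t, t))
    ny, nx = pixels.shape
    # crop symmetrically when larger, centre when smaller
    r0 = max(0, (ny - t) // 2)
    c0 = max(0, (nx - t) // 2)
    src = pixels[r0 : r0 + t, c0 : c0 + t]
    dr = (t - src.shape[0]) // 2
    dc = (t - src.shape[1]) // 2
    canvas[dr : dr + src.shape[0], dc : dc + src.shape[1]] = src
    canvas -= canvas.mean()
    canvas *= gaussian_tile_mask(t, grid.mask_sigma_px)
    return canvas, power_spectrum(canvas)
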