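import numpy as np
import pytest

from helixtrace.app_io import _render_paths, render_reference
from helixtrace.preprocess import Micrograph, TracingParams, make_tile_grid


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def parm_like_params():
    """Tracing parameters in the typical range for a thin filament."""
    return TracingParams(
        tile_size_A=400.0,
        overlap_pct=80.0,
        binning_factor=2,
        helix_width_A=100.0,
        min_helix_len_A=600.0,
        max_helix_len_A=1500.0,
        alpha=0.001,
    )


def render_filament_tile(
    size_px: int,
    pixel_size_A: float,
    theta_deg: float,
    delta_px: float,
    helix_width_A: float = 100.0,
    axial_repeat_A: float = 50.0,
) -> np.ndarray:
    """Straight synthetic filament through a tile.

    The filament axis has direction (sin theta, cos theta) in (x, y)
    and passes through the tile centre displaced by ``delta_px`` along
    the normal (cos theta, -sin theta), matching the tile-matching
    convention.
    """
    c = (size_px - 1) / 2.0 * pixel_size_A
    t = np.radians(theta_deg)
    d = np.array([np.sin(t), np.cos(t)])
    n = np.array([np.cos(t), -np.sin(t)])
    centre = np.array([c, c]) + delta_px * pixel_size_A * n
    span = 2.0 * size_px * pixel_size_A
    path = np.array([centre - span * d, centre + span * d])
    return _render_paths(
        (size_px, size_px), pixel_size_A, [path], helix_width_A, axial_repeat_A
    )


@pytest.fixture
def filament_tile_factory():
    return render_filament_tile


@pytest.fixture
def small_reference():
    """Clean vertical reference matching an 8 A working pixel size."""
    return render_reference(100.0, 50.0, 50, 8.0)
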