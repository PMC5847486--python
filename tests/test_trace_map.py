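"""Correlation map accumulation, exponential null, skeleton, branches."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from helixtrace.preprocess import TracingParams, make_tile_grid
from helixtrace.tile_correlation import TileMatch
from helixtrace.trace_map import (
    _RING,
    CorrelationMap,
    SkeletonMap,
    accumulate_map,
    branch_ring_configs,
    branch_templates,
    detect_branch_points,
    erase_branch_regions,
    extract_paths,
    fit_null,
    remove_junction_pixels,
    skeletonize,
    threshold_map,
)


def _grid(shape=(120, 120), tile_A=100.0, overlap=80.0):
    return make_tile_grid(shape, TracingParams(tile_size_A=tile_A, overlap_pct=overlap), 1.0)


class TestAccumulateMap:
    def test_empty_matches_give_zero_map(self):
        g = _grid()
        cmap = accumulate_map([], g, (120, 120))
        assert not np.any(cmap.values)

    def test_single_match_peaks_at_adjusted_centre(self):
        g = _grid()
        cmap = accumulate_map([TileMatch(0, 0.0, 0.0, 1.0)], g, (120, 120))
        r, c = np.unravel_index(np.argmax(cmap.values), cmap.values.shape)
        # tile 0 spans [0, 100); its centre is at 49.5
        assert abs(r - 49.5) <= 1 and abs(c - 49.5) <= 1
        # vertical line: transverse decay away from the centre column
        peak_col = cmap.values[:, c].max()
        assert cmap.values[49, c + 10] < 0.01 * peak_col

    def test_delta_displaces_line_along_normal(self):
        g = _grid()
        cmap = accumulate_map([TileMatch(0, 0.0, 10.0, 1.0)], g, (120, 120))
        _, c = np.unravel_index(np.argmax(cmap.values), cmap.values.shape)
        # theta=0 normal is +x, so the line shifts 10 px in columns
        assert abs(c - 59.5) <= 1

    def test_collinear_neighbours_reinforce_midpoint(self):
        g = _grid()
        # two vertically adjacent tiles (origins (0,0) and (20,0)),
        # both matching a vertical helix through their centres
        i_a = g.origins.index((0, 0))
        i_b = g.origins.index((20, 0))
        both = accumulate_map(
            [TileMatch(i_a, 0.0, 0.0, 1.0), TileMatch(i_b, 0.0, 0.0, 1.0)],
            g, (120, 120),
        )
        alone_a = accumulate_map([TileMatch(i_a, 0.0, 0.0, 1.0)], g, (120, 120))
        alone_b = accumulate_map([TileMatch(i_b, 0.0, 0.0, 1.0)], g, (120, 120))
        mid = (59, 49)  # between the two tile centres, on the shared axis
        assert both.values[mid] > alone_a.values[mid]
        assert both.values[mid] > alone_b.values[mid]
        assert both.values[mid] == pytest.approx(
            alone_a.values[mid] + alone_b.values[mid]
        )


class TestExponentialNull:
    def test_constant_values_give_median_over_ln2(self):
        v = np.zeros((50, 50))
        v[:10] = 3.0
        null = fit_null(CorrelationMap(v, 2.0))
        assert null.lambda_scale == pytest.approx(3.0 / np.log(2))

    def test_recovers_known_exponential_scale(self, rng):
        v = rng.exponential(2.0, (1000, 1000))
        null = fit_null(CorrelationMap(v, 2.0))
        assert null.lambda_scale == pytest.approx(2.0, rel=0.01)

    def test_robust_to_high_outliers(self, rng):
        """5% of 100x outliers barely move the median-based estimate.

        The contaminated median solves
        0.95 (1 - exp(-x/2)) + 0.05 (1 - exp(-x/200)) = 1/2,
        i.e. x ~ 1.4927 and lambda ~ 2.1536: an 8% shift, where a
        mean-based estimate would be off sixfold.
        """
        v = rng.exponential(2.0, 10**6)
        idx = rng.choice(v.size, v.size // 20, replace=False)
        v[idx] *= 100
        null = fit_null(CorrelationMap(v.reshape(1000, 1000), 2.0))
        assert null.lambda_scale == pytest.approx(2.1536, rel=0.01)
        assert abs(null.lambda_scale - 2.0) / 2.0 < 0.08
        assert abs(v.mean() - 2.0) / 2.0 > 2.0  # the non-robust alternative

    def test_too_few_values_rejected(self):
        v = np.zeros((20, 20))
        v[0, :5] = 1.0
        with pytest.raises(ValueError, match="non-zero"):
            fit_null(CorrelationMap(v, 2.0))


class TestThresholdMap:
    def test_closed_form_cutoff(self):
        from helixtrace.trace_map import ExponentialNull

        null = ExponentialNull(1.0)
        assert null.threshold(0.001) == pytest.approx(np.log(1000), abs=1e-4)
        v = np.array([[6.90, 6.92]])
        out = threshold_map(CorrelationMap(v, 1.0), null, 0.001)
        assert out.tolist() == [[False, True]]

    def test_alpha_one_keeps_every_nonzero_pixel(self, rng):
        from helixtrace.trace_map import ExponentialNull

        v = rng.exponential(1.0, (50, 50))
        v[0, 0] = 0.0
        out = threshold_map(CorrelationMap(v, 1.0), ExponentialNull(1.0), 1.0)
        assert out.sum() == v.size - 1

    def test_false_positive_calibration(self, rng):
        from helixtrace.trace_map import ExponentialNull

        alpha = 0.001
        v = rng.exponential(1.7, (1000, 1000))
        out = threshold_map(CorrelationMap(v, 1.0), ExponentialNull(1.7), alpha)
        frac = out.mean()
        se = np.sqrt(alpha * (1 - alpha) / v.size)
        assert abs(frac - alpha) < 3 * se

    @given(a1=st.floats(1e-4, 0.5), a2=st.floats(1e-4, 0.5))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_threshold_monotone_in_alpha(self, a1, a2):
        from helixtrace.trace_map import ExponentialNull

        rng = np.random.default_rng(0)
        v = rng.exponential(1.0, (100, 100))
        null = ExponentialNull(1.0)
        lo, hi = sorted([a1, a2])
        small = threshold_map(CorrelationMap(v, 1.0), null, lo)
        large = threshold_map(CorrelationMap(v, 1.0), null, hi)
        assert not np.any(small & ~large)


def _random_blobs(rng, shape=(80, 80), n=5):
    img = np.zeros(shape, dtype=bool)
    for _ in range(n):
        r, c = rng.integers(10, shape[0] - 10, 2)
        rad = int(rng.integers(2, 7))
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        img |= (yy - r) ** 2 + (xx - c) ** 2 <= rad**2
    return img


class TestSkeletonize:
    def test_bar_reduces_to_single_path(self):
        img = np.zeros((20, 60), dtype=bool)
        img[8:13, 10:50] = True
        sk = skeletonize(img).mask
        paths = extract_paths(remove_junction_pixels(SkeletonMap(sk)))
        assert len(paths) == 1
        ends = paths[0].rc[[0, -1]]
        assert abs(ends[:, 1].min() - 10) <= 3
        assert abs(ends[:, 1].max() - 49) <= 3

    def test_one_pixel_line_unchanged(self):
        img = np.zeros((10, 30), dtype=bool)
        img[5, 3:27] = True
        assert np.array_equal(skeletonize(img).mask, img)

    def test_thinness_no_full_2x2_block(self, rng):
        for _ in range(20):
            sk = skeletonize(_random_blobs(rng)).mask
            stacked = sk[:-1, :-1] & sk[1:, :-1] & sk[:-1, 1:] & sk[1:, 1:]
            assert not stacked.any()

    def test_component_count_preserved(self, rng):
        eight = np.ones((3, 3), dtype=int)
        for _ in range(100):
            img = _random_blobs(rng)
            _, n_before = ndimage.label(img, structure=eight)
            _, n_after = ndimage.label(skeletonize(img).mask, structure=eight)
            assert n_after == n_before

    def test_skeleton_subset_of_input(self, rng):
        img = _random_blobs(rng)
        sk = skeletonize(img).mask
        assert not np.any(sk & ~img)


class TestBranchTemplates:
    def test_exactly_seven_canonical_templates(self):
        assert len(branch_templates()) == 7

    def test_straight_line_neighbourhoods_excluded(self):
        # two opposite neighbours = 2 runs: not a branch
        for bits in (0b00100010, 0b01000100, 0b00010001):
            assert bits not in branch_ring_configs()

    def test_plus_and_x_are_distinct_detection_patterns(self):
        plus = sum(1 << i for i, (dr, dc) in enumerate(_RING) if abs(dr) + abs(dc) == 1)
        x = sum(1 << i for i, (dr, dc) in enumerate(_RING) if abs(dr) + abs(dc) == 2)
        configs = branch_ring_configs()
        assert plus in configs and x in configs and plus != x

    def test_templates_have_three_branches_and_at_most_four_neighbours(self):
        for pat in branch_templates():
            assert pat[1, 1]
            assert 3 <= pat.sum() - 1 <= 4


class TestDetectBranchPoints:
    def test_plus_sign_centre_reported(self):
        sk = np.zeros((9, 9), dtype=bool)
        sk[4, :] = True
        sk[:, 4] = True
        assert detect_branch_points(SkeletonMap(sk)) == [(4, 4)]

    def test_curved_line_has_no_branch_points(self):
        sk = np.zeros((30, 30), dtype=bool)
        for c in range(25):
            sk[10 + (c // 7), c] = True
        assert detect_branch_points(SkeletonMap(sk)) == []

    def test_matches_run_counting_oracle(self, rng):
        """Convolution-code detection equals per-pixel run counting."""
        from helixtrace.trace_map import _ring_runs

        for _ in range(100):
            sk = skeletonize(_random_blobs(rng, n=8)).mask
            detected = set(detect_branch_points(SkeletonMap(sk)))
            oracle = set()
            padded = np.pad(sk, 1)
            for r, c in np.argwhere(sk):
                bits = 0
                for i, (dr, dc) in enumerate(_RING):
                    if padded[r + 1 + dr, c + 1 + dc]:
                        bits |= 1 << i
                n_set = bin(bits).count("1")
                if n_set <= 4 and _ring_runs(bits) >= 3:
                    oracle.add((r, c))
            assert detected == oracle


class TestEraseBranchRegions:
    def test_plus_splits_into_four_arms(self):
        sk = np.zeros((41, 41), dtype=bool)
        sk[20, :] = True
        sk[:, 20] = True
        points = detect_branch_points(SkeletonMap(sk))
        out = erase_branch_regions(SkeletonMap(sk), points, 10.0, 1.0)
        _, n = ndimage.label(out.mask, structure=np.ones((3, 3), dtype=int))
        assert n == 4

    def test_no_points_is_identity(self):
        sk = SkeletonMap(np.eye(10, dtype=bool))
        assert erase_branch_regions(sk, [], 10.0, 1.0) is sk

    def test_x_crossing_of_synthetic_traces(self):
        sk = np.zeros((41, 41), dtype=bool)
        idx = np.arange(41)
        sk[idx, idx] = True
        sk[idx, 40 - idx] = True
        points = detect_branch_points(SkeletonMap(sk))
        assert points  # the crossing is found
        out = erase_branch_regions(SkeletonMap(sk), points, 6.0, 1.0)
        _, n = ndimage.label(out.mask, structure=np.ones((3, 3), dtype=int))
        assert n == 4


class TestExtractPaths:
    def test_horizontal_line_counts(self):
        sk = np.zeros((10, 50), dtype=bool)
        sk[5, 3:44] = True
        paths = extract_paths(SkeletonMap(sk))
        assert len(paths) == 1
        assert len(paths[0].rc) == 41
        assert paths[0].contour_length_px() == pytest.approx(40.0)

    def test_diagonal_line_sqrt2_steps(self):
        sk = np.zeros((50, 50), dtype=bool)
        idx = np.arange(41)
        sk[idx, idx] = True
        paths = extract_paths(SkeletonMap(sk))
        assert paths[0].contour_length_px() == pytest.approx(40 * np.sqrt(2))

    def test_consecutive_pixels_are_8_neighbours(self, rng):
        for _ in range(20):
            sk = skeletonize(_random_blobs(rng)).mask
            points = detect_branch_points(SkeletonMap(sk))
            clean = remove_junction_pixels(
                erase_branch_regions(SkeletonMap(sk), points, 3.0, 1.0)
            )
            for path in extract_paths(clean):
                steps = np.abs(np.diff(path.rc, axis=0))
                assert np.all(steps.max(axis=1) == 1)

    def test_loop_is_cut_and_flagged(self):
        # a diamond ring: every pixel has exactly two 8-neighbours
        yy, xx = np.mgrid[0:21, 0:21]
        sk = np.abs(yy - 10) + np.abs(xx - 10) == 6
        paths = extract_paths(SkeletonMap(sk))
        assert len(paths) == 1
        assert paths[0].loop
        assert len(paths[0].rc) == sk.sum()

    def test_junction_pixel_raises(self):
        sk = np.zeros((9, 9), dtype=bool)
        sk[4, :] = True
        sk[:4, 4] = True
        with pytest.raises(ValueError, match="junction"):
            extract_paths(SkeletonMap(sk))
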