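import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from visearch import stimgen
from visearch.stimgen import (
    DEFAULT_THETA,
    EXP1_GRID,
    EXP2_GRID,
    DifficultyMap,
    GridSpec,
    OrientationRangeMapping,
    TargetSpec,
    cell_difficulties,
    eligible_target_cells,
    equalize_to_parabola,
    generate_noise_field,
    make_jumbled,
    make_split_half,
    make_uniform,
    orientation_in_interval,
    parabola_cdf,
    place_target,
    range_from_difficulty,
    render_stimulus,
    sample_orientation_grid,
    split_hard_mask,
)


def radial_log_power_slope(values):
    """Independent periodogram oracle: slope of log power vs log frequency."""
    centred = values - values.mean()
    power = np.abs(np.fft.fft2(centred)) ** 2
    fy = np.fft.fftfreq(values.shape[0])
    fx = np.fft.fftfreq(values.shape[1])
    f = np.hypot(fx[None, :], fy[:, None])
    mask = (f > 0.01) & (f < 0.25) & (power > 0)
    return np.polyfit(np.log(f[mask]), np.log(power[mask]), 1)[0]


class TestGridSpec:
    def test_extent_and_centre(self):
        grid = GridSpec(4, 2, 10, origin_px=(5, 7))
        assert grid.extent_px == (40, 20)
        assert grid.centre_px == (25.0, 17.0)

    def test_cell_lookup_half_open(self):
        grid = GridSpec(4, 2, 10)
        assert grid.cell_at(0, 0) == (0, 0)
        assert grid.cell_at(39.999, 19.999) == (3, 1)
        assert grid.cell_at(40, 10) is None

    @pytest.mark.parametrize("bad", [dict(n_cols=1), dict(n_rows=1), dict(cell_px=0)])
    def test_invalid(self, bad):
        kwargs = dict(n_cols=4, n_rows=4, cell_px=8)
        kwargs.update(bad)
        with pytest.raises(ValueError):
            GridSpec(**kwargs)

    def test_default_grids(self):
        assert (EXP1_GRID.n_cols, EXP1_GRID.n_rows) == (22, 16)
        assert EXP1_GRID.extent_px == (704, 512)
        assert (EXP2_GRID.n_cols, EXP2_GRID.n_rows) == (32, 24)
        assert EXP2_GRID.extent_px == (1024, 768)


class TestNoiseField:
    def test_shape_and_range(self):
        field = generate_noise_field((1024, 768), seed=0)
        assert (field.width_px, field.height_px) == (1024, 768)
        assert field.values.min() == 0.0
        assert field.values.max() == 1.0

    @pytest.mark.parametrize("size", [(0, 10), (10, -1), (2000, 100), (100, 1025)])
    def test_invalid_sizes(self, size):
        with pytest.raises(ValueError):
            generate_noise_field(size, seed=0)

    def test_deterministic(self):
        a = generate_noise_field((256, 128), seed=7)
        b = generate_noise_field((256, 128), seed=7)
        np.testing.assert_array_equal(a.values, b.values)

    def test_exponent_zero_is_white(self):
        v = generate_noise_field((1024, 768), exponent=0.0, seed=3).values
        r_x = np.corrcoef(v[:, :-1].ravel(), v[:, 1:].ravel())[0, 1]
        r_y = np.corrcoef(v[:-1, :].ravel(), v[1:, :].ravel())[0, 1]
        assert abs(r_x) < 0.05 and abs(r_y) < 0.05

    def test_spectral_slope_difference(self):
        pink = generate_noise_field((1024, 1024), exponent=2.0, seed=5).values
        white = generate_noise_field((1024, 1024), exponent=0.0, seed=5).values
        diff = radial_log_power_slope(pink) - radial_log_power_slope(white)
        # amplitude ~ 1/f^2 means power slope steeper by 2*2
        assert diff == pytest.approx(-4.0, abs=0.6)


class TestEqualizeToParabola:
    def test_empty_map_rejected(self):
        with pytest.raises(ValueError):
            DifficultyMap(np.empty((0, 0)))

    def test_median_pixel_maps_to_half(self, rng):
        values = rng.random((3, 3))
        out = equalize_to_parabola(DifficultyMap(values)).values.ravel()
        median_pos = np.argsort(values.ravel())[4]
        assert out[median_pos] == pytest.approx(0.5)

    def test_uniform_input_matches_cdf(self, rng):
        values = rng.random((768, 1024))
        out = equalize_to_parabola(DifficultyMap(values)).values.ravel()
        xs = np.sort(out)
        n = xs.size
        ecdf_hi = np.arange(1, n + 1) / n
        ecdf_lo = np.arange(0, n) / n
        ks = max(
            np.max(np.abs(ecdf_hi - parabola_cdf(xs))),
            np.max(np.abs(parabola_cdf(xs) - ecdf_lo)),
        )
        assert ks < 0.01

    def test_tail_mass(self, rng):
        # P(X in [0, .25] U [.75, 1]) = F(.25) + 1 - F(.75) = 0.875
        out = equalize_to_parabola(DifficultyMap(rng.random((200, 200)))).values
        frac = np.mean((out <= 0.25) | (out >= 0.75))
        assert frac == pytest.approx(0.875, abs=0.01)

    def test_extremes_approach_bounds(self, rng):
        out = equalize_to_parabola(DifficultyMap(rng.random((100, 100)))).values
        assert out.min() < 0.01 and out.max() > 0.99

    @given(seed=st.integers(0, 2**32 - 1))
    @settings(max_examples=20, deadline=None)
    def test_monotone_transform_invariance(self, seed):
        values = np.random.default_rng(seed).random((8, 8))
        base = equalize_to_parabola(DifficultyMap(values)).values
        for transform in (np.exp, lambda v: v**3, lambda v: 5 * v - 2):
            same = equalize_to_parabola(DifficultyMap(transform(values))).values
            np.testing.assert_allclose(same, base)


class TestCellDifficulties:
    def test_constant_map(self):
        grid = GridSpec(3, 2, 4)
        dmap = DifficultyMap(np.full((8, 12), 0.37))
        np.testing.assert_allclose(cell_difficulties(dmap, grid), 0.37)

    def test_two_block_toy(self):
        grid = GridSpec(2, 2, 4)
        values = np.zeros((8, 8))
        values[:, 4:] = 1.0
        out = cell_difficulties(DifficultyMap(values), grid)
        np.testing.assert_allclose(out, [[0, 1], [0, 1]])

    def test_matches_loop_oracle(self, rng):
        grid = GridSpec(5, 3, 7)
        values = rng.random((21, 35))
        out = cell_difficulties(DifficultyMap(values), grid)
        for r in range(3):
            for c in range(5):
                block = values[r * 7 : (r + 1) * 7, c * 7 : (c + 1) * 7]
                assert out[r, c] == pytest.approx(block.mean())

    def test_extent_mismatch(self):
        with pytest.raises(ValueError):
            cell_difficulties(DifficultyMap(np.zeros((8, 8))), GridSpec(3, 2, 4))


class TestRangeFromDifficulty:
    def test_endpoints(self):
        assert range_from_difficulty(0.0) == pytest.approx(math.pi / 6)
        assert range_from_difficulty(1.0) == pytest.approx(2 * math.pi / 3)

    def test_midpoint(self):
        assert range_from_difficulty(0.5) == pytest.approx(5 * math.pi / 12)

    @given(
        d1=st.floats(0, 0.99),
        delta=st.floats(1e-4, 1.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_strictly_increasing_and_bounded(self, d1, delta):
        d2 = min(d1 + delta, 1.0)
        m = OrientationRangeMapping()
        r1, r2 = range_from_difficulty(d1, m), range_from_difficulty(d2, m)
        assert r1 < r2
        assert m.range_min <= r1 <= r2 <= m.range_max

    @pytest.mark.parametrize("bad", [-0.01, 1.01])
    def test_out_of_range(self, bad):
        with pytest.raises(ValueError):
            range_from_difficulty(bad)

    def test_invalid_mapping(self):
        with pytest.raises(ValueError):
            OrientationRangeMapping(range_min=0.5, range_max=0.4)


class TestSampleOrientationGrid:
    def test_mean_is_perpendicular_to_target(self, rng):
        ranges = np.full((100, 100), math.pi / 6)
        target = TargetSpec(False, None, DEFAULT_THETA)
        ori = sample_orientation_grid(ranges, target, rng)
        centre = DEFAULT_THETA + math.pi / 2
        se = (math.pi / 6) / math.sqrt(12) / 100
        assert abs(ori.mean() - centre) < 3 * se

    def test_zero_range_limit(self, rng):
        ranges = np.full((4, 4), 1e-12)
        ori = sample_orientation_grid(ranges, TargetSpec(False), rng)
        np.testing.assert_allclose(ori, DEFAULT_THETA + math.pi / 2, atol=1e-9)

    def test_target_cell_exact(self, rng):
        ranges = np.full((5, 6), math.pi / 3)
        target = TargetSpec(True, (2, 3), DEFAULT_THETA)
        ori = sample_orientation_grid(ranges, target, rng)
        assert ori[3, 2] == DEFAULT_THETA % math.pi

    def test_all_orientations_within_interval(self, rng):
        ranges = np.full((50, 50), 2 * math.pi / 3)  # interval wraps past pi
        ori = sample_orientation_grid(ranges, TargetSpec(False), rng)
        centre = DEFAULT_THETA + math.pi / 2
        assert orientation_in_interval(ori, centre, 2 * math.pi / 3).all()


class TestSplitHalf:
    def test_hard_up_rows(self):
        stim = make_split_half(EXP1_GRID, "horizontal", "up", seed=0)
        assert (stim.cell_difficulty[:8, :] == 1).all()
        assert (stim.cell_difficulty[8:, :] == 0).all()

    def test_halves_partition_evenly(self):
        for axis, side in [("horizontal", "down"), ("vertical", "left")]:
            grid = EXP1_GRID if axis == "horizontal" else EXP2_GRID
            mask = split_hard_mask(grid, axis, side)
            assert mask.sum() == mask.size // 2

    def test_inconsistent_axis_side(self):
        with pytest.raises(ValueError):
            make_split_half(EXP1_GRID, "horizontal", "left")

    def test_absent_target_never_matches_theta(self):
        for seed in range(100):
            stim = make_split_half(seed=seed, target_half="absent")
            assert not stim.target.present
            assert not np.any(np.isclose(stim.orientations, DEFAULT_THETA % math.pi))

    def test_target_placed_in_requested_half(self, rng):
        for half in ("easy", "hard"):
            stim = make_split_half(seed=42, target_half=half, hard_side="up")
            col, row = stim.target.cell
            on_hard = row < 8
            assert on_hard == (half == "hard")

    def test_orientations_modulo_pi(self):
        stim = make_split_half(seed=9)
        assert (stim.orientations >= 0).all() and (stim.orientations < math.pi).all()


class TestJumbled:
    def test_default_grid_dimensions(self):
        stim = make_jumbled(seed=0)
        assert (stim.grid.n_cols, stim.grid.n_rows) == (32, 24)

    def test_same_seed_bit_exact(self):
        a = make_jumbled(seed=4, target_present=True)
        b = make_jumbled(seed=4, target_present=True)
        np.testing.assert_array_equal(a.orientations, b.orientations)
        np.testing.assert_array_equal(a.cell_difficulty, b.cell_difficulty)
        assert a.target == b.target

    def test_pooled_cell_difficulties_u_shaped(self):
        # scaled down from a 200-array check; the U shape is unambiguous here
        pooled = np.concatenate(
            [make_jumbled(seed=s).cell_difficulty.ravel() for s in range(30)]
        )
        outer = np.mean((pooled <= 0.25) | (pooled >= 0.75))
        assert outer > 0.5

    def test_orientations_within_cell_intervals(self):
        stim = make_jumbled(seed=11)
        centre = DEFAULT_THETA + math.pi / 2
        ranges = stim.cell_ranges()
        ok = orientation_in_interval(stim.orientations, centre, ranges)
        assert ok.all()


class TestPlaceTarget:
    def test_eligible_count_32x24(self):
        grid = GridSpec(32, 24, 32)
        assert eligible_target_cells(grid).sum() == 656

    def test_matches_enumeration_oracle(self):
        grid = GridSpec(32, 24, 32)
        oracle = set()
        for r in range(24):
            for c in range(32):
                if r in (0, 23) or c in (0, 31):
                    continue
                if c in (15, 16) and r in (11, 12):
                    continue
                oracle.add((c, r))
        mask = eligible_target_cells(grid)
        ours = {(c, r) for r, c in zip(*np.nonzero(mask))}
        assert ours == oracle

    def test_degenerate_3x3_raises(self, rng):
        with pytest.raises(ValueError):
            place_target(GridSpec(3, 3, 10), rng)

    def test_uniform_placement(self, rng):
        from scipy import stats

        grid = GridSpec(32, 24, 32)
        mask = eligible_target_cells(grid)
        counts = np.zeros(mask.shape)
        for _ in range(10_000):
            col, row = place_target(grid, rng).cell
            assert mask[row, col]
            counts[row, col] += 1
        observed = counts[mask]
        result = stats.chisquare(observed)
        assert result.pvalue > 0.01


class TestRender:
    def test_image_spans_screen(self, tmp_path):
        stim = make_split_half(seed=0)
        img = render_stimulus(stim)
        assert img.size == (1024, 768)

    def test_zero_orientation_is_horizontal(self):
        grid = GridSpec(2, 2, 32)
        stim = stimgen.StimulusArray(
            grid, np.zeros((2, 2)), np.zeros((2, 2)), "easy", "none",
            TargetSpec(False), 0,
        )
        img = np.asarray(render_stimulus(stim, background=200, line_width=2))
        cx, cy = grid.cell_centre(0, 0)
        assert img[int(cy), int(cx) + 6] == 0  # along the segment
        assert img[int(cy) + 6, int(cx)] == 200  # perpendicular: background

    def test_render_deterministic_bytes(self, tmp_path):
        stim = make_uniform("easy", seed=2)
        p1, p2 = tmp_path / "a.png", tmp_path / "b.png"
        render_stimulus(stim, out_path=p1)
        render_stimulus(stim, out_path=p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_unwritable_path(self):
        stim = make_uniform("easy", seed=2)
        with pytest.raises(OSError):
            render_stimulus(stim, out_path="/nonexistent-dir/x.png")
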