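"""Map algebra: assembly, alignment, interpolation, group averaging with the
minimum-sampling mask, vertical profiles and region means."""

import numpy as np
import pytest
from scipy.integrate import dblquad

from optomap.core import GridGeometry
from optomap.events import EvokedResponse
from optomap.exceptions import (IncompatibleMapsError, InvalidFrameError,
                                InvalidParameterError)
from optomap.maps import (DIRECT_EXCLUDED, UNSAMPLED, VALID, InputMap, Rect,
                          align_to_barrel, align_to_soma, average_group,
                          build_cell_map, interpolate_half, region_mean,
                          vertical_profile)
from optomap.synthgen import SynthConfig, _innervation_field


def response(amp, r, c, excluded=False):
    return EvokedResponse(trace=None, amplitude=amp,
                          classification="direct" if excluded else "synaptic",
                          excluded=excluded, grid_index=(r, c))


def grid_map(values, soma=(0.0, 0.0), spacing=50.0, skip=(), direct=()):
    values = np.asarray(values, dtype=float)
    rows, cols = values.shape
    g = GridGeometry(rows, cols, spacing, spacing)
    resps = [response(values[r, c], r, c, excluded=(r, c) in direct)
             for r in range(rows) for c in range(cols) if (r, c) not in skip]
    return build_cell_map(resps, g, soma_pos=soma)


class TestBuildAndAlign:
    def test_known_matrix_is_reproduced(self):
        vals = np.arange(16.0).reshape(4, 4)
        m = grid_map(vals)
        assert np.array_equal(m.values, vals)
        assert np.all(m.mask == VALID)

    def test_direct_and_unsampled_spots_are_masked(self):
        m = grid_map(np.ones((4, 4)), skip={(0, 0)}, direct={(1, 1)})
        assert m.mask[0, 0] == UNSAMPLED
        assert m.mask[1, 1] == DIRECT_EXCLUDED
        assert np.isnan(m.values[1, 1])
        assert (m.mask == VALID).sum() == 14

    def test_duplicate_grid_index_rejected(self):
        g = GridGeometry(2, 2, 50, 50)
        with pytest.raises(InvalidParameterError):
            build_cell_map([response(1, 0, 0), response(2, 0, 0)], g, (0, 0))

    def test_all_zero_map_is_valid(self):
        m = grid_map(np.zeros((3, 3)))
        assert np.all(m.values == 0) and np.all(m.mask == VALID)

    def test_soma_moves_to_origin(self):
        m = grid_map(np.ones((12, 12)), soma=(137.0, -260.0))
        a = align_to_soma(m)
        # soma pixel (6, 6) is at coordinate (0, 0) after alignment
        assert a.x_coords[6] == pytest.approx(0.0)
        assert a.y_coords[6] == pytest.approx(0.0)
        assert a.frame == "soma_aligned"

    def test_alignment_is_translation_invariant(self):
        vals = np.random.default_rng(0).uniform(0, 30, (6, 6))
        a = align_to_soma(grid_map(vals, soma=(10.0, -50.0)))
        b = align_to_soma(grid_map(vals, soma=(410.0, -850.0)))
        assert np.allclose(a.x_coords, b.x_coords)
        assert np.allclose(a.y_coords, b.y_coords)
        assert np.array_equal(a.values, b.values)

    def test_missing_soma_rejected(self):
        m = grid_map(np.ones((2, 2)))
        m.soma_pos = None
        with pytest.raises(InvalidParameterError):
            align_to_soma(m)


class TestBarrelAlignment:
    def test_stretch_factor_arithmetic(self):
        base = grid_map(np.ones((8, 8)))
        m = align_to_barrel(base, Rect(0, 0, 300.0, 200.0),
                            Rect(0, 0, 250.0, 200.0))
        # x extent shrinks by sx = 250/300 = 0.8333...; the output lattice
        # keeps the nominal 50 um spacing shared by all aligned maps
        sx = 250.0 / 300.0
        assert m.pixel_size[0] == pytest.approx(50.0)
        expect_span = (base.x_coords[-1] - base.x_coords[0]) * sx
        assert m.x_coords[-1] - m.x_coords[0] <= expect_span + 1e-9
        assert m.x_coords[-1] - m.x_coords[0] >= expect_span - 2 * 50.0

    def test_identity_barrel_is_pure_translation(self):
        vals = np.random.default_rng(1).uniform(0, 20, (6, 6))
        base = grid_map(vals, soma=(0.0, 0.0))
        home = Rect(50.0, -50.0, 100.0, 100.0)  # centre on the pixel lattice
        a = align_to_barrel(base, home, home)
        assert a.frame == "barrel_aligned"
        common = a.values[np.isfinite(a.values)]
        assert common.size > 0
        # overlapping lattice points carry the original values exactly
        for i, y in enumerate(a.y_coords):
            for j, x in enumerate(a.x_coords):
                if np.isfinite(a.values[i, j]):
                    src_j = np.argmin(np.abs(base.x_coords - (x + home.cx)))
                    src_i = np.argmin(np.abs(base.y_coords - (y + home.cy)))
                    assert a.values[i, j] == pytest.approx(
                        base.values[src_i, src_j], abs=1e-9)

    def test_uniform_map_stays_uniform(self):
        m = align_to_barrel(grid_map(np.full((8, 8), 7.0)),
                            Rect(25.0, -25.0, 300.0, 120.0),
                            Rect(0, 0, 250.0, 100.0))
        vals = m.values[np.isfinite(m.values)]
        assert np.allclose(vals, 7.0)

    def test_degenerate_barrel_rejected(self):
        with pytest.raises(InvalidParameterError):
            Rect(0, 0, 0.0, 100.0)


class TestInterpolation:
    def test_constant_map_stays_constant(self):
        h = interpolate_half(grid_map(np.full((4, 4), 3.0)))
        assert np.allclose(h.values, 3.0)

    def test_affine_field_reproduced_exactly_and_pixel_halved(self):
        vals = np.add.outer(3.0 * np.arange(4), 2.0 * np.arange(4)) + 1.0
        m = grid_map(vals, spacing=50.0)
        h = interpolate_half(m)
        assert h.pixel_size == (25.0, 25.0)
        assert h.values.shape == (7, 7)
        # bilinear reproduces affine fields: check against the closed form
        expect = np.add.outer(1.5 * np.arange(7), 1.0 * np.arange(7)) + 1.0
        assert np.allclose(h.values, expect)

    def test_mask_propagation_is_conservative(self):
        m = grid_map(np.ones((4, 4)), direct={(1, 1)})
        h = interpolate_half(m)
        # every output pixel whose bilinear stencil touches input pixel
        # (1, 1) is masked: the 3x3 block of half-pixels centred on it
        assert np.all(h.mask[1:4, 1:4].ravel() == DIRECT_EXCLUDED)
        assert h.mask[0, 0] == VALID
        assert h.mask[4, 4] == VALID
        assert (h.mask == DIRECT_EXCLUDED).sum() == 9


class TestGroupAveraging:
    def test_mean_and_min_n_rule(self):
        maps = [align_to_soma(grid_map(np.full((3, 3), float(v))))
                for v in range(1, 9)]
        gm = average_group(maps, min_n=8)
        assert np.allclose(gm.values, 4.5)
        assert np.all(gm.n == 8)
        # seven contributions at one pixel -> masked there
        maps7 = [align_to_soma(grid_map(np.full((3, 3), float(v)),
                                        direct={(0, 0)} if v == 1 else ()))
                 for v in range(1, 9)]
        gm7 = average_group(maps7, min_n=8)
        assert gm7.n[0, 0] == 7 and np.isnan(gm7.values[0, 0])
        assert gm7.n[1, 1] == 8 and np.isfinite(gm7.values[1, 1])

    def test_group_pixel_equals_mean_of_contributors(self, rng):
        """Conservation, exhaustively on random masked fixtures."""
        maps = []
        vals_list = []
        for i in range(10):
            vals = rng.uniform(0, 50, (4, 4))
            direct = {(int(rng.integers(4)), int(rng.integers(4)))}
            maps.append(align_to_soma(grid_map(vals, direct=direct)))
            masked = vals.copy()
            for (r, c) in direct:
                masked[r, c] = np.nan
            vals_list.append(masked)
        gm = average_group(maps, min_n=1)
        stack = np.array(vals_list)
        expect = np.nanmean(stack, axis=0)
        n = np.sum(np.isfinite(stack), axis=0)
        assert np.allclose(gm.values, expect, equal_nan=True)
        assert np.array_equal(gm.n, n)

    def test_adding_a_map_never_masks_an_unmasked_pixel(self, rng):
        maps = [align_to_soma(grid_map(rng.uniform(0, 10, (3, 3))))
                for _ in range(8)]
        before = average_group(maps, min_n=8)
        extra = align_to_soma(grid_map(np.ones((3, 3)),
                                       direct={(0, 0), (1, 1)}))
        after = average_group(maps + [extra], min_n=8)
        assert not np.any(np.isfinite(before.values) & ~np.isfinite(after.values))

    def test_mixed_frames_rejected(self):
        a = align_to_soma(grid_map(np.ones((3, 3))))
        b = grid_map(np.ones((3, 3)))
        with pytest.raises(IncompatibleMapsError):
            average_group([a, b], min_n=1)


class TestProfilesAndRegions:
    def test_two_by_two_profile(self):
        m = align_to_soma(grid_map([[1.0, 3.0], [5.0, 7.0]]))
        _, prof = vertical_profile(m)
        assert np.allclose(prof, [2.0, 6.0])

    def test_uniform_map_gives_flat_profile(self):
        _, prof = vertical_profile(align_to_soma(grid_map(np.full((5, 5), 4.0))))
        assert np.allclose(prof, 4.0)

    def test_unaligned_frame_rejected(self):
        with pytest.raises(InvalidFrameError):
            vertical_profile(grid_map(np.ones((3, 3))))

    def test_gaussian_field_profile_peaks_pia_ward_of_soma(self):
        cfg = SynthConfig.for_mode("sCRACM", seed=0)
        field = _innervation_field(cfg)
        m = align_to_soma(grid_map(field, spacing=50.0))
        offsets, prof = vertical_profile(m)
        peak_offset = offsets[np.nanargmax(prof)]
        assert abs(peak_offset - cfg.field_offset_y) <= 50.0

    def test_region_mean_uniform_and_single_pixel(self):
        m = align_to_soma(grid_map(np.full((4, 4), 10.0)))
        assert region_mean(m, (-100, 100, -100, 100)) == pytest.approx(10.0)
        vals = np.arange(16.0).reshape(4, 4)
        m2 = align_to_soma(grid_map(vals))
        # pixel (2, 2) sits at the aligned-frame origin for a 4x4 grid
        assert region_mean(m2, (-1, 1, -1, 1)) == pytest.approx(vals[2, 2])

    def test_region_without_valid_pixels_is_missing(self):
        m = align_to_soma(grid_map(np.ones((2, 2)),
                                   direct={(0, 0), (0, 1), (1, 0), (1, 1)}))
        assert np.isnan(region_mean(m, (-100, 100, -100, 100)))

    def test_region_mean_matches_field_quadrature(self):
        """Pixel-centre average of the innervation field approximates the
        continuous field mean over the region (midpoint rule, ~O(h^2))."""
        cfg = SynthConfig.for_mode("sCRACM", seed=0)
        m = align_to_soma(grid_map(_innervation_field(cfg), spacing=50.0))
        region = (-75.0, 75.0, 25.0, 175.0)

        def f(y, x):
            return cfg.field_peak_amp * np.exp(
                -(x ** 2 + (y - cfg.field_offset_y) ** 2)
                / (2 * cfg.field_sigma ** 2))

        # the region bounds coincide with the support of the selected pixels
        # (centres +- half a pixel), so integrate over the region itself
        x0, x1, y0, y1 = region
        integral, _ = dblquad(f, x0, x1, y0, y1, epsabs=1e-6)
        continuous_mean = integral / ((x1 - x0) * (y1 - y0))
        assert region_mean(m, region) == pytest.approx(continuous_mean, rel=0.02)

    def test_region_mean_frame_invariance(self, rng):
        vals = rng.uniform(0, 30, (6, 6))
        region = (-60, 60, -60, 60)
        a = region_mean(align_to_soma(grid_map(vals, soma=(0, 0))), region)
        b = region_mean(align_to_soma(grid_map(vals, soma=(220.0, -740.0))),
                        region)
        assert a == pytest.approx(b)

    def test_power_normalisation(self):
        m = align_to_soma(grid_map(np.full((3, 3), 12.0)))
        assert region_mean(m, (-60, 60, -60, 60), power=4.0) == pytest.approx(3.0)
        with pytest.raises(InvalidParameterError):
            region_mean(m, (-60, 60, -60, 60), power=0.0)
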