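"""Grid geometry: rasterization, surface extraction, longitudinal resampling."""

import numpy as np
import pytest
from shapely.geometry import Point, Polygon

from contourqa import (
    ContourPolygonSet,
    ImageGrid,
    extract_surface,
    mask_to_contours,
    rasterize_contours,
    resample_longitudinal,
)
from contourqa.errors import (
    ArgumentError,
    CoordinateMismatchError,
    EmptyStructureError,
)

from conftest import random_blob, sphere_mask


def shapely_rasterize(polys, grid, k):
    """Independent even-odd oracle: XOR of shapely point-in-polygon tests
    over all voxel centers of slice k."""
    xs = grid.axis_coordinates(0)
    ys = grid.axis_coordinates(1)
    out = np.zeros((len(xs), len(ys)), dtype=bool)
    shapes = [Polygon(p) for p in polys]
    for i, x in enumerate(xs):
        for j, y in enumerate(ys):
            pt = Point(x, y)
            out[i, j] = sum(s.contains(pt) for s in shapes) % 2 == 1
    return out


class TestRasterize:
    def test_square_20mm_counts_400_voxels(self):
        grid = ImageGrid(origin=(0.5, 0.5, 0), spacing=(1, 1, 5), shape=(30, 30, 3))
        square = np.array([(0, 0), (20, 0), (20, 20), (0, 20)], dtype=float)
        cps = ContourPolygonSet(name="sq", planes=[(5.0, [square])])
        mask = rasterize_contours(cps, grid)
        assert mask.voxel_count == 400
        assert mask.data[:, :, 0].sum() == 0 and mask.data[:, :, 2].sum() == 0
        oracle = shapely_rasterize([square], grid, 1)
        np.testing.assert_array_equal(mask.data[:, :, 1], oracle)

    def test_empty_polygon_set_gives_empty_mask(self):
        grid = ImageGrid(origin=(0, 0, 0), spacing=(1, 1, 1), shape=(5, 5, 5))
        mask = rasterize_contours(ContourPolygonSet(name="e", planes=[]), grid)
        assert mask.is_empty

    def test_concentric_squares_make_a_ring(self):
        grid = ImageGrid(origin=(0.5, 0.5, 0), spacing=(1, 1, 1), shape=(30, 30, 1))
        outer = np.array([(0, 0), (24, 0), (24, 24), (0, 24)], dtype=float)
        inner = np.array([(8, 8), (16, 8), (16, 16), (8, 16)], dtype=float)
        ring = rasterize_contours(
            ContourPolygonSet(name="ring", planes=[(0.0, [outer, inner])]), grid
        )
        only_outer = rasterize_contours(
            ContourPolygonSet(name="o", planes=[(0.0, [outer])]), grid
        )
        only_inner = rasterize_contours(
            ContourPolygonSet(name="i", planes=[(0.0, [inner])]), grid
        )
        np.testing.assert_array_equal(
            ring.data, only_outer.data & ~only_inner.data
        )
        oracle = shapely_rasterize([outer, inner], grid, 0)
        np.testing.assert_array_equal(ring.data[:, :, 0], oracle)

    def test_plane_outside_grid_raises_with_plane_named(self):
        grid = ImageGrid(origin=(0, 0, 0), spacing=(1, 1, 5), shape=(10, 10, 3))
        tri = np.array([(1, 1), (4, 1), (2, 4)], dtype=float)
        cps = ContourPolygonSet(name="t", planes=[(30.0, [tri])])
        with pytest.raises(CoordinateMismatchError, match="30"):
            rasterize_contours(cps, grid)

    def test_circle_area_converges_to_pi_r_squared(self):
        r = 15.0
        grid = ImageGrid(origin=(-20, -20, 0), spacing=(1, 1, 1), shape=(41, 41, 1))
        theta = np.linspace(0, 2 * np.pi, 400, endpoint=False)
        circle = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
        mask = rasterize_contours(
            ContourPolygonSet(name="c", planes=[(0.0, [circle])]), grid
        )
        area = mask.voxel_count * 1.0
        # voxelization error is O(spacing * perimeter)
        assert abs(area - np.pi * r**2) < 1.0 * (2 * np.pi * r)

    def test_degenerate_polygon_rejected(self):
        with pytest.raises(ArgumentError):
            ContourPolygonSet(name="bad", planes=[(0.0, [np.array([[0, 0], [1, 1]])])])


class TestSurface:
    def test_single_voxel_single_surface_point(self, iso_grid):
        mask = sphere_mask(iso_grid, 0.4, center=(10, 11, 12))
        assert mask.voxel_count == 1
        surf = extract_surface(mask)
        np.testing.assert_allclose(surf.points, [[10, 11, 12]])

    def test_3x3x3_block_has_26_surface_points(self, iso_grid):
        data = np.zeros(iso_grid.shape, dtype=bool)
        data[10:13, 10:13, 10:13] = True
        from contourqa import StructureMask

        surf = extract_surface(StructureMask(name="b", grid=iso_grid, data=data))
        assert len(surf) == 26

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_brute_force_neighborhood_scan(self, iso_grid, seed):
        mask = sphere_mask(iso_grid, 10.0) if seed == 0 else random_blob(iso_grid, seed)
        surf = extract_surface(mask)
        # brute force: pad and scan the 6-neighborhood of every occupied voxel
        d = np.pad(mask.data, 1)
        expected = set()
        for i, j, k in np.argwhere(mask.data):
            nbrs = [
                d[i + 2, j + 1, k + 1], d[i, j + 1, k + 1],
                d[i + 1, j + 2, k + 1], d[i + 1, j, k + 1],
                d[i + 1, j + 1, k + 2], d[i + 1, j + 1, k],
            ]
            if not all(nbrs):
                expected.add((i, j, k))
        got = {tuple(ijk) for ijk in np.round(surf.points).astype(int)}
        assert got == expected

    def test_surface_removal_leaves_interior_only(self, iso_grid):
        from contourqa import StructureMask
        from scipy import ndimage

        mask = sphere_mask(iso_grid, 12.0)
        surf_idx = np.round(extract_surface(mask).points).astype(int)
        remaining = mask.data.copy()
        remaining[tuple(surf_idx.T)] = False
        # no remaining voxel touches background face-to-face
        interior = ndimage.binary_erosion(
            mask.data, ndimage.generate_binary_structure(3, 1), border_value=0
        )
        np.testing.assert_array_equal(remaining, interior)

    def test_empty_mask_raises(self, iso_grid):
        from contourqa import StructureMask

        empty = StructureMask(
            name="e", grid=iso_grid, data=np.zeros(iso_grid.shape, bool)
        )
        with pytest.raises(EmptyStructureError):
            extract_surface(empty)


class TestResample:
    def test_factor_one_is_identity(self, ct_grid):
        mask = sphere_mask(ct_grid, 12.0)
        out = resample_longitudinal(mask, 1)
        assert out.grid.same_frame(mask.grid)
        np.testing.assert_array_equal(out.data, mask.data)

    def test_factor_three_gives_2p5mm_slices(self, ct_grid):
        mask = sphere_mask(ct_grid, 12.0)
        out = resample_longitudinal(mask, 3)
        assert out.grid.spacing[2] == pytest.approx(2.5)
        assert out.voxel_count == 3 * mask.voxel_count
        assert out.volume_cc == pytest.approx(mask.volume_cc)

    def test_single_slice_100_voxels_factor_4(self):
        grid = ImageGrid(origin=(0, 0, 0), spacing=(1, 1, 7.5), shape=(10, 10, 1))
        from contourqa import StructureMask

        mask = StructureMask(name="s", grid=grid, data=np.ones((10, 10, 1), bool))
        out = resample_longitudinal(mask, 4)
        assert out.voxel_count == 400
        assert out.volume_cc == pytest.approx(mask.volume_cc)

    def test_subslice_centers_tile_original_slice(self, ct_grid):
        out = resample_longitudinal(sphere_mask(ct_grid, 12.0), 3)
        # mean of the 3 sub-slice centers recovers each original center
        zs = out.grid.axis_coordinates(2).reshape(-1, 3).mean(axis=1)
        np.testing.assert_allclose(zs, ct_grid.axis_coordinates(2))

    def test_factor_below_one_rejected(self, ct_grid):
        with pytest.raises(ArgumentError):
            resample_longitudinal(sphere_mask(ct_grid, 12.0), 0)


class TestMaskToContours:
    @pytest.mark.parametrize("seed", [0, 3, 7])
    def test_trace_then_rasterize_recovers_mask_exactly(self, seed):
        grid = ImageGrid(origin=(0, 0, 0), spacing=(1.17, 1.17, 7.5), shape=(20, 20, 4))
        mask = random_blob(grid, seed, p=0.4)
        back = rasterize_contours(mask_to_contours(mask), grid)
        np.testing.assert_array_equal(back.data, mask.data)

    def test_ring_mask_round_trips_through_hole_polygons(self):
        grid = ImageGrid(origin=(0, 0, 0), spacing=(1, 1, 1), shape=(20, 20, 1))
        from contourqa import StructureMask

        data = np.zeros(grid.shape, bool)
        data[3:17, 3:17, 0] = True
        data[7:13, 7:13, 0] = False
        mask = StructureMask(name="ring", grid=grid, data=data)
        cps = mask_to_contours(mask)
        assert len(cps.planes[0][1]) == 2  # outer loop + hole
        back = rasterize_contours(cps, grid)
        np.testing.assert_array_equal(back.data, mask.data)
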