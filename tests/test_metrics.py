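"""Contour metrics: Dice, distance distributions, HD percentiles, Eff."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import cdist

from contourqa import (
    DistanceDistribution,
    ImageGrid,
    StructureMask,
    compare_structures,
    dice,
    distance_distribution,
    efficiency_gain,
    extract_surface,
    hd_percentile,
)
from contourqa.errors import (
    ArgumentError,
    EmptyStructureError,
    GridMismatchError,
    UndefinedMetricError,
)

from conftest import random_blob, sphere_mask


def points(arr, name="p"):
    from contourqa import SurfacePointSet

    return SurfacePointSet(name=name, points=np.asarray(arr, dtype=float))


class TestDice:
    def test_identity_is_one(self, iso_grid):
        m = sphere_mask(iso_grid, 10.0)
        assert dice(m, m) == 1.0

    def test_disjoint_is_zero(self, iso_grid):
        a = sphere_mask(iso_grid, 4.0, center=(8, 8, 8))
        b = sphere_mask(iso_grid, 4.0, center=(30, 30, 30))
        assert dice(a, b) == 0.0

    def test_concentric_spheres_match_closed_form(self, iso_grid):
        # Dice of concentric spheres = 2 rho^3 / (1 + rho^3), rho = r2/r1
        a = sphere_mask(iso_grid, 20.0)
        b = sphere_mask(iso_grid, 17.0)
        rho = 17.0 / 20.0
        expected = 2 * rho**3 / (1 + rho**3)
        assert dice(a, b) == pytest.approx(expected, abs=0.01)

    def test_symmetry(self, iso_grid):
        a = random_blob(iso_grid, 1)
        b = random_blob(iso_grid, 2)
        assert dice(a, b) == dice(b, a)
        assert 0.0 <= dice(a, b) <= 1.0

    def test_grid_mismatch_raises(self, iso_grid, ct_grid):
        with pytest.raises(GridMismatchError):
            dice(sphere_mask(iso_grid, 5.0), sphere_mask(ct_grid, 5.0))

    def test_both_empty_is_undefined(self, iso_grid):
        e = StructureMask(name="e", grid=iso_grid, data=np.zeros(iso_grid.shape, bool))
        with pytest.raises(UndefinedMetricError):
            dice(e, e)


class TestDistanceDistribution:
    def test_identical_sets_all_zero(self):
        p = points([[0, 0, 0], [3, 4, 0], [1, 1, 7.5]])
        for direction in ("a_to_b", "b_to_a", "symmetric"):
            d = distance_distribution(p, p, direction)
            assert np.all(d.distances == 0.0)

    def test_two_points_5mm_apart(self):
        a, b = points([[0, 0, 0]]), points([[3, 4, 0]])
        assert distance_distribution(a, b, "a_to_b").distances.tolist() == [5.0]
        assert distance_distribution(a, b, "b_to_a").distances.tolist() == [5.0]

    def test_symmetric_cardinality_is_sum_of_surfaces(self, iso_grid):
        sa = extract_surface(sphere_mask(iso_grid, 10.0))
        sb = extract_surface(sphere_mask(iso_grid, 8.0))
        d = distance_distribution(sa, sb, "symmetric")
        assert len(d) == len(sa) + len(sb)

    def test_concentric_spheres_directed_distances_near_radius_gap(self, iso_grid):
        # r1=20, r2=17: every directed distance ~ 3 mm within a voxel diagonal
        sa = extract_surface(sphere_mask(iso_grid, 20.0))
        sb = extract_surface(sphere_mask(iso_grid, 17.0))
        voxel_diag = np.sqrt(3.0)
        for direction in ("a_to_b", "b_to_a"):
            d = distance_distribution(sa, sb, direction).distances
            assert np.all(np.abs(d - 3.0) <= voxel_diag)

    def test_matches_all_pairs_brute_force(self, iso_grid):
        sa = extract_surface(sphere_mask(iso_grid, 9.0, center=(20, 20, 20)))
        sb = extract_surface(sphere_mask(iso_grid, 7.0, center=(24, 21, 20)))
        assert len(sa) + len(sb) < 10_000
        full = cdist(sa.points, sb.points)
        np.testing.assert_allclose(
            np.sort(distance_distribution(sa, sb, "a_to_b").distances),
            np.sort(full.min(axis=1)),
            atol=1e-9,
        )
        np.testing.assert_allclose(
            np.sort(distance_distribution(sa, sb, "symmetric").distances),
            np.sort(np.concatenate([full.min(axis=1), full.min(axis=0)])),
            atol=1e-9,
        )

    def test_anisotropic_spacing_in_physical_mm(self, ct_grid):
        # one-slice offset on 7.5 mm slices is a 7.5 mm distance
        a = sphere_mask(ct_grid, 0.5, center=(23.4, 23.4, 37.5))
        b = sphere_mask(ct_grid, 0.5, center=(23.4, 23.4, 45.0))
        d = distance_distribution(extract_surface(a), extract_surface(b), "a_to_b")
        assert d.distances.tolist() == [7.5]

    def test_empty_point_set_raises(self):
        with pytest.raises(EmptyStructureError):
            distance_distribution(points(np.empty((0, 3))), points([[0, 0, 0]]))


def dist(vals):
    v = np.asarray(vals, dtype=float)
    return DistanceDistribution(distances=v, direction="a_to_b", n_a=v.size, n_b=v.size)


class TestHDPercentile:
    def test_all_zero_distribution(self):
        assert hd_percentile(dist(np.zeros(50)), 95) == 0.0

    def test_order_statistic_on_1_to_100(self):
        assert hd_percentile(dist(np.arange(1, 101)), 95) == 95.0

    def test_p100_is_max(self):
        assert hd_percentile(dist([0, 0, 7]), 100) == 7.0

    @pytest.mark.parametrize("p", [0, -5, 101])
    def test_p_out_of_domain(self, p):
        with pytest.raises(ArgumentError):
            hd_percentile(dist([1.0, 2.0]), p)

    def test_matches_brute_force_counting(self):
        rng = np.random.default_rng(42)
        d = dist(rng.exponential(2.0, size=137))
        for p in (5, 50, 95, 99.9, 100):
            t = hd_percentile(d, p)
            # smallest distance with >= p% of values at or below it
            assert np.mean(d.distances <= t) >= p / 100.0
            smaller = d.distances[d.distances < t]
            if smaller.size:
                t2 = smaller.max()
                assert np.mean(d.distances <= t2) < p / 100.0

    def test_non_decreasing_in_p(self):
        d = dist(np.random.default_rng(7).random(60) * 10)
        ps = np.linspace(1, 100, 34)
        vals = [hd_percentile(d, p) for p in ps]
        assert np.all(np.diff(vals) >= 0)


class TestEfficiencyGain:
    def test_identical_contours_are_100_percent(self, iso_grid):
        s = extract_surface(sphere_mask(iso_grid, 10.0))
        d = distance_distribution(s, s, "a_to_b")
        assert efficiency_gain(d, 1.0) == 1.0

    def test_70_of_100_below_tolerance(self):
        d = dist([0.0] * 70 + [3.0] * 30)
        assert efficiency_gain(d, 1.0) == pytest.approx(0.70)

    def test_delta_beyond_max_is_one(self):
        d = dist([0.5, 2.0, 4.0])
        assert efficiency_gain(d, 4.0 + 1.0) == 1.0

    @given(st.integers(min_value=0, max_value=2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_non_decreasing_in_delta(self, seed):
        d = dist(np.random.default_rng(seed).random(40) * 5)
        deltas = [0.5, 1.0, 2.0, 4.0, 6.0]
        effs = [efficiency_gain(d, x) for x in deltas]
        assert np.all(np.diff(effs) >= 0)
        assert effs[-1] == 1.0

    def test_bad_arguments(self):
        with pytest.raises(ArgumentError):
            efficiency_gain(dist([1.0]), 0.0)
        with pytest.raises(EmptyStructureError):
            efficiency_gain(dist([]), 1.0)


class TestCompareStructures:
    def test_self_comparison(self, iso_grid):
        m = sphere_mask(iso_grid, 10.0)
        r = compare_structures(m, m)
        assert (r.dice, r.hd95, r.eff) == (1.0, 0.0, 1.0)
        assert r.hd95 <= r.hd_max

    def test_concentric_spheres_bundle(self, iso_grid):
        r = compare_structures(sphere_mask(iso_grid, 20.0), sphere_mask(iso_grid, 17.0))
        rho = 17.0 / 20.0
        assert r.dice == pytest.approx(2 * rho**3 / (1 + rho**3), abs=0.01)
        assert r.hd95 == pytest.approx(3.0, abs=np.sqrt(3.0))
        assert r.eff <= 0.05  # essentially no surface within 1 mm

    def test_z_shifted_sphere_matches_brute_force(self):
        grid = ImageGrid(origin=(0, 0, 0), spacing=(1, 1, 2.5), shape=(30, 30, 20))
        a = sphere_mask(grid, 8.0, center=(15, 15, 20))
        b = sphere_mask(grid, 8.0, center=(15, 15, 30))
        r = compare_structures(a, b)
        sa, sb = extract_surface(a), extract_surface(b)
        full = cdist(sa.points, sb.points)
        sym = np.sort(np.concatenate([full.min(axis=1), full.min(axis=0)]))
        k = int(np.ceil(0.95 * sym.size)) - 1
        assert r.hd95 == pytest.approx(sym[k])
        assert r.hd_max == pytest.approx(sym.max())
        assert r.eff == pytest.approx(np.mean(full.min(axis=1) < 1.0))

    def test_one_empty_mask_flags_degenerate(self, iso_grid):
        a = sphere_mask(iso_grid, 6.0)
        e = StructureMask(name="e", grid=iso_grid, data=np.zeros(iso_grid.shape, bool))
        r = compare_structures(a, e)
        assert r.degenerate and r.dice == 0.0 and np.isnan(r.hd95)

    def test_high_dice_can_hide_total_surface_disagreement(self):
        # the Dice critique, by construction: large concentric spheres with a
        # 2 mm gap everywhere -> Dice > 0.9 yet Eff(1 mm) ~ 0
        grid = ImageGrid(origin=(0, 0, 0), spacing=(1, 1, 1), shape=(125, 125, 125))
        a = sphere_mask(grid, 60.0)
        b = sphere_mask(grid, 58.0)
        r = compare_structures(a, b)
        assert r.dice > 0.9
        assert r.eff < 0.05
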