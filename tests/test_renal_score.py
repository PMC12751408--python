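import math

import numpy as np
import pytest

from nephroscore import phantom as ph
from nephroscore import renal_score as rs
from nephroscore import seg_eval as se
from nephroscore.io_volumes import LabelMask, VoxelVolume

from conftest import cube_mask, mask_from, sphere_mask


class TestLargestComponent:
    def test_keeps_biggest_of_two(self):
        m = np.zeros((20, 20, 20), bool)
        m[1:6, 1:6, 1:6] = True   # 5^3
        m[10:12, 10:12, 10:12] = True  # 2^3
        out = rs.largest_component(mask_from(m))
        assert out.count() == 125
        assert out.data[3, 3, 3] == 1 and out.data[10, 10, 10] == 0

    def test_single_component_identity(self):
        m = cube_mask((10, 10, 10), 2, 4)
        out = rs.largest_component(m)
        np.testing.assert_array_equal(out.data, m.data)

    def test_tie_broken_by_lowest_z(self):
        m = np.zeros((20, 20, 20), bool)
        m[2:5, 2:5, 10:13] = True  # higher z
        m[10:13, 10:13, 2:5] = True  # lower z wins
        out = rs.largest_component(mask_from(m))
        assert out.data[11, 11, 3] == 1 and out.data[3, 3, 11] == 0

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            rs.largest_component(mask_from(np.zeros((8, 8, 8), np.uint8)))


class TestMaxDiameter:
    @pytest.mark.parametrize("r", [10.0, 15.0])
    def test_digitized_sphere_diameter(self, r):
        m = sphere_mask(r, 0.5)
        assert rs.measure_max_diameter(m) == pytest.approx(
            2 * r, abs=math.sqrt(3) * 0.5)

    def test_axis_aligned_box_longest_edge(self):
        m = np.zeros((20, 20, 50), bool)
        m[5:15, 5:15, 5:45] = True  # 10 x 10 x 40 mm at 1 mm
        assert rs.measure_max_diameter(mask_from(m)) == pytest.approx(
            40.0, abs=math.sqrt(3))

    def test_rotated_box_invariance(self):
        th = math.radians(30)
        ct, st = math.cos(th), math.sin(th)
        n = 130
        ax = np.arange(n) * 0.5 - 32.5
        X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
        U = ct * X + st * Y
        V = -st * X + ct * Y
        m = (np.abs(U) <= 20) & (np.abs(V) <= 5) & (np.abs(Z) <= 5)
        d = rs.measure_max_diameter(LabelMask(m, (0.5,) * 3))
        assert d == pytest.approx(40.0, abs=2 * math.sqrt(3) * 0.5)

    def test_single_voxel_returns_max_spacing(self):
        m = np.zeros((9, 9, 9), bool)
        m[4, 4, 4] = True
        assert rs.measure_max_diameter(LabelMask(m, (0.5, 1.0, 2.0))) == 2.0


class TestExophyticFraction:
    def test_interior_tumor_is_fully_endophytic(self):
        spec = ph.ellipsoid_spec(seed=3)
        spec.tumor_center = (52.0, 46.0, 62.0)
        spec.tumor_radius = 12.0
        case, truth = ph.generate_phantom(spec)
        assert truth.exophytic_fraction == 0.0
        for mode in ("slice-ellipse", "slice-hull", "3d-hull"):
            assert rs.measure_exophytic_fraction(
                case.kidney, case.tumor, mode=mode) == 0.0

    def test_empty_kidney_raises(self):
        t = cube_mask((10, 10, 10), 3, 3)
        empty = mask_from(np.zeros((10, 10, 10), np.uint8))
        with pytest.raises(ValueError, match="parenchymal"):
            rs.measure_exophytic_fraction(empty, t)

    def test_lateral_protrusion_tracked_on_ellipsoid(self):
        case, truth = ph.generate_phantom(ph.ellipsoid_spec(seed=4),
                                          oracle_resolution_mm=0.5)
        measured = rs.measure_exophytic_fraction(case.kidney, case.tumor)
        assert measured == pytest.approx(truth.exophytic_fraction, abs=0.05)


class TestSinus:
    def test_phantom_sinus_recovered(self, ellipsoid_case):
        case, _ = ellipsoid_case
        spec = ph.ellipsoid_spec(seed=11)
        sinus = rs.segment_sinus(case.image, case.kidney)
        nx, ny, nz = spec.grid_shape
        X = np.arange(nx)[:, None, None]
        Y = np.arange(ny)[None, :, None]
        Z = np.arange(nz)[None, None, :]
        sc, sa = spec.sinus_center, spec.sinus_semiaxes
        true = (((X - sc[0]) / sa[0]) ** 2 + ((Y - sc[1]) / sa[1]) ** 2
                + ((Z - sc[2]) / sa[2]) ** 2) <= 1
        true &= ~case.tumor.bool
        assert se.dice(sinus, LabelMask(true, (1, 1, 1))) >= 0.95

    def test_out_of_window_sinus_is_empty(self):
        spec = ph.ellipsoid_spec(seed=2)
        spec.sinus_hu = -200.0
        case, _ = ph.generate_phantom(spec)
        assert rs.segment_sinus(case.image, case.kidney).count() == 0

    def test_uniform_parenchyma_has_no_sinus(self):
        spec = ph.ellipsoid_spec(seed=2)
        spec.sinus_semiaxes = None
        case, _ = ph.generate_phantom(spec)
        assert rs.segment_sinus(case.image, case.kidney).count() == 0


class TestSinusDistance:
    def test_overlapping_masks_give_zero(self):
        a = cube_mask((12, 12, 12), 2, 5)
        b = cube_mask((12, 12, 12), 4, 5)
        assert rs.measure_sinus_distance(a, b) == 0.0

    def test_single_voxel_pair(self):
        t = np.zeros((12, 12, 12), bool)
        s = np.zeros((12, 12, 12), bool)
        t[2, 5, 5] = True
        s[5, 5, 5] = True
        assert rs.measure_sinus_distance(mask_from(t), mask_from(s)) == 3.0

    def test_empty_sinus_returns_inf(self):
        t = cube_mask((10, 10, 10), 2, 3)
        empty = mask_from(np.zeros((10, 10, 10), np.uint8))
        assert math.isinf(rs.measure_sinus_distance(t, empty))

    def test_grid_mismatch_raises(self):
        t = cube_mask((10, 10, 10), 2, 3)
        s = cube_mask((12, 12, 12), 2, 3)
        with pytest.raises(ValueError, match="grid"):
            rs.measure_sinus_distance(t, s)


class TestPolar:
    def test_planes_at_sinus_extent(self):
        kidney = cube_mask((20, 20, 101), (2, 2, 0), (10, 10, 101))
        sinus = cube_mask((20, 20, 101), (5, 5, 40), (4, 4, 41))
        assert rs.locate_polar_planes(kidney, sinus) == (80.0, 40.0)

    def test_fallback_quartiles_of_kidney_extent(self):
        kidney = cube_mask((20, 20, 101), (2, 2, 0), (10, 10, 101))
        empty = mask_from(np.zeros((20, 20, 101), np.uint8))
        assert rs.locate_polar_planes(kidney, empty) == (75.0, 25.0)

    def test_thin_kidney_raises(self):
        kidney = cube_mask((20, 20, 10), (2, 2, 4), (10, 10, 2))
        empty = mask_from(np.zeros((20, 20, 10), np.uint8))
        with pytest.raises(ValueError, match="polar"):
            rs.locate_polar_planes(kidney, empty)

    def test_relation_categories(self):
        tumor = cube_mask((10, 10, 40), (2, 2, 25), (4, 4, 10))
        above = rs.measure_polar_relation(tumor, (20.0, 10.0))
        assert above.category == "entirely_polar" and above.crossing_fraction == 0
        inside = rs.measure_polar_relation(tumor, (36.0, 20.0))
        assert inside.category == "central" and inside.crossing_fraction == 1.0
        # 3 of 10 slices strictly inside the planes -> crosses at 0.30
        straddle = rs.measure_polar_relation(tumor, (28.0, 10.0))
        assert straddle.crossing_fraction == pytest.approx(0.30)
        assert straddle.category == "crosses"


class TestPointMapping:
    @pytest.mark.parametrize("measurements,expected", [
        ((35.0, 0.6, 8.0, "entirely_polar"), (1, 1, 1, 1)),
        ((80.0, 0.0, 2.0, "central"), (3, 3, 3, 3)),
        ((41.0, 0.5, 7.0, "crosses"), (2, 1, 1, 2)),
        ((40.0, 0.25, 4.0, "central"), (1, 2, 3, 3)),
        ((70.0, 1.0, 5.0, "crosses"), (3, 1, 2, 2)),
    ])
    def test_component_points(self, measurements, expected):
        d, e, n, cat = measurements
        polar = rs.PolarRelation(cat, 0.3, 10.0, 0.0)
        score = rs.score_components(
            rs.NephrometryMeasurements(d, e, n, polar))
        assert (score.r_pts, score.e_pts, score.n_pts, score.l_pts) == expected
        assert score.total == sum(expected)

    def test_no_sinus_maps_to_one_point_with_flag(self):
        polar = rs.PolarRelation("crosses", 0.3, 10.0, 0.0)
        score = rs.score_components(
            rs.NephrometryMeasurements(30.0, 0.2, math.inf, polar))
        assert score.n_pts == 1 and "NO_SINUS" in score.flags

    def test_monotonicity_of_mapping(self):
        diams = [5, 20, 40, 41, 55, 69, 70, 90]
        assert all(rs.points_for_radius(a) <= rs.points_for_radius(b)
                   for a, b in zip(diams, diams[1:]))
        dists = [20, 8, 7, 6.5, 4.5, 4, 1, 0]
        assert all(rs.points_for_nearness(a) <= rs.points_for_nearness(b)
                   for a, b in zip(dists, dists[1:]))
        fracs = [1.0, 0.7, 0.5, 0.49, 0.1, 0.0]
        assert all(rs.points_for_exophytic(a) <= rs.points_for_exophytic(b)
                   for a, b in zip(fracs, fracs[1:]))

    def test_stratification(self):
        assert rs.stratify_renal(5) == "low"
        assert rs.stratify_renal(7) == "moderate"
        assert rs.stratify_renal(10) == "high"
        for bad in (3, 13):
            with pytest.raises(ValueError):
                rs.stratify_renal(bad)


class TestPipeline:
    def test_end_to_end_matches_truth(self, ellipsoid_case):
        case, truth = ellipsoid_case
        score = rs.compute_renal_score(case)
        assert (score.r_pts, score.e_pts, score.n_pts, score.l_pts) == \
            truth.expected_points
        assert score.total == truth.expected_total
        assert score.stratum == truth.expected_stratum

    def test_report_dict_is_json_ready(self, ellipsoid_case):
        import json

        case, _ = ellipsoid_case
        d = rs.compute_renal_score(case).as_dict()
        json.dumps(d)
        assert d["total"] == d["r_pts"] + d["e_pts"] + d["n_pts"] + d["l_pts"]
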