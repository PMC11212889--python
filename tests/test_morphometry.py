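import dataclasses

import numpy as np
import pytest

from bundlekit3d import morphometry, phantoms
from bundlekit3d.morphometry import BinaryProjection, HeightMeasurement
from bundlekit3d.stackio import LabelVolume


def volume_from_planes(planes):
    return LabelVolume(np.asarray(planes, dtype=np.int64))


class TestProjectZ:
    def test_single_plane_projection_is_the_plane(self):
        plane = np.zeros((6, 6), dtype=np.int64)
        plane[2, 1:5] = 3
        vol = volume_from_planes([plane])
        proj = morphometry.project_z(vol, 3)
        np.testing.assert_array_equal(proj.grid, plane == 3)

    def test_repeated_support_idempotent(self):
        plane = np.zeros((6, 6), dtype=np.int64)
        plane[2:4, 2:4] = 1
        vol = volume_from_planes([plane] * 5)
        np.testing.assert_array_equal(morphometry.project_z(vol, 1).grid, plane == 1)

    def test_disjoint_planes_union(self):
        a = np.zeros((6, 6), dtype=np.int64)
        a[0, 0:3] = 1
        b = np.zeros((6, 6), dtype=np.int64)
        b[5, 3:6] = 1
        proj = morphometry.project_z(volume_from_planes([a, b]), 1)
        np.testing.assert_array_equal(proj.grid, (a == 1) | (b == 1))

    def test_unknown_id(self):
        vol = volume_from_planes([np.zeros((4, 4), dtype=np.int64)])
        with pytest.raises(KeyError):
            morphometry.project_z(vol, 9)


class TestTipBasePoints:
    def test_single_voxel_degenerate(self):
        labels = np.zeros((8, 10, 10), dtype=np.int64)
        labels[3, 7, 7] = 1
        m = morphometry.tip_base_points(volume_from_planes(labels), 1)
        assert m.tip == (7, 7, 3)
        assert m.base == (7, 7, 3)
        assert morphometry.bundle_height(m, (1, 1, 1)) == 0.0

    def test_tip_tie_breaks_to_min_x(self):
        plane = np.zeros((10, 12), dtype=np.int64)
        plane[2, 4] = 1
        plane[2, 9] = 1
        plane[3:6, 4] = 1
        m = morphometry.tip_base_points(volume_from_planes([plane]), 1)
        assert (m.tip[0], m.tip[1]) == (4, 2)

    def test_base_z_is_deepest_plane_of_component(self, small_phantom):
        _, labels, truth = small_phantom
        for rec in truth.table.itertuples():
            m = morphometry.tip_base_points(labels, rec.id)
            assert m.base[2] == rec.base_z
            assert m.tip == (rec.tip_x, rec.tip_y, rec.tip_z)
            assert m.base == (rec.base_x, rec.base_y, rec.base_z)


class TestBundleHeight:
    @pytest.mark.parametrize(
        "tip,base,voxel,expected",
        [
            ((0, 0, 0), (3, 4, 0), (1, 1, 1), 5.0),
            ((2, 2, 2), (2, 2, 2), (1, 1, 1), 0.0),
            # Δ(x,y,z) = (10,20,4) at the reference imaging scale:
            # sqrt(0.43² + 0.86² + 0.44²) = sqrt(1.1181)
            ((0, 0, 0), (10, 20, 4), (0.110, 0.043, 0.043), 1.05740),
        ],
    )
    def test_scaled_euclidean_distance(self, tip, base, voxel, expected):
        m = HeightMeasurement(bundle_id=1, tip=tip, base=base)
        assert morphometry.bundle_height(m, voxel) == pytest.approx(expected, abs=5e-5)

    def test_height_recovery_within_voxel_diagonal(self, small_cfg):
        diag = float(np.sqrt(sum(s**2 for s in small_cfg.voxel_size)))
        for seed in range(5):
            cfg = dataclasses.replace(small_cfg, seed=seed)
            _, labels, truth = phantoms.generate_stack(cfg)
            heights = morphometry.measure_heights(labels, cfg.voxel_size).set_index("id")
            for rec in truth.table.itertuples():
                assert abs(heights.loc[rec.id, "height_um"] - rec.height_um) <= diag


class TestRegionMeasurements:
    def test_solid_cube_closed_forms(self):
        labels = np.zeros((12, 12, 12), dtype=np.int64)
        labels[1:11, 1:11, 1:11] = 1
        table = morphometry.region_measurements(volume_from_planes(labels), (1, 1, 1))
        row = table.iloc[0]
        assert row.volume_voxels == 1000
        assert row.volume_um3 == pytest.approx(1000.0)
        assert row.surface_area_um2 == pytest.approx(600.0)
        assert row.depth_layers == 10
        assert (row.bbox_z0, row.bbox_z1) == (1, 11)

    def test_box_surface_area_closed_form(self, rng):
        a, b, c = 3, 5, 7
        labels = np.zeros((10, 10, 10), dtype=np.int64)
        labels[1 : 1 + a, 1 : 1 + b, 1 : 1 + c] = 1
        table = morphometry.region_measurements(volume_from_planes(labels), (1, 1, 1))
        assert table.iloc[0].surface_area_um2 == pytest.approx(2 * (a * b + b * c + c * a))

    def test_single_voxel_degenerate_values(self):
        labels = np.zeros((3, 5, 5), dtype=np.int64)
        labels[1, 2, 2] = 1
        row = morphometry.region_measurements(volume_from_planes(labels), (0.1, 0.2, 0.2)).iloc[0]
        assert row.volume_voxels == 1
        assert row.surface_area_um2 == pytest.approx(2 * 0.2 * 0.2 + 4 * 0.1 * 0.2)
        assert row.perimeter_um == pytest.approx(4 * 0.2)
        assert row.eccentricity == 0.0
        assert 0 < row.solidity <= 1

    def test_fifteen_metrics_present(self, small_phantom):
        _, labels, truth = small_phantom
        table = morphometry.region_measurements(labels, (0.110, 0.043, 0.043))
        named = [
            "volume_voxels", "volume_um3", "centroid_z", "surface_area_um2", "bbox_z0",
            "depth_layers", "projection_area_px", "perimeter_um", "eccentricity",
            "major_axis_px", "minor_axis_px", "equivalent_diameter_px", "solidity",
            "extent", "projection_orientation_deg",
        ]
        assert all(c in table.columns for c in named)
        merged = table.merge(truth.table, left_on="id", right_on="id")
        np.testing.assert_array_equal(merged.volume_voxels, merged.voxels)

    def test_relabeling_permutation_invariance(self, small_phantom):
        _, labels, _ = small_phantom
        table = morphometry.region_measurements(labels, (1, 1, 1))
        permuted = labels.labels.copy()
        permuted[labels.labels == 1] = 99
        table_p = morphometry.region_measurements(LabelVolume(permuted), (1, 1, 1))
        a = table[table.id == 1].drop(columns="id").reset_index(drop=True)
        b = table_p[table_p.id == 99].drop(columns="id").reset_index(drop=True)
        assert a.equals(b)


def v_projection(peak=(50, 10), base_y=40, half_width=20):
    """Ideal one-pixel-wide V for angle arithmetic tests."""
    grid = np.zeros((60, 100), dtype=bool)
    px, py = peak
    n = base_y - py
    for i in range(n + 1):
        off = round(i * half_width / n)
        grid[py + i, px - off] = True
        grid[py + i, px + off] = True
    return BinaryProjection(grid=grid, bundle_id=1)


class TestAngles:
    def test_symmetric_v_reference_angles(self):
        baseline, axis, apex = morphometry.angles_from_points((30, 40), (70, 40), (50, 10))
        assert baseline == pytest.approx(0.0)
        assert axis == pytest.approx(90.0)
        assert apex == pytest.approx(2 * np.degrees(np.arctan(20 / 30)), abs=1e-6)

    def test_displaced_peak(self):
        _, axis, _ = morphometry.angles_from_points((30, 40), (70, 40), (55, 10))
        # atan2(-30, 5) mapped to [0, 180) -> 99.46°
        assert axis == pytest.approx(np.degrees(np.arctan2(-30, 5)) % 180, abs=1e-6)

    def test_coincident_points_rejected(self):
        with pytest.raises(ValueError):
            morphometry.angles_from_points((3, 3), (3, 3), (0, 0))


class TestOrientation:
    def test_symmetric_v_axis_exactly_90(self):
        proj = v_projection()
        for fn in (morphometry.orientation_height_only, morphometry.orientation_height_distance):
            res = fn(proj)
            assert res.axis_angle_deg == 90.0
            assert res.baseline_angle_deg == 0.0
            assert res.left == (30.0, 40.0)
            assert res.right == (70.0, 40.0)

    def test_height_distance_prefers_remote_point_within_band(self):
        proj = v_projection()
        # a hook: near-lowest pixel on the left that is farther from the peak
        proj.grid[39, 5] = True
        ho = morphometry.orientation_height_only(proj)
        hd = morphometry.orientation_height_distance(proj, tolerance_px=2)
        assert ho.left == (30.0, 40.0)   # strictly lowest wins
        assert hd.left == (5.0, 39.0)    # most remote within the 2-px band

    def test_tolerance_zero_restricts_to_lowest_row(self):
        proj = v_projection()
        proj.grid[39, 5] = True
        hd0 = morphometry.orientation_height_distance(proj, tolerance_px=0)
        assert hd0.left == (30.0, 40.0)

    def test_phantom_angle_recovery(self, small_cfg):
        for rot in (10.0, -10.0, 15.0):
            cfg = dataclasses.replace(
                small_cfg, rotation_deg=rot, wing_length_px=60.0, depth=8,
                shape=(16, 384, 384), x_margin=80.0, row_y=(120.0,),
            )
            _, labels, truth = phantoms.generate_stack(cfg)
            for method in ("height_only", "height_distance"):
                ori = morphometry.measure_orientations(labels, method=method)
                err = np.abs(ori.orientation_deg.values - truth.table.axis_angle_deg.values)
                assert err.max() < 3.0, (rot, method, err)

    def test_rotation_leaves_height_nearly_unchanged(self):
        cfg0 = phantoms.PhantomConfig(
            shape=(30, 384, 384), row_y=(110.0,), bundles_per_row=2, x_margin=80.0, seed=2
        )
        cfg15 = dataclasses.replace(cfg0, rotation_deg=15.0)
        _, l0, _ = phantoms.generate_stack(cfg0)
        _, l15, _ = phantoms.generate_stack(cfg15)
        h0 = morphometry.measure_heights(l0, cfg0.voxel_size).height_um.values
        h15 = morphometry.measure_heights(l15, cfg15.voxel_size).height_um.values
        assert np.abs(h15 / h0 - 1).max() < 0.05
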