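import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import stereogold as sg
from stereogold import atlas, mapping, synthetic
from stereogold.exceptions import ConsistencyError, ParameterError

from conftest import cylinder_cloud, make_geometry, rotation_matrix_zyx, rotate_zyx


class TestSegmentsAndSectors:
    @pytest.mark.parametrize(
        "height_nm,expected", [(2390.0, 12), (1930.0, 10), (1240.0, 6)]
    )
    def test_printed_row_segment_counts(self, height_nm, expected):
        assert atlas.n_segments_for(height_nm) == expected

    def test_minimum_one_segment(self):
        assert atlas.n_segments_for(40.0) == 1

    @pytest.mark.parametrize(
        "azimuth,expected",
        [(0.0, "anterior"), (-180.0, "posterior"), (90.0, "lateral_left"),
         (-90.0, "lateral_right"), (44.999, "anterior"), (45.0, "lateral_left"),
         (135.0, "posterior"), (-135.0, "lateral_right")],
    )
    def test_sector_conventions(self, azimuth, expected):
        assert atlas.sector_of(azimuth) == expected

    @settings(max_examples=200, deadline=None)
    @given(a=st.floats(-180.0, 179.999))
    def test_sector_matches_exhaustive_angle_check(self, a):
        # independent check: nearest sector center at 0/90/180/-90
        centers = {"anterior": 0.0, "lateral_left": 90.0, "lateral_right": -90.0}
        best, bestd = "posterior", min(abs(a - 180.0), abs(a + 180.0))
        for name, c in centers.items():
            d = abs(a - c)
            if d < bestd:
                best, bestd = name, d
        if bestd != 45.0:  # exact boundaries are convention, skip them
            assert atlas.sector_of(a) == best

    def test_sector_area_formula(self):
        assert round(atlas.sector_area_um2(157.0), 3) == 0.025
        assert atlas.sector_area_um2(182.0) == pytest.approx(0.028, abs=0.001)
        assert atlas.sector_area_um2(129.0) == pytest.approx(0.021, abs=0.001)
        assert atlas.sector_area_um2(0.0) == 0.0


def _row_of_cilia(bases, angle_from_y_deg=0.0, length=1000.0, radius=60.0):
    """Cilia along +z with base centroids on a line in the (y, x) plane."""
    geoms = []
    for i, s in enumerate(bases):
        a = math.radians(angle_from_y_deg)
        base = np.array([0.0, s * math.cos(a), s * math.sin(a)])
        pts = cylinder_cloud(length, radius, n=400, rng=i, origin=base)
        geoms.append(
            make_geometry(i + 1, pts, [1, 0, 0], base, base + [length, 0, 0])
        )
    return geoms


class TestAzimuthCorrection:
    def test_straight_row_zero_rotation(self):
        geoms = _row_of_cilia([-300.0, 0.0, 300.0])
        corr = atlas.azimuth_correction(geoms[1], geoms, np.array([0.0, 0.0, 1.0]))
        assert corr.angle_deg == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(corr.local_normal, [0.0, 0.0, 1.0])

    def test_inclined_arm_rotation_angle(self):
        # row line tilted 30 deg from +y: local normal sits 30 deg from the
        # mechano direction, so the correction rotates by 30 deg
        geoms = _row_of_cilia([-300.0, 0.0, 300.0], angle_from_y_deg=30.0)
        corr = atlas.azimuth_correction(geoms[1], geoms, np.array([0.0, 0.0, 1.0]))
        assert abs(corr.angle_deg) == pytest.approx(30.0, abs=1e-6)

    def test_single_cilium_identity_with_warning(self, caplog):
        geoms = _row_of_cilia([0.0])
        with caplog.at_level("WARNING", logger="stereogold.atlas"):
            corr = atlas.azimuth_correction(geoms[0], geoms, np.array([0.0, 0.0, 1.0]))
        assert corr.angle_deg == 0.0
        assert any("no same-row neighbor" in r.message for r in caplog.records)

    def test_row_end_uses_single_neighbor(self):
        geoms = _row_of_cilia([-300.0, 0.0, 300.0])
        corr = atlas.azimuth_correction(geoms[0], geoms, np.array([0.0, 0.0, 1.0]))
        assert corr.angle_deg == pytest.approx(0.0, abs=1e-9)


def _bead_on(geom, frac, azimuth_deg, normal):
    """A ProjectedBead whose surface point sits at the given height/azimuth."""
    lvec = atlas.cross_zyx(geom.axis, normal)
    ang = math.radians(azimuth_deg)
    radius = geom.diameter_nm / 2
    sp = (
        geom.taper_nm
        + frac * geom.height_nm * geom.axis
        + radius * (math.cos(ang) * normal + math.sin(ang) * lvec)
    )
    return mapping.ProjectedBead(
        bead_id=int(frac * 1000 + azimuth_deg),
        centroid_nm=sp,
        cilium_id=geom.cilium_id,
        surface_point_nm=sp,
        distance_nm=0.0,
        nearest_distance_nm=0.0,
        discarded=False,
    )


class TestCanonicalize:
    def test_height_scale_and_tip_fraction(self):
        geoms = _row_of_cilia([-300.0, 0.0, 300.0])
        corr = atlas.azimuth_correction(geoms[1], geoms, np.array([0.0, 0.0, 1.0]))
        normal = corr.local_normal
        tip_bead = _bead_on(geoms[1], 1.0, 10.0, normal)
        canon = atlas.canonicalize(geoms[1], corr, row_max_height_nm=1200.0, beads=[tip_bead])
        assert canon.height_scale == pytest.approx(1000.0 / 1200.0)
        assert tip_bead.height_fraction == pytest.approx(1.0)
        # tallest cilium of a row has scale exactly 1
        canon2 = atlas.canonicalize(geoms[1], corr, row_max_height_nm=geoms[1].height_nm)
        assert canon2.height_scale == 1.0

    def test_bead_azimuth_round_trip(self):
        geoms = _row_of_cilia([-300.0, 0.0, 300.0])
        corr = atlas.azimuth_correction(geoms[1], geoms, np.array([0.0, 0.0, 1.0]))
        for az in (-170.0, -90.0, 0.0, 30.0, 145.0):
            bead = _bead_on(geoms[1], 0.5, az, corr.local_normal)
            atlas.canonicalize(geoms[1], corr, 1000.0, beads=[bead])
            assert bead.azimuth_deg == pytest.approx(az, abs=1e-6)
            assert bead.sector == atlas.sector_of(az)

    def test_rotated_copies_identical_canonical_clouds(self):
        geoms = _row_of_cilia([-300.0, 0.0, 300.0])
        mech = np.array([0.0, 0.0, 1.0])
        corr = atlas.azimuth_correction(geoms[1], geoms, mech)
        bead = _bead_on(geoms[1], 0.4, 60.0, corr.local_normal)
        canon = atlas.canonicalize(geoms[1], corr, 1000.0, beads=[bead])

        R = rotation_matrix_zyx([0.3, 1.0, -0.2], 1.1)
        rot_geoms = []
        for g in geoms:
            rot_geoms.append(
                make_geometry(
                    g.cilium_id,
                    rotate_zyx(g.surface_points, R),
                    R @ g.axis,
                    R @ g.taper_nm,
                    R @ g.tip_nm,
                    diameter_nm=g.diameter_nm,
                )
            )
        corr_r = atlas.azimuth_correction(rot_geoms[1], rot_geoms, R @ mech)
        bead_r = _bead_on(rot_geoms[1], 0.4, 60.0, corr_r.local_normal)
        canon_r = atlas.canonicalize(rot_geoms[1], corr_r, 1000.0, beads=[bead_r])
        assert np.allclose(canon.canonical_points, canon_r.canonical_points, atol=1e-6)
        assert bead_r.azimuth_deg == pytest.approx(bead.azimuth_deg, abs=1e-6)
        assert bead_r.height_fraction == pytest.approx(bead.height_fraction, abs=1e-9)

    def test_row_max_smaller_than_height_rejected(self):
        geoms = _row_of_cilia([0.0, 300.0])
        corr = atlas.azimuth_correction(geoms[0], geoms, np.array([0.0, 0.0, 1.0]))
        with pytest.raises(ParameterError):
            atlas.canonicalize(geoms[0], corr, row_max_height_nm=500.0)


class TestDensityMap:
    def _canon(self, geoms, beads_by_cilium=None):
        mech = np.array([0.0, 0.0, 1.0])
        out = []
        row_max = max(g.height_nm for g in geoms)
        for g in geoms:
            corr = atlas.azimuth_correction(g, geoms, mech)
            out.append(
                atlas.canonicalize(
                    g, corr, row_max, beads=(beads_by_cilium or {}).get(g.cilium_id, [])
                )
            )
        return out

    def test_zero_beads_all_zero(self):
        geoms = _row_of_cilia([-300.0, 0.0, 300.0])
        canon = self._canon(geoms)
        dmap = atlas.compute_density_map([], canon, {"tall": 157.0}, n_segments={"tall": 12})
        assert dmap.total_count == 0
        assert np.all(dmap.rows["tall"].density == 0.0)

    def test_three_beads_one_bin_arithmetic(self):
        geoms = _row_of_cilia([-300.0, 0.0, 300.0])
        mech = np.array([0.0, 0.0, 1.0])
        corr = atlas.azimuth_correction(geoms[0], geoms, mech)
        beads = [_bead_on(geoms[0], 0.99, az, corr.local_normal) for az in (-10.0, 0.0, 10.0)]
        for i, b in enumerate(beads):
            b.bead_id = i
        canon = self._canon(geoms, {1: beads})
        dmap = atlas.compute_density_map(beads, canon, {"tall": 157.0}, n_segments={"tall": 12})
        rd = dmap.rows["tall"]
        assert rd.counts[11, atlas.SECTORS.index("anterior")] == 3
        expected = 3.0 / (atlas.sector_area_um2(157.0) * 3)
        assert rd.density[11, 0] == pytest.approx(expected)

    def test_unknown_cilium_rejected(self):
        geoms = _row_of_cilia([-300.0, 0.0, 300.0])
        mech = np.array([0.0, 0.0, 1.0])
        corr = atlas.azimuth_correction(geoms[0], geoms, mech)
        bead = _bead_on(geoms[0], 0.5, 0.0, corr.local_normal)
        bead.cilium_id = 99
        canon = self._canon(geoms)
        with pytest.raises(ConsistencyError):
            atlas.compute_density_map([bead], canon, {"tall": 157.0})

    def test_bin_partition_conserves_counts(self, small_analysis):
        assigned = sum(not p.discarded for p in small_analysis.projected)
        assert small_analysis.density_map.total_count == assigned

    def test_uniform_rate_bins_within_poisson_error(self):
        rate = 60.0
        spec = sg.BundlePhantomSpec(
            bead_density_field=synthetic.uniform_field(rate), rng_seed=5
        )
        vol, truth = sg.generate_bundle_phantom(spec)
        res = sg.map_bundle(vol, seed=0)
        for row, rd in res.density_map.rows.items():
            h = truth.cilia[truth.cilia.row == row].height_nm.mean()
            area = math.pi * spec.row_diameter_nm[row] * (h / rd.n_segments) / 4 * 1e-6
            expected = rate * area * rd.n_cilia
            dev = np.abs(rd.counts - expected) / math.sqrt(expected)
            assert dev.max() <= 3.0

    def test_density_map_rotation_invariance(self):
        rng = np.random.default_rng(8)
        geoms = _row_of_cilia([-300.0, 0.0, 300.0])
        mech = np.array([0.0, 0.0, 1.0])
        beads = rng.uniform([-100, -500, -200], [1100, 500, 200], size=(60, 3))

        def run(geo_list, mech_vec, bead_coords):
            import pandas as pd

            table = pd.DataFrame(
                {
                    "bead_id": np.arange(len(bead_coords)),
                    "z_nm": bead_coords[:, 0],
                    "y_nm": bead_coords[:, 1],
                    "x_nm": bead_coords[:, 2],
                }
            )
            projected = mapping.project_beads(table, geo_list, k=10)
            by_c = {}
            for p in projected:
                if not p.discarded:
                    by_c.setdefault(p.cilium_id, []).append(p)
            row_max = max(g.height_nm for g in geo_list)
            canon = []
            for g in geo_list:
                corr = atlas.azimuth_correction(g, geo_list, mech_vec)
                canon.append(atlas.canonicalize(g, corr, row_max, beads=by_c.get(g.cilium_id, [])))
            return atlas.compute_density_map(
                projected, canon, {"tall": 120.0}, n_segments={"tall": 5}
            )

        dmap = run(geoms, mech, beads)
        R = rotation_matrix_zyx([1.0, 0.5, -0.3], 0.8)
        rot_geoms = [
            make_geometry(
                g.cilium_id,
                rotate_zyx(g.surface_points, R),
                R @ g.axis,
                R @ g.taper_nm,
                R @ g.tip_nm,
                diameter_nm=g.diameter_nm,
            )
            for g in geoms
        ]
        dmap_r = run(rot_geoms, R @ mech, rotate_zyx(beads, R))
        assert dmap == dmap_r


class TestRepresentativeSurface:
    def test_single_cilium_is_own_cloud(self):
        geoms = _row_of_cilia([0.0])
        mech = np.array([0.0, 0.0, 1.0])
        corr = atlas.azimuth_correction(geoms[0], geoms, mech)
        canon = atlas.canonicalize(geoms[0], corr, geoms[0].height_nm)
        pts, _ = atlas.representative_surface([canon], target_count=10**6)
        assert np.array_equal(pts, canon.canonical_points)

    def test_decimation_and_containment(self):
        geoms = _row_of_cilia([-300.0, 300.0])
        mech = np.array([0.0, 0.0, 1.0])
        canon = [
            atlas.canonicalize(g, atlas.azimuth_correction(g, geoms, mech), 1000.0)
            for g in geoms
        ]
        pts, _ = atlas.representative_surface(canon, target_count=100, seed=0)
        assert len(pts) == 100
        radius = np.hypot(pts[:, 1], pts[:, 2])
        assert radius.max() <= 60.0 + 1e-6

    def test_overlay_mean_radius_matches_spec(self):
        geoms = _row_of_cilia([-300.0, 0.0, 300.0], radius=80.0)
        mech = np.array([0.0, 0.0, 1.0])
        canon = [
            atlas.canonicalize(g, atlas.azimuth_correction(g, geoms, mech), 1000.0)
            for g in geoms
        ]
        pts, _ = atlas.representative_surface(canon, target_count=2000, seed=0)
        mid = (pts[:, 0] >= 250.0) & (pts[:, 0] <= 750.0)
        assert np.hypot(pts[mid, 1], pts[mid, 2]).mean() == pytest.approx(80.0, rel=0.05)
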