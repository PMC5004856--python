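"""Designs: ring geometry, increment placement, schedules, enumeration."""

import numpy as np
import pytest

from larvalsens import design as dz
from larvalsens import synthetic_ocean as so
from larvalsens._geo import M_PER_DEG, haversine_km


class TestRingReleasePoints:
    def test_sixteen_points_equally_spaced(self, guyot):
        _, topo = guyot
        pts = dz.ring_release_points(topo, 1000.0, 16)
        assert [p.id for p in pts] == list(range(16))
        d = [haversine_km(pts[i].lon, pts[i].lat,
                          pts[(i + 1) % 16].lon, pts[(i + 1) % 16].lat)
             for i in range(16)]
        assert np.ptp(d) / np.mean(d) < 1e-3
        # id 0 due north of the centroid, ids clockwise
        clon = np.mean([p.lon for p in pts])
        assert abs(pts[0].lon - clon) < 1e-3
        assert pts[4].lon > clon  # quarter turn clockwise = due east

    @pytest.mark.parametrize("depth", [700.0, 1000.0, 1500.0])
    def test_points_lie_on_the_requested_contour(self, guyot, depth):
        _, topo = guyot
        for p in dz.ring_release_points(topo, depth, 16):
            assert float(topo.depth_at(p.lon, p.lat)) == pytest.approx(depth, abs=0.5)

    def test_no_closed_contour_is_an_error(self, guyot):
        _, topo = guyot
        with pytest.raises(ValueError, match="contour"):
            dz.ring_release_points(topo, 550.0, 16)  # shallower than the summit

    def test_ring_invariant_under_longitude_shift(self):
        """Rotating the guyot in longitude rotates the ring rigidly."""
        rings = []
        for lon0 in (0.0, 1.5):
            grid = so.GridSpec(lon_min=lon0 - 2, lon_max=lon0 + 2,
                               lat_min=-2, lat_max=2, z_levels=(700.0,),
                               n_snapshots=1)
            topo = so.make_guyot_topography(grid, centre=(lon0, 0.0))
            rings.append(dz.ring_release_points(topo, 1000.0, 8))
        for a, b in zip(*rings):
            assert b.lon - a.lon == pytest.approx(1.5, abs=1e-6)
            assert b.lat == pytest.approx(a.lat, abs=1e-6)


class TestOffsetAlongContour:
    def test_small_offset_arc_length(self, guyot):
        """0.001 degrees of buffer radius is a 111.19 m along-contour arc."""
        _, topo = guyot
        p = dz.ring_release_points(topo, 1000.0, 16)[3]
        q = dz.offset_along_contour(p, 0.001, topo)
        moved = haversine_km(p.lon, p.lat, q.lon, q.lat) * 1000.0
        assert moved == pytest.approx(111.19, rel=2e-3)
        assert q.role == "increment" and q.increment == 0.001

    def test_offsets_are_additive_on_the_contour(self, guyot):
        _, topo = guyot
        p = dz.ring_release_points(topo, 1000.0, 16)[5]
        two_steps = dz.offset_along_contour(
            dz.offset_along_contour(p, 0.001, topo), 0.004, topo)
        one_step = dz.offset_along_contour(p, 0.005, topo)
        assert two_steps.lon == pytest.approx(one_step.lon, abs=1e-9)
        assert two_steps.lat == pytest.approx(one_step.lat, abs=1e-9)

    def test_offset_point_keeps_depth_and_contour(self, guyot):
        _, topo = guyot
        p = dz.ring_release_points(topo, 1000.0, 16)[0]
        q = dz.offset_along_contour(p, 0.025, topo)
        assert q.depth == p.depth
        assert float(topo.depth_at(q.lon, q.lat)) == pytest.approx(1000.0, abs=0.5)

    def test_offset_beyond_half_contour_rejected(self, guyot):
        _, topo = guyot
        p = dz.ring_release_points(topo, 1000.0, 16)[0]
        with pytest.raises(ValueError, match="half the contour"):
            dz.offset_along_contour(p, 2.0, topo)


class TestOffsetDepth:
    def test_shallower_displacements(self):
        p = dz.ReleasePoint(id=0, lon=0, lat=0, depth=1000.0)
        assert dz.offset_depth(p, -50.0).depth == 950.0
        q = dz.offset_depth(dz.ReleasePoint(id=0, lon=0, lat=0, depth=200.0), -0.1)
        assert q.depth == pytest.approx(199.9)
        assert (q.lon, q.lat) == (0.0, 0.0)

    def test_zero_offset_is_identity(self):
        p = dz.ReleasePoint(id=0, lon=0, lat=0, depth=1000.0)
        assert dz.offset_depth(p, 0.0) is p

    def test_surfacing_rejected(self):
        p = dz.ReleasePoint(id=0, lon=0, lat=0, depth=30.0)
        with pytest.raises(ValueError):
            dz.offset_depth(p, -40.0)


class TestSchedules:
    @pytest.mark.parametrize("label,count", [
        ("daily", 365), ("2-daily", 183), ("biweekly", 104),
        ("weekly", 52), ("monthly", 12), ("seasonal", 4)])
    def test_standard_frequency_counts(self, label, count):
        sched = dz.build_release_schedule(1, label)
        assert len(sched) == count
        assert np.all(np.diff(sched.times) > 0)
        assert sched.times[-1] < 365.0

    def test_multi_year_and_explicit_count(self):
        sched = dz.build_release_schedule(3, 12)
        assert len(sched) == 36
        assert sched.times[12] == pytest.approx(365.0)

    def test_nao_tagging(self):
        sched = dz.build_release_schedule(5, "monthly", start_year=2008)
        assert sched.nao_states[2010] == "strong negative"
        assert sched.nao_states[2012] == "strong positive"
        assert sched.nao_states[2008] == "unclassified"

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="frequency"):
            dz.build_release_schedule(1, "fortnightly")


class TestYearCombinations:
    @pytest.mark.parametrize("k,expected", [(1, 5), (2, 10), (3, 10),
                                            (4, 5), (5, 1)])
    def test_five_year_subset_counts(self, k, expected):
        combos = dz.year_combinations([2008, 2009, 2010, 2011, 2012], k)
        assert len(combos) == expected
        assert combos == sorted(combos, key=lambda c: c.years)

    def test_nao_states_tagged(self):
        combos = dz.year_combinations([2009, 2010, 2012], 3)
        assert combos[0].nao_states == ("neutral", "strong negative",
                                        "strong positive")

    def test_k_out_of_range(self):
        with pytest.raises(ValueError):
            dz.year_combinations([2008, 2009], 3)


class TestEnumeration:
    def test_standard_spatial_design_counts(self):
        """16 points x 3 depths x 12 monthly releases x 4 increments."""
        pts = [dz.ReleasePoint(id=i, lon=0, lat=0, depth=d)
               for d in (700.0, 1000.0, 1500.0) for i in range(16)]
        design = dz.ExperimentDesign(
            points=pts, schedule=dz.build_release_schedule(1, "monthly"),
            sweep=dz.ParameterSweep.default("HS"))
        counts = dz.enumerate_design(design)
        assert counts.baseline_tracks == 576
        assert counts.total_particles == 2880
        assert counts.points_per_depth == 16 and counts.n_depths == 3

    def test_release_frequency_extremes(self):
        pts = [dz.ReleasePoint(id=i, lon=0, lat=0, depth=d)
               for d in (700.0, 1000.0, 1500.0) for i in range(16)]
        daily = dz.ExperimentDesign(
            points=pts, schedule=dz.build_release_schedule(1, "daily"))
        assert dz.enumerate_design(daily).baseline_tracks == 17520
        seasonal = dz.ExperimentDesign(
            points=pts, schedule=dz.build_release_schedule(1, "seasonal"))
        assert dz.enumerate_design(seasonal).baseline_tracks == 192

    def test_zero_increments_total_equals_baseline(self):
        pts = [dz.ReleasePoint(id=0, lon=0, lat=0, depth=700.0)]
        design = dz.ExperimentDesign(
            points=pts, schedule=dz.build_release_schedule(1, "monthly"))
        counts = dz.enumerate_design(design)
        assert counts.total_particles == counts.baseline_tracks == 12

    def test_enumeration_matches_release_units(self):
        pts = [dz.ReleasePoint(id=i, lon=0.1 * i, lat=0, depth=500.0)
               for i in range(4)]
        design = dz.ExperimentDesign(
            points=pts, schedule=dz.build_release_schedule(1, "seasonal"))
        assert dz.enumerate_design(design).baseline_tracks == len(design.release_units())


class TestSweepsAndPersistence:
    def test_default_sweeps_match_the_standard_table(self):
        assert dz.ParameterSweep.default("TS").increments == (3.0, 6.0, 12.0, 24.0)
        assert dz.ParameterSweep.default("HS").increments == (0.001, 0.005, 0.01, 0.025)
        assert dz.ParameterSweep.default("VS").increments == (-0.1, -1.0, -10.0, -50.0)
        assert dz.ParameterSweep.default("RF").increments == (183.0, 104.0, 52.0, 12.0, 4.0)
        assert dz.ParameterSweep.default("TR").baseline == 5.0

    def test_duplicate_or_unordered_increments_rejected(self):
        with pytest.raises(ValueError):
            dz.ParameterSweep("HS", 0.0, (0.001, 0.001))
        with pytest.raises(ValueError):
            dz.ParameterSweep("HS", 0.0, (0.005, 0.001, 0.01))

    def test_design_yaml_round_trip(self, tmp_path, guyot):
        _, topo = guyot
        design = dz.ExperimentDesign(
            points=dz.ring_release_points(topo, 1000.0, 4),
            schedule=dz.build_release_schedule(1, "seasonal", start_year=2012),
            sweep=dz.ParameterSweep.default("HS"))
        path = tmp_path / "design.yaml"
        dz.save_design(design, path)
        back = dz.load_design(path)
        assert len(back.points) == 4
        assert back.points[2].lon == pytest.approx(design.points[2].lon)
        assert back.sweep.increments == design.sweep.increments
        assert np.allclose(back.schedule.times, design.schedule.times)
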