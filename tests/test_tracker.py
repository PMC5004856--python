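"""Tracker: velocity sampling, RK4 advection, batch runs, trajectory I/O."""

import numpy as np
import pytest

from larvalsens import design as dz
from larvalsens import synthetic_ocean as so
from larvalsens import tracker as tk
from larvalsens._geo import M_PER_DEG

from conftest import make_series

OMEGA = 1e-5  # s^-1, solid-body rotation rate used in orbit tests


def rotation_series(n_snapshots=2, snapshot_interval=10.0):
    """Static solid-body rotation about (0, 0) on an equatorial tangent plane."""
    return make_series(
        u=lambda LON, LAT: -OMEGA * LAT * M_PER_DEG,
        v=lambda LON, LAT: OMEGA * LON * M_PER_DEG,
        lon=(-0.4, 0.4), lat=(-0.4, 0.4), spacing=0.02,
        n_snapshots=n_snapshots, snapshot_interval=snapshot_interval)


class TestSampleVelocity:
    def test_constant_field_everywhere(self):
        series = make_series(u=0.1, v=-0.05)
        for q in [(-1.9, -1.9, 500.0, 0.0), (0.33, 1.2, 777.0, 1.6),
                  (1.99, 0.0, 1000.0, 2.0)]:
            u, v = tk.sample_velocity(series, *q)
            assert u == pytest.approx(0.1, abs=1e-12)
            assert v == pytest.approx(-0.05, abs=1e-12)

    def test_reproduces_stored_value_at_grid_node(self):
        rng = np.random.default_rng(0)
        series = make_series(z_levels=(500.0, 1000.0), n_snapshots=3)
        series.u[:] = rng.normal(size=series.u.shape)
        g = series.grid
        i, j, k, t = 7, 11, 1, 2
        u, v = tk.sample_velocity(series, g.lons[i], g.lats[j],
                                  g.z_levels[k], g.times[t])
        assert u == pytest.approx(series.u[t, k, j, i], abs=1e-12)

    def test_bilinear_cell_centre_hand_computation(self):
        """Corners (0, 2, 4, 6) average to 3 at the cell centre."""
        series = make_series(z_levels=(500.0,), n_snapshots=1)
        g = series.grid
        series.u[0, 0, 10, 10] = 0.0
        series.u[0, 0, 10, 11] = 2.0
        series.u[0, 0, 11, 10] = 4.0
        series.u[0, 0, 11, 11] = 6.0
        lon = g.lons[10] + 0.5 * g.spacing
        lat = g.lats[10] + 0.5 * g.spacing
        u, _ = tk.sample_velocity(series, lon, lat, 500.0, 0.0, mode="linear")
        assert u == pytest.approx(3.0, abs=1e-12)

    def test_out_of_bounds_raises_domain_error(self):
        series = make_series()
        with pytest.raises(tk.DomainError):
            tk.sample_velocity(series, 5.0, 0.0, 500.0, 0.0)
        with pytest.raises(tk.DomainError):
            tk.sample_velocity(series, 0.0, 0.0, 500.0, 99.0)

    def test_linear_depth_interpolation_between_levels(self):
        series = make_series(z_levels=(500.0, 1000.0), n_snapshots=1)
        series.u[:, 0] = 0.1
        series.u[:, 1] = 0.3
        u, _ = tk.sample_velocity(series, 0.0, 0.0, 750.0, 0.0)
        assert u == pytest.approx(0.2, abs=1e-12)


class TestRk4Step:
    def test_zero_field_is_a_fixed_point(self):
        series = make_series(u=0.0, v=0.0)
        st = tk.ParticleState(0.3, -0.2, 700.0, 0.0)
        out = tk.rk4_step(series, st, 3600.0)
        assert (out.lon, out.lat) == (0.3, -0.2)
        assert out.status == "active"

    def test_uniform_flow_displacement_matches_metric(self):
        """u = 0.1 m/s at the equator moves 0.003238 deg/hour east."""
        series = make_series(u=0.1, v=0.0)
        out = tk.rk4_step(series, tk.ParticleState(0.0, 0.0, 700.0, 0.0), 3600.0)
        assert out.lon == pytest.approx(0.1 * 3600.0 / M_PER_DEG, rel=1e-12)
        assert out.lat == pytest.approx(0.0, abs=1e-15)

    def test_solid_body_orbit_closes_after_one_period(self):
        series = rotation_series()
        period = 2 * np.pi / OMEGA
        dt = period / 1000.0
        st = tk.ParticleState(0.05, 0.0, 700.0, 0.0)
        for _ in range(1000):
            st = tk.rk4_step(series, st, dt)
            assert st.status == "active"
        err = np.hypot(st.lon - 0.05, st.lat - 0.0)
        assert err < 1e-3 * 0.05


class TestAdvection:
    def test_zero_field_emits_identical_daily_records(self):
        series = make_series(u=0.0, v=0.0, n_snapshots=12)
        cfg = tk.TrackerConfig(pld_days=10)
        release = dz.ReleasePoint(id=0, lon=0.1, lat=0.1, depth=700.0)
        track = tk.advect_particle(series, release, 0.0, cfg)
        assert len(track) == 11
        assert track.status == "active"
        assert np.all(track.lons == 0.1) and np.all(track.lats == 0.1)

    def test_flow_off_the_grid_escapes_and_freezes(self):
        series = make_series(u=1.0, v=0.0, n_snapshots=12)
        cfg = tk.TrackerConfig(pld_days=10)
        release = dz.ReleasePoint(id=0, lon=1.9, lat=0.0, depth=700.0)
        track = tk.advect_particle(series, release, 0.0, cfg)
        assert track.status == "escaped"
        assert len(track) == 11  # record count unaffected by status
        assert track.lons[-1] == track.lons[-2]  # frozen at last valid position
        assert track.lons[-1] <= 2.0

    def test_uniform_flow_daily_positions_colinear_equal_spacing(self):
        series = make_series(u=0.2, v=0.0, n_snapshots=8)
        cfg = tk.TrackerConfig(pld_days=5)
        release = dz.ReleasePoint(id=0, lon=-1.5, lat=0.0, depth=700.0)
        track = tk.advect_particle(series, release, 0.0, cfg)
        steps = np.diff(track.lons)
        assert np.all(np.abs(track.lats) < 1e-9)
        assert np.all(np.abs(steps - steps[0]) < 1e-9)

    def test_release_on_land_rejected(self, guyot):
        grid, topo = guyot
        series = so.generate_velocity_series(grid, topo,
                                             so.EddyFieldParams(seed=0, n_eddies=0))
        clon, clat = grid.centre
        with pytest.raises(ValueError, match="release"):
            # 1500 m release over the 600 m summit
            tk.advect_batch(series, [clon], [clat], [1500.0], [0.0],
                            tk.TrackerConfig(pld_days=5))

    def test_reversibility_in_static_field(self):
        series = rotation_series()
        cfg = tk.TrackerConfig(pld_days=4, timestep_s=1800.0)
        release = dz.ReleasePoint(id=0, lon=0.05, lat=0.02, depth=700.0)
        fwd = tk.advect_particle(series, release, 0.0, cfg)
        back_series = make_series(
            u=lambda LON, LAT: OMEGA * LAT * M_PER_DEG,
            v=lambda LON, LAT: -OMEGA * LON * M_PER_DEG,
            lon=(-0.4, 0.4), lat=(-0.4, 0.4), spacing=0.02,
            n_snapshots=2, snapshot_interval=10.0)
        end = dz.ReleasePoint(id=0, lon=fwd.lons[-1], lat=fwd.lats[-1],
                              depth=700.0)
        back = tk.advect_particle(back_series, end, 0.0, cfg)
        assert back.lons[-1] == pytest.approx(0.05, abs=1e-7)
        assert back.lats[-1] == pytest.approx(0.02, abs=1e-7)

    def test_recorded_positions_never_inside_the_seamount(self, eddy_series):
        topo = eddy_series.topo
        pts = dz.ring_release_points(topo, 950.0, 8)
        sched = dz.ReleaseSchedule(times=np.array([0.0, 10.0]))
        tracks = tk.run_release_set(
            eddy_series, dz.ExperimentDesign(points=[
                dz.ReleasePoint(id=p.id, lon=p.lon, lat=p.lat, depth=700.0,
                                contour_depth=950.0) for p in pts],
                schedule=sched),
            tk.TrackerConfig(pld_days=20))
        assert len(tracks) == 16
        for tr in tracks:
            floor = topo.depth_at(tr.lons, tr.lats)
            # never deeper into the seamount than the beach tolerance
            assert np.all(floor >= tr.depth - 51.0)


class TestRunReleaseSet:
    def test_empty_design(self):
        series = make_series()
        design = dz.ExperimentDesign(points=[],
                                     schedule=dz.ReleaseSchedule(times=np.array([])))
        out = tk.run_release_set(series, design, tk.TrackerConfig(pld_days=1))
        assert list(out) == [] and out.errors == []

    def test_deterministic_and_ordered(self):
        series = make_series(u=0.05, v=0.02, n_snapshots=10)
        pts = [dz.ReleasePoint(id=i, lon=-1 + 0.3 * i, lat=0.2, depth=d)
               for i in range(3) for d in (500.0, 800.0)]
        design = dz.ExperimentDesign(
            points=pts, schedule=dz.ReleaseSchedule(times=np.array([0.0, 2.0])))
        a = tk.run_release_set(series, design, tk.TrackerConfig(pld_days=5))
        b = tk.run_release_set(series, design, tk.TrackerConfig(pld_days=5))
        assert len(a) == 12
        keys = [(t.depth, t.meta["point_id"], t.release_day) for t in a]
        assert keys == sorted(keys)
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.lons, tb.lons)

    def test_bad_release_collected_not_fatal(self):
        series = make_series(n_snapshots=10)
        pts = [dz.ReleasePoint(id=0, lon=0.0, lat=0.0, depth=500.0),
               dz.ReleasePoint(id=1, lon=44.0, lat=0.0, depth=500.0)]
        design = dz.ExperimentDesign(
            points=pts, schedule=dz.ReleaseSchedule(times=np.array([0.0])))
        out = tk.run_release_set(series, design, tk.TrackerConfig(pld_days=5))
        assert len(out) == 1
        assert len(out.errors) == 1 and "point 1" in out.errors[0]

    def test_window_exceeding_span_collected(self):
        series = make_series(n_snapshots=10)
        design = dz.ExperimentDesign(
            points=[dz.ReleasePoint(id=0, lon=0.0, lat=0.0, depth=500.0)],
            schedule=dz.ReleaseSchedule(times=np.array([6.0])))
        out = tk.run_release_set(series, design, tk.TrackerConfig(pld_days=5))
        assert len(out) == 0 and "span" in out.errors[0]


class TestTrajectoryIO:
    def test_csv_round_trip(self, tmp_path):
        series = make_series(u=0.1, v=0.05, n_snapshots=8)
        pts = [dz.ReleasePoint(id=i, lon=-1.0 + 0.2 * i, lat=0.0, depth=500.0)
               for i in range(3)]
        design = dz.ExperimentDesign(
            points=pts, schedule=dz.ReleaseSchedule(times=np.array([0.0, 1.0])))
        tracks = tk.run_release_set(series, design, tk.TrackerConfig(pld_days=5))
        path = tmp_path / "tracks.csv"
        tk.write_tracks_csv(tracks, path)
        back = tk.read_tracks_csv(path)
        assert len(back) == len(tracks)
        orig = {(t.meta["point_id"], t.release_day): t for t in tracks}
        for t in back:
            o = orig[(t.meta["point_id"], t.release_day)]
            assert np.allclose(t.lons, o.lons)

    def test_netcdf_layout(self, tmp_path):
        import xarray as xr

        series = make_series(u=0.1, n_snapshots=8)
        design = dz.ExperimentDesign(
            points=[dz.ReleasePoint(id=0, lon=0.0, lat=0.0, depth=500.0)],
            schedule=dz.ReleaseSchedule(times=np.array([0.0])))
        tracks = tk.run_release_set(series, design, tk.TrackerConfig(pld_days=5))
        path = tmp_path / "tracks.nc"
        tk.write_tracks_netcdf(tracks, path)
        with xr.open_dataset(path, engine="scipy") as ds:
            assert ds["lon"].dims == ("track", "obs")
            assert ds.sizes["obs"] == 6
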