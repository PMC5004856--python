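"""Saturation engine: rasterization, FUV, envelopes and optima."""

import numpy as np
import pytest

from larvalsens import saturation_analysis as sat
from larvalsens.tracker import Track


def make_track(lons, lats, track_id=0):
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    return Track(track_id=track_id, lons=lons, lats=lats,
                 days=np.arange(len(lons), dtype=float), depth=1000.0,
                 release_day=0.0)


def raster_of(cells, cell=1.0):
    """DensityRaster from a dict {(i, j): count} on a small grid."""
    nx = max(i for i, _ in cells) + 1
    ny = max(j for _, j in cells) + 1
    counts = np.zeros((ny, nx), dtype=int)
    for (i, j), c in cells.items():
        counts[j, i] = c
    return sat.DensityRaster(lon0=0.0, lat0=0.0, cell_deg=cell, counts=counts)


class TestRasterize:
    def test_straight_equatorial_track_marks_crossed_cells(self):
        """A straight track through 3 cells marks exactly those 3 cells."""
        tr = make_track([0.01, 0.11], [0.02, 0.02])
        raster = sat.rasterize_tracks([tr], cell_deg=0.04)
        assert raster.counts.sum() == 3
        assert np.all((raster.counts == 0) | (raster.counts == 1))

    def test_loop_through_visited_cell_counts_once(self):
        tr = make_track([0.02, 0.10, 0.10, 0.02], [0.02, 0.02, 0.06, 0.02])
        raster = sat.rasterize_tracks([tr], cell_deg=0.04)
        assert raster.counts.max() == 1

    def test_empty_track_set(self):
        raster = sat.rasterize_tracks([], cell_deg=0.04)
        assert raster.counts.sum() == 0

    def test_skipped_cells_still_credited(self):
        """A daily jump across several cells credits every cell on the path."""
        tr = make_track([0.0, 1.0], [0.0, 0.0])
        raster = sat.rasterize_tracks([tr], cell_deg=0.04)
        assert raster.counts.sum() == 26  # 1 degree / 0.04 + endpoint cell

    def test_max_count_bounded_by_track_number(self):
        rng = np.random.default_rng(5)
        tracks = [make_track(np.cumsum(rng.normal(0, 0.05, 20)),
                             np.cumsum(rng.normal(0, 0.05, 20)), track_id=i)
                  for i in range(7)]
        raster = sat.rasterize_tracks(tracks, cell_deg=0.04)
        assert raster.counts.max() <= 7

    def test_dense_sampling_oracle_agrees(self):
        """Exact traversal equals dense point-sampling of the polyline."""
        rng = np.random.default_rng(11)
        for tid in range(5):
            lons = np.cumsum(rng.normal(0, 0.07, 15))
            lats = np.cumsum(rng.normal(0, 0.07, 15))
            tr = make_track(lons, lats, track_id=tid)
            cell = 0.04
            raster = sat.rasterize_tracks([tr], cell_deg=cell)
            exact = {(i, j) for j, i in zip(*np.nonzero(raster.counts))}
            oracle = set()
            for k in range(len(lons) - 1):
                seg = np.hypot(lons[k + 1] - lons[k], lats[k + 1] - lats[k])
                n = max(int(seg / (cell / 400)), 1)
                for f in np.linspace(0.0, 1.0, n + 1):
                    x = lons[k] + f * (lons[k + 1] - lons[k])
                    y = lats[k] + f * (lats[k + 1] - lats[k])
                    oracle.add((int(np.floor((x - raster.lon0) / cell)),
                                int(np.floor((y - raster.lat0) / cell))))
            assert oracle == exact

    def test_extent_auto_expands_and_aligns(self):
        a = sat.rasterize_tracks([make_track([0.0, 0.1], [0.0, 0.0])],
                                 cell_deg=0.04, extent=(0.0, 0.05, 0.0, 0.05))
        assert a.lon0 / 0.04 == pytest.approx(round(a.lon0 / 0.04))
        ny, nx = a.shape
        assert a.lon0 + nx * 0.04 >= 0.1


class TestFuv:
    def test_identical_rasters(self):
        r = raster_of({(0, 0): 1, (1, 0): 2, (0, 1): 3})
        score = sat.fuv(r, r)
        assert score.r == pytest.approx(1.0) and score.fuv == pytest.approx(0.0)

    def test_scale_invariance(self):
        a = raster_of({(0, 0): 1, (1, 0): 2, (0, 1): 3, (1, 1): 5})
        b = sat.DensityRaster(0.0, 0.0, 1.0, a.counts * 2)
        assert sat.fuv(a, b).fuv == pytest.approx(0.0, abs=1e-12)

    def test_symmetry(self):
        a = raster_of({(0, 0): 1, (1, 0): 2, (0, 1): 3, (1, 1): 1})
        b = raster_of({(0, 0): 2, (1, 0): 1, (0, 1): 4, (1, 1): 3})
        assert sat.fuv(a, b).fuv == pytest.approx(sat.fuv(b, a).fuv, abs=1e-12)

    def test_hand_computed_four_cell_pearson(self):
        """a = (1,2,3,4), b = (2,1,4,3): cov 0.75, var 1.25 -> r = 0.6."""
        a = raster_of({(0, 0): 1, (1, 0): 2, (0, 1): 3, (1, 1): 4})
        b = raster_of({(0, 0): 2, (1, 0): 1, (0, 1): 4, (1, 1): 3})
        score = sat.fuv(a, b)
        assert score.r == pytest.approx(0.6, abs=1e-12)
        assert score.fuv == pytest.approx(1 - 0.6 ** 2, abs=1e-12)

    def test_zero_variance_rejected(self):
        a = raster_of({(0, 0): 1, (1, 0): 1, (0, 1): 1, (1, 1): 1})
        b = raster_of({(0, 0): 1, (1, 0): 2, (0, 1): 3, (1, 1): 4})
        with pytest.raises(sat.UndefinedCorrelationError):
            sat.fuv(a, b)

    def test_joint_zero_cells_excluded(self):
        """Padding both rasters with empty cells must not change FUV."""
        a = raster_of({(0, 0): 1, (1, 0): 2, (0, 1): 3, (1, 1): 4})
        b = raster_of({(0, 0): 2, (1, 0): 1, (0, 1): 4, (1, 1): 3})
        base = sat.fuv(a, b).fuv
        big_a = sat.DensityRaster(0.0, 0.0, 1.0, np.pad(a.counts, (0, 5)))
        big_b = sat.DensityRaster(0.0, 0.0, 1.0, np.pad(b.counts, (0, 5)))
        assert sat.fuv(big_a, big_b).fuv == pytest.approx(base, abs=1e-12)

    def test_misaligned_origins_are_padded_onto_union_grid(self):
        a = raster_of({(0, 0): 1, (1, 0): 2})
        b = sat.DensityRaster(1.0, 0.0, 1.0, np.array([[2, 1]]))
        score = sat.fuv(a, b)  # overlap only at cell (1, 0)
        assert 0.0 <= score.fuv <= 1.0


class TestEnvelopeAndOptimum:
    def test_single_replicate_envelope_passes_through_values(self):
        knots, interp = sat.fuv_envelope([4, 52, 183], [[0.6], [0.2], [0.04]])
        assert np.allclose(knots, [0.6, 0.2, 0.04])
        assert interp(52) == pytest.approx(0.2)

    def test_identical_replicates(self):
        knots, _ = sat.fuv_envelope([1, 2], [[0.3] * 20, [0.1] * 20])
        assert np.allclose(knots, [0.3, 0.1])

    def test_quantile_matches_order_statistic_oracle(self):
        """Linear-interpolation quantile: x(94) + 0.05 * (x(95) - x(94))."""
        rng = np.random.default_rng(2024)
        draws = rng.uniform(0, 1, 100)
        x = np.sort(draws)
        expected = x[94] + 0.05 * (x[95] - x[94])  # position 0.95 * (n - 1)
        knots, _ = sat.fuv_envelope([1, 2], [draws, draws])
        assert knots[0] == pytest.approx(expected, abs=1e-12)
        # and lands near the distribution's true 95th percentile
        assert 0.85 < knots[0] < 1.0

    def test_standard_example_crossing_between_52_and_183(self):
        incs = [4.0, 52.0, 183.0, 365.0]
        env = [0.6, 0.2, 0.04, 0.0]
        opt, flag = sat.optimal_from_envelope(incs, env, 0.05)
        assert not flag and 52.0 < opt < 183.0
        # dense-grid oracle within 0.5 of an increment unit
        from scipy.interpolate import PchipInterpolator

        xs = np.arange(4.0, 365.0, 0.01)
        ys = PchipInterpolator(incs, env)(xs)
        oracle = xs[np.flatnonzero(ys <= 0.05)[0]]
        assert opt == pytest.approx(oracle, abs=0.5)

    def test_all_below_threshold_returns_smallest(self):
        opt, flag = sat.optimal_from_envelope([4, 52, 183], [0.04, 0.02, 0.0], 0.05)
        assert not flag and opt == 4.0

    def test_never_reaching_threshold_flags(self):
        opt, flag = sat.optimal_from_envelope([4, 52, 183], [0.9, 0.8, 0.7], 0.05)
        assert flag


class TestFuvToCorrelation:
    @pytest.mark.parametrize("fuv_val,r", [(0.0, 1.0), (1.0, 0.0),
                                           (0.05, 0.9747)])
    def test_closed_form(self, fuv_val, r):
        assert sat.fuv_to_correlation(fuv_val) == pytest.approx(r, abs=1e-4)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            sat.fuv_to_correlation(1.2)


class TestRasterExport:
    def test_ascii_grid_round_trippable_by_eye(self, tmp_path):
        r = raster_of({(0, 0): 1, (1, 1): 3})
        path = tmp_path / "grid.asc"
        sat.write_ascii_grid(r, path)
        lines = path.read_text().splitlines()
        assert lines[0] == "ncols 2" and lines[1] == "nrows 2"
        assert lines[-1].split() == ["1", "0"]

    def test_netcdf_export(self, tmp_path):
        import xarray as xr

        r = raster_of({(0, 0): 1, (1, 1): 3}, cell=0.04)
        path = tmp_path / "grid.nc"
        sat.write_raster_netcdf(r, path)
        with xr.open_dataset(path, engine="scipy") as ds:
            assert ds["track_count"].shape == (2, 2)
            assert ds["lon"].values[0] == pytest.approx(0.02)
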