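"""Shared fixtures: tiny analytic field series, a guyot, and suite runs."""

from __future__ import annotations

import numpy as np
import pytest

from larvalsens import synthetic_ocean as so


def make_series(u=0.0, v=0.0, lon=(-2.0, 2.0), lat=(-2.0, 2.0),
                z_levels=(500.0, 1000.0), n_snapshots=3, spacing=0.08,
                basin_depth=3000.0, snapshot_interval=1.0, topo=None):
    """A velocity series over a flat basin (or explicit topography).

    ``u``/``v`` may be constants or callables ``f(LON, LAT)`` evaluated on
    the grid nodes (one static pattern replicated over time and depth).
    """
    grid = so.GridSpec(lon_min=lon[0], lon_max=lon[1], lat_min=lat[0],
                       lat_max=lat[1], z_levels=tuple(z_levels),
                       spacing=spacing, n_snapshots=n_snapshots,
                       snapshot_interval=snapshot_interval)
    ny, nx = len(grid.lats), len(grid.lons)
    if topo is None:
        topo = so.Topography(grid=grid, depth=np.full((ny, nx), basin_depth))
    LON, LAT = np.meshgrid(grid.lons, grid.lats)
    u2 = u(LON, LAT) if callable(u) else np.full((ny, nx), float(u))
    v2 = v(LON, LAT) if callable(v) else np.full((ny, nx), float(v))
    shape = grid.shape
    uarr = np.broadcast_to(u2, shape).copy()
    varr = np.broadcast_to(v2, shape).copy()
    valid = so.validity_mask(grid, topo)
    uarr[:, ~valid] = 0.0
    varr[:, ~valid] = 0.0
    return so.VelocityFieldSeries(grid=grid, u=uarr, v=varr, valid=valid,
                                  topo=topo)


@pytest.fixture(scope="session")
def guyot():
    """A small grid with the default guyot (600-2000 m over a 2500 m basin)."""
    grid = so.GridSpec(lon_min=-13.0, lon_max=-9.0, lat_min=55.5, lat_max=59.5,
                       z_levels=tuple(so.levitus_levels(150, 2000)),
                       n_snapshots=40)
    topo = so.make_guyot_topography(grid)
    return grid, topo


@pytest.fixture(scope="session")
def eddy_series(guyot):
    """Default synthetic eddy fields on the guyot grid (seed 7)."""
    grid, topo = guyot
    return so.generate_velocity_series(grid, topo,
                                       so.EddyFieldParams(seed=7))


@pytest.fixture(scope="session")
def recovery_runs():
    """Twenty seeded demo sensitivity-suite runs (HS + RF tests).

    Shared by the stochastic parameter-recovery checks: the horizontal-
    separation depth ordering, DST monotonicity in offset, and FUV
    monotonicity in release frequency are all read off these runs.
    """
    from larvalsens.workbench import SuiteConfig, run_sensitivity_suite

    results = []
    for seed in range(20):
        cfg = SuiteConfig.demo(seed=seed, tests=("HS", "RF"))
        results.append(run_sensitivity_suite(cfg))
    return results
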