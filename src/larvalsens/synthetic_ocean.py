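"""Synthetic depth-stratified ocean: gridded velocity series over a guyot.

This module generates the environment the particle tracker consumes without
any external data: a regular lon/lat grid with z-levels following the Levitus
depth convention, an idealized flat-topped seamount (guyot), and a time series
of horizontal velocity fields built from Gaussian streamfunction eddies riding
on a weak background flow.

Design notes
------------
* Eddies are *streamfunction* vortices: per level, ``u = -dpsi/dy`` and
  ``v = +dpsi/dx``.  The derivatives are taken as discrete central
  differences of the streamfunction sampled on the grid (with the longitude
  metric frozen at the domain-centre latitude), so the discrete
  central-difference horizontal divergence vanishes to machine precision —
  the flow injects no artificial particle sources or sinks in a purely
  horizontal (2-D) advection setting.
* Eddies are columnar: one set of centres and time-evolving strengths shared
  by all levels, scaled per level by an amplitude profile.  The default
  profile peaks at 1000 m and is weakest at 1500 m, emulating a mid-depth
  maximum of mesoscale variability over the seamount.
* Temporal evolution combines an Ornstein–Uhlenbeck modulation of each eddy's
  strength (default e-folding 2 days, the rough decorrelation scale of
  daily-averaged mid-latitude currents) with a random walk of the centres.
* Everything is driven by one :class:`numpy.random.Generator` seeded from
  ``EddyFieldParams.seed``; identical inputs give bit-identical fields.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np

from ._geo import M_PER_DEG, haversine_km

__all__ = [
    "GridSpec",
    "Topography",
    "EddyFieldParams",
    "VelocityFieldSeries",
    "levitus_levels",
    "make_guyot_topography",
    "default_amplitude_profile",
    "generate_velocity_series",
    "write_fields",
    "read_fields",
    "FieldParseError",
]


# ---------------------------------------------------------------------------
# grid / topography containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GridSpec:
    """Regular lon/lat grid with z-levels and a daily-snapshot time axis.

    Depths are metres, positive down.  ``spacing`` defaults to 0.08 degrees,
    the horizontal resolution of the global ocean-model outputs this generator
    emulates.
    """

    lon_min: float
    lon_max: float
    lat_min: float
    lat_max: float
    z_levels: tuple[float, ...]
    spacing: float = 0.08
    time_origin: str = "2012-01-04"
    n_snapshots: int = 1
    snapshot_interval: float = 1.0  # days

    def __post_init__(self):
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.lon_max <= self.lon_min:
            raise ValueError("lon_max must exceed lon_min")
        if not (-90.0 < self.lat_min < self.lat_max < 90.0):
            raise ValueError("latitudes must satisfy -90 < lat_min < lat_max < 90")
        z = np.asarray(self.z_levels, dtype=float)
        if z.ndim != 1 or len(z) == 0 or np.any(np.diff(z) <= 0):
            raise ValueError("z_levels must be non-empty and strictly increasing")
        object.__setattr__(self, "z_levels", tuple(float(v) for v in z))
        if self.n_snapshots < 1:
            raise ValueError("n_snapshots must be >= 1")
        if self.snapshot_interval <= 0:
            raise ValueError("snapshot_interval must be positive")

    @property
    def lons(self) -> np.ndarray:
        n = int(round((self.lon_max - self.lon_min) / self.spacing)) + 1
        return self.lon_min + self.spacing * np.arange(n)

    @property
    def lats(self) -> np.ndarray:
        n = int(round((self.lat_max - self.lat_min) / self.spacing)) + 1
        return self.lat_min + self.spacing * np.arange(n)

    @property
    def times(self) -> np.ndarray:
        """Snapshot times, days since ``time_origin``."""
        return self.snapshot_interval * np.arange(self.n_snapshots)

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return (self.n_snapshots, len(self.z_levels), len(self.lats), len(self.lons))

    @property
    def centre(self) -> tuple[float, float]:
        return (0.5 * (self.lon_min + self.lon_max), 0.5 * (self.lat_min + self.lat_max))


@dataclass
class Topography:
    """Seafloor depth (m, positive down) on the grid's lon/lat nodes.

    ``depth_fn``, when present, is the analytic surface the gridded depths
    were sampled from; contour geometry uses it for sub-grid accuracy.
    """

    grid: GridSpec
    depth: np.ndarray  # (nlat, nlon)
    depth_fn: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None

    def __post_init__(self):
        self.depth = np.asarray(self.depth, dtype=float)
        ny, nx = len(self.grid.lats), len(self.grid.lons)
        if self.depth.shape != (ny, nx):
            raise ValueError(f"depth shape {self.depth.shape} != grid shape {(ny, nx)}")
        if not np.all(np.isfinite(self.depth)):
            raise ValueError("topography depths must be finite")

    @property
    def land(self) -> np.ndarray:
        return self.depth <= 0.0

    def depth_at(self, lon, lat):
        """Seafloor depth at arbitrary points (analytic if available, else bilinear)."""
        if self.depth_fn is not None:
            return self.depth_fn(np.asarray(lon, float), np.asarray(lat, float))
        g = self.grid
        fi = np.clip((np.asarray(lon, float) - g.lons[0]) / g.spacing, 0, len(g.lons) - 1)
        fj = np.clip((np.asarray(lat, float) - g.lats[0]) / g.spacing, 0, len(g.lats) - 1)
        i0 = np.clip(np.floor(fi).astype(int), 0, len(g.lons) - 2)
        j0 = np.clip(np.floor(fj).astype(int), 0, len(g.lats) - 2)
        sx, sy = fi - i0, fj - j0
        d = self.depth
        return ((1 - sy) * ((1 - sx) * d[j0, i0] + sx * d[j0, i0 + 1])
                + sy * ((1 - sx) * d[j0 + 1, i0] + sx * d[j0 + 1, i0 + 1]))


# ---------------------------------------------------------------------------
# Levitus z-level convention
# ---------------------------------------------------------------------------

#: (band start, band end, step) in metres — spacing coarsens with depth
_LEVITUS_BANDS = ((150.0, 300.0, 50.0), (300.0, 1500.0, 100.0),
                  (1500.0, 2000.0, 250.0), (2000.0, 5500.0, 500.0))


def levitus_levels(min_depth: float, max_depth: float) -> list[float]:
    """Standard z-levels between two depths, following the Levitus convention.

    Spacing is 50 m within 150-300 m, 100 m within 300-1500 m, 250 m within
    1500-2000 m and 500 m within 2000-5500 m; band-boundary depths appear
    once.  Returns strictly increasing levels clipped to
    ``[min_depth, max_depth]``.
    """
    if not (0 < min_depth < max_depth):
        raise ValueError("require 0 < min_depth < max_depth")
    if min_depth < _LEVITUS_BANDS[0][0] or max_depth > _LEVITUS_BANDS[-1][1]:
        raise ValueError("supported depth range is 150-5500 m")
    levels: list[float] = []
    for lo, hi, step in _LEVITUS_BANDS:
        pts = np.arange(lo, hi + 0.5 * step, step)
        for p in pts:
            if min_depth <= p <= max_depth and (not levels or p > levels[-1]):
                levels.append(float(p))
    return levels


# ---------------------------------------------------------------------------
# guyot topography
# ---------------------------------------------------------------------------

def make_guyot_topography(grid: GridSpec,
                          centre: tuple[float, float] | None = None,
                          summit_depth: float = 600.0,
                          base_depth: float = 2000.0,
                          summit_radius_km: float = 12.0,
                          base_radius_km: float = 35.0,
                          basin_depth: float = 2500.0) -> Topography:
    """Idealized flat-topped seamount: radially symmetric, linear flanks.

    Depth equals ``summit_depth`` inside ``summit_radius_km`` of ``centre``
    (great-circle distance), rises linearly to ``base_depth`` at
    ``base_radius_km``, and equals ``basin_depth`` beyond.  Defaults emulate a
    table mount spanning 600-2000 m in a deep basin.
    """
    if centre is None:
        centre = grid.centre
    clon, clat = centre
    if not (grid.lon_min <= clon <= grid.lon_max and grid.lat_min <= clat <= grid.lat_max):
        raise ValueError("guyot centre lies outside the grid")
    if not summit_depth < base_depth:
        raise ValueError("summit_depth must be shallower than base_depth")
    if not summit_radius_km < base_radius_km:
        raise ValueError("summit_radius_km must be less than base_radius_km")
    if base_depth > basin_depth:
        raise ValueError("base_depth cannot exceed basin_depth")

    def depth_fn(lon, lat):
        r = haversine_km(lon, lat, clon, clat)
        frac = np.clip((r - summit_radius_km) / (base_radius_km - summit_radius_km), 0.0, 1.0)
        d = summit_depth + frac * (base_depth - summit_depth)
        return np.where(r >= base_radius_km, basin_depth, d)

    glon, glat = np.meshgrid(grid.lons, grid.lats)
    return Topography(grid=grid, depth=np.asarray(depth_fn(glon, glat), float),
                      depth_fn=depth_fn)


# ---------------------------------------------------------------------------
# eddy field parameters and generation
# ---------------------------------------------------------------------------

def default_amplitude_profile(z):
    """Relative eddy-streamfunction amplitude vs depth (dimensionless).

    Piecewise linear: a surface-intensified upper layer with strong vertical
    gradient around 200 m (winter-mixed / upper-water-mass structure), a
    mid-depth mesoscale maximum at 1000 m — the greatest horizontal
    variability of the profile — and quiescent deep water below 1500 m, the
    qualitative depth ordering of current variability this generator targets.
    """
    zk = np.array([0.0, 200.0, 700.0, 1000.0, 1500.0, 5500.0])
    ak = np.array([0.05, 0.50, 0.32, 1.00, 0.15, 0.10])
    return np.interp(np.asarray(z, dtype=float), zk, ak)


def default_length_scale_profile(z):
    """Eddy length scale (km) vs depth.

    Velocity patches are smallest at mid-depth (1000 m band) — many small
    features rather than a few broad ones — and broadest in the quiescent
    deep water, the second ingredient (besides amplitude) of the mid-depth
    variability maximum.  Piecewise constant so levels sharing a scale can
    share one streamfunction evaluation.
    """
    z = np.asarray(z, dtype=float)
    return np.where(z < 850.0, 26.0, np.where(z < 1250.0, 16.0, 36.0))


@dataclass
class EddyFieldParams:
    """Controls for the synthetic mesoscale eddy field.

    ``amplitude_m2s`` is the streamfunction peak (m^2/s) of a unit-strength
    eddy at the profile maximum; peak swirl speed is roughly
    ``amplitude / (L * sqrt(e))``.  The default amplitude and 30 km length
    scale give mid-depth speeds of order 0.2 m/s over a weak background, in
    line with drifter speeds around mid-latitude seamounts.
    """

    amplitude_m2s: float = 1.2e4
    length_scale_km: float = 24.0
    #: optional per-depth eddy length scale (km); overrides
    #: ``length_scale_km`` when set (e.g. to make mid-depth velocity patches
    #: smaller, at the cost of patchier seed-to-seed eddy coverage)
    length_scale_profile: Callable[[np.ndarray], np.ndarray] | None = None
    n_eddies: int = 24
    drift_speed_km_day: float = 3.0
    amp_timescale_days: float = 2.0
    amp_sigma: float = 0.4
    background_ms: tuple[float, float] = (0.015, 0.005)
    amplitude_profile: Callable[[np.ndarray], np.ndarray] = default_amplitude_profile
    #: width, in grid cells, of the horizontal taper that brings the
    #: streamfunction to zero at each level's masked (seafloor) region, making
    #: topography a streamline the flow deflects around; must span several
    #: cells to be resolved by the discrete curl (0 disables the taper and
    #: the flow then runs straight into the mask)
    topo_taper_cells: float = 3.0
    seed: int = 0

    def __post_init__(self):
        if self.length_scale_km <= 0:
            raise ValueError("length_scale_km must be positive")
        if self.n_eddies < 0:
            raise ValueError("n_eddies must be >= 0")
        if self.amp_timescale_days <= 0:
            raise ValueError("amp_timescale_days must be positive")


@dataclass
class VelocityFieldSeries:
    """4-D gridded horizontal velocity: u, v with shape (time, z, lat, lon).

    ``valid`` is a per-level cell mask; u and v are exactly zero on invalid
    (seafloor-shallower-than-level) cells so interpolation stays total.
    """

    grid: GridSpec
    u: np.ndarray
    v: np.ndarray
    valid: np.ndarray  # (nz, nlat, nlon) bool
    topo: Topography | None = None
    seed: int | None = None

    def __post_init__(self):
        if self.u.shape != self.grid.shape or self.v.shape != self.grid.shape:
            raise ValueError("u/v shape inconsistent with grid")
        if self.valid.shape != self.grid.shape[1:]:
            raise ValueError("valid mask shape inconsistent with grid")
        bad = ~np.isfinite(self.u[:, self.valid]) | ~np.isfinite(self.v[:, self.valid])
        if np.any(bad):
            raise ValueError("velocities must be finite on valid cells")


def validity_mask(grid: GridSpec, topo: Topography) -> np.ndarray:
    """Per-level cell validity: seafloor at least as deep as the level, not land."""
    z = np.asarray(grid.z_levels)[:, None, None]
    return (topo.depth[None, :, :] >= z) & (topo.depth[None, :, :] > 0.0)


def generate_velocity_series(grid: GridSpec, topo: Topography,
                             params: EddyFieldParams,
                             dtype=np.float64) -> VelocityFieldSeries:
    """Generate the full (time, z, lat, lon) velocity series.

    Deterministic given (grid, topo, params): a single seeded generator drives
    eddy placement, strength evolution and centre drift.
    """
    rng = np.random.default_rng(params.seed)
    nt, nz, ny, nx = grid.shape
    lons, lats = grid.lons, grid.lats
    clat = 0.5 * (grid.lat_min + grid.lat_max)
    # tangent-plane metric (m), lon metric frozen at centre latitude so the
    # discrete curl of psi is exactly divergence-free
    dx = grid.spacing * M_PER_DEG * np.cos(np.radians(clat))
    dy = grid.spacing * M_PER_DEG
    X = (lons[None, :] - lons[0]) * M_PER_DEG * np.cos(np.radians(clat))
    Y = (lats[:, None] - lats[0]) * M_PER_DEG

    amp = params.amplitude_m2s * np.asarray(
        params.amplitude_profile(np.asarray(grid.z_levels)), dtype=float)
    bg = np.asarray(params.background_ms, dtype=float)
    if bg.ndim == 1:
        bg = np.tile(bg, (nz, 1))
    if bg.shape != (nz, 2):
        raise ValueError("background_ms must be (u0, v0) or one pair per z-level")

    ne = params.n_eddies
    # initial eddy state
    ex = rng.uniform(X.min(), X.max(), size=ne)
    ey = rng.uniform(Y.min(), Y.max(), size=ne)
    sign = np.where(np.arange(ne) % 2 == 0, 1.0, -1.0)
    strength = 1.0 + params.amp_sigma * rng.standard_normal(ne)

    if params.length_scale_profile is not None:
        L_per_level = np.asarray(params.length_scale_profile(
            np.asarray(grid.z_levels)), dtype=float) * 1000.0
    else:
        L_per_level = np.full(nz, params.length_scale_km * 1000.0)
    distinct_L = sorted(set(L_per_level.tolist()))
    dt = grid.snapshot_interval
    decay = np.exp(-dt / params.amp_timescale_days)
    kick = params.amp_sigma * np.sqrt(1.0 - decay ** 2)
    step_sd = params.drift_speed_km_day * 1000.0 * dt / np.sqrt(2.0)

    valid = validity_mask(grid, topo)
    u = np.zeros((nt, nz, ny, nx), dtype=dtype)
    v = np.zeros_like(u)

    # per-level taper: streamfunction ramps from 0 at the level's masked
    # region to full strength ``topo_taper_cells`` grid cells away, so the
    # seamount boundary is a streamline and flow deflects around it; the
    # ramp spans several cells so the discrete curl resolves it
    if params.topo_taper_cells > 0:
        from scipy.ndimage import distance_transform_edt

        sigma = np.empty((nz, ny, nx))
        for k in range(nz):
            if np.all(valid[k]):
                sigma[k] = 1.0
                continue
            dist = distance_transform_edt(valid[k])
            s = np.clip(dist / params.topo_taper_cells, 0.0, 1.0)
            sigma[k] = s * s * (3.0 - 2.0 * s)  # smoothstep
    else:
        sigma = np.ones((nz, ny, nx))
    # background flow as a linear streamfunction per level
    psi_bg = (-bg[:, 0, None, None] * Y[None, :, :]
              + bg[:, 1, None, None] * X[None, :, :])

    zero_psi = np.zeros((ny, nx))
    for it in range(nt):
        if ne > 0:
            r2 = ((X[None, :, :] - ex[:, None, None]) ** 2
                  + (Y[None, :, :] - ey[:, None, None]) ** 2)
            psi_by_L = {L: np.einsum("e,eyx->yx", sign * strength,
                                     np.exp(-r2 / (2.0 * L * L)))
                        for L in distinct_L}
        else:
            psi_by_L = {L: zero_psi for L in distinct_L}
        for k in range(nz):
            psi_k = amp[k] * psi_by_L[L_per_level[k]] + psi_bg[k]
            band = (sigma[k] > 0.0) & (sigma[k] < 1.0)
            if np.any(band):
                # reference the streamfunction to its wall-band mean so the
                # taper carries only the along-wall variation (a deflection
                # jet of realistic size, not the full gyre transport)
                psi_k = psi_k - psi_k[band].mean()
            u[it, k] = -np.gradient(psi_k * sigma[k], dy, axis=0)
            v[it, k] = np.gradient(psi_k * sigma[k], dx, axis=1)
        u[it][~valid] = 0.0
        v[it][~valid] = 0.0
        if ne > 0 and it + 1 < nt:
            strength = 1.0 + (strength - 1.0) * decay + kick * rng.standard_normal(ne)
            ex = _reflect(ex + step_sd * rng.standard_normal(ne), X.min(), X.max())
            ey = _reflect(ey + step_sd * rng.standard_normal(ne), Y.min(), Y.max())

    return VelocityFieldSeries(grid=grid, u=u, v=v, valid=valid, topo=topo,
                               seed=params.seed)


def _reflect(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Reflect positions into [lo, hi]."""
    span = hi - lo
    y = np.mod(x - lo, 2.0 * span)
    y = np.where(y > span, 2.0 * span - y, y)
    return lo + y


# ---------------------------------------------------------------------------
# field I/O: netCDF and a plain-text fixture format
# ---------------------------------------------------------------------------

class FieldParseError(ValueError):
    """A field file is malformed; the message names the offending attribute."""


def write_fields(series: VelocityFieldSeries, path) -> None:
    """Write a velocity series to ``path`` (.nc netCDF, or .txt text dump)."""
    path = Path(path)
    if path.suffix == ".txt":
        _write_text(series, path)
    else:
        _write_netcdf(series, path)


def read_fields(path) -> VelocityFieldSeries:
    """Read a velocity series written by :func:`write_fields`."""
    path = Path(path)
    if path.suffix == ".txt":
        return _read_text(path)
    return _read_netcdf(path)


def _to_dataset(series: VelocityFieldSeries):
    import xarray as xr

    g = series.grid
    ds = xr.Dataset(
        {
            "u": (("time", "depth", "lat", "lon"), series.u,
                  {"units": "m s-1", "long_name": "eastward velocity"}),
            "v": (("time", "depth", "lat", "lon"), series.v,
                  {"units": "m s-1", "long_name": "northward velocity"}),
            "valid": (("depth", "lat", "lon"), series.valid.astype(np.int8),
                      {"long_name": "cell validity (0 = below seafloor/land)"}),
        },
        coords={
            "time": ("time", g.times, {"units": f"days since {g.time_origin}"}),
            "depth": ("depth", np.asarray(g.z_levels), {"units": "m", "positive": "down"}),
            "lat": ("lat", g.lats, {"units": "degrees_north"}),
            "lon": ("lon", g.lons, {"units": "degrees_east"}),
        },
        attrs={"Conventions": "CF-1.8", "source": "larvalsens synthetic ocean",
               "spacing": g.spacing,
               "seed": -1 if series.seed is None else int(series.seed)},
    )
    if series.topo is not None:
        ds["seafloor_depth"] = (("lat", "lon"), series.topo.depth, {"units": "m"})
    return ds


def _write_netcdf(series: VelocityFieldSeries, path: Path) -> None:
    _to_dataset(series).to_netcdf(path, engine="scipy")


def _read_netcdf(path: Path) -> VelocityFieldSeries:
    import xarray as xr

    with xr.open_dataset(path, engine="scipy", decode_times=False) as ds:
        ds = ds.load()
    for name in ("lon", "lat", "depth", "time"):
        if name not in ds.coords:
            raise FieldParseError(f"missing coordinate variable '{name}'")
    for name in ("u", "v"):
        if name not in ds:
            raise FieldParseError(f"missing variable '{name}'")
    lons = ds["lon"].values
    lats = ds["lat"].values
    if len(lons) < 2 or len(lats) < 2:
        raise FieldParseError("degenerate 'lon'/'lat' axis")
    spacing = float(ds.attrs.get("spacing", lons[1] - lons[0]))
    tunits = str(ds["time"].attrs.get("units", ""))
    m = re.match(r"days since (.+)", tunits)
    if not m:
        raise FieldParseError("time coordinate lacks 'days since <origin>' units")
    times = np.asarray(ds["time"].values, dtype=float)
    interval = float(times[1] - times[0]) if len(times) > 1 else 1.0
    grid = GridSpec(lon_min=float(lons[0]), lon_max=float(lons[-1]),
                    lat_min=float(lats[0]), lat_max=float(lats[-1]),
                    z_levels=tuple(float(z) for z in ds["depth"].values),
                    spacing=spacing, time_origin=m.group(1).strip(),
                    n_snapshots=len(times), snapshot_interval=interval)
    topo = None
    if "seafloor_depth" in ds:
        topo = Topography(grid=grid, depth=ds["seafloor_depth"].values)
    if "valid" in ds:
        valid = ds["valid"].values.astype(bool)
    else:
        valid = np.ones(grid.shape[1:], dtype=bool)
    seed = int(ds.attrs.get("seed", -1))
    return VelocityFieldSeries(grid=grid, u=np.asarray(ds["u"].values),
                               v=np.asarray(ds["v"].values), valid=valid,
                               topo=topo, seed=None if seed < 0 else seed)


_TEXT_MAGIC = "LARVALSENS-FIELDS 1"


def _write_text(series: VelocityFieldSeries, path: Path) -> None:
    g = series.grid
    nt, nz, ny, nx = g.shape
    lines = [_TEXT_MAGIC,
             f"origin {g.time_origin}",
             f"lon {g.lons[0]:.10g} {g.spacing:.10g} {nx}",
             f"lat {g.lats[0]:.10g} {g.spacing:.10g} {ny}",
             "z " + " ".join(f"{z:.10g}" for z in g.z_levels),
             "time " + " ".join(f"{t:.10g}" for t in g.times),
             f"seed {-1 if series.seed is None else series.seed}"]
    for k in range(nz):
        lines.append(f"mask z={k}")
        for j in range(ny):
            lines.append(" ".join(str(int(b)) for b in series.valid[k, j]))
    for name, arr in (("u", series.u), ("v", series.v)):
        for it in range(nt):
            for k in range(nz):
                lines.append(f"var {name} t={it} z={k}")
                for j in range(ny):
                    lines.append(" ".join(f"{x!r}" for x in arr[it, k, j].tolist()))
    path.write_text("\n".join(lines) + "\n")


def _read_text(path: Path) -> VelocityFieldSeries:
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines or lines[0].strip() != _TEXT_MAGIC:
        raise FieldParseError("missing magic header line")
    head: dict[str, str] = {}
    i = 1
    while i < len(lines) and not lines[i].startswith(("mask", "var")):
        key, _, rest = lines[i].partition(" ")
        head[key] = rest.strip()
        i += 1
    for req in ("origin", "lon", "lat", "z", "time"):
        if req not in head:
            raise FieldParseError(f"missing header attribute '{req}'")
    try:
        lon0, dlon, nx = head["lon"].split()
        lat0, dlat, ny = head["lat"].split()
        z = [float(s) for s in head["z"].split()]
        times = [float(s) for s in head["time"].split()]
        nx, ny = int(nx), int(ny)
    except ValueError as exc:
        raise FieldParseError(f"malformed header: {exc}") from None
    if abs(float(dlon) - float(dlat)) > 1e-12:
        raise FieldParseError("attribute 'spacing' differs between lon and lat")
    spacing = float(dlon)
    grid = GridSpec(lon_min=float(lon0), lon_max=float(lon0) + spacing * (nx - 1),
                    lat_min=float(lat0), lat_max=float(lat0) + spacing * (ny - 1),
                    z_levels=tuple(z), spacing=spacing, time_origin=head["origin"],
                    n_snapshots=len(times),
                    snapshot_interval=(times[1] - times[0]) if len(times) > 1 else 1.0)
    nt, nz = len(times), len(z)
    u = np.zeros(grid.shape)
    v = np.zeros(grid.shape)
    valid = np.ones(grid.shape[1:], dtype=bool)
    while i < len(lines):
        header = lines[i].split()
        i += 1
        try:
            if header[0] == "mask":
                k = int(header[1].split("=")[1])
                block = [[bool(int(s)) for s in lines[i + j].split()] for j in range(ny)]
                valid[k] = np.asarray(block)
            elif header[0] == "var":
                name = header[1]
                it = int(header[2].split("=")[1])
                k = int(header[3].split("=")[1])
                block = [[float(s) for s in lines[i + j].split()] for j in range(ny)]
                (u if name == "u" else v)[it, k] = np.asarray(block)
            else:
                raise FieldParseError(f"unrecognized block '{header[0]}'")
        except (IndexError, ValueError) as exc:
            raise FieldParseError(f"malformed block '{' '.join(header)}': {exc}") from None
        i += ny
    seed = int(head.get("seed", "-1"))
    return VelocityFieldSeries(grid=grid, u=u, v=v, valid=valid,
                               seed=None if seed < 0 else seed)
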