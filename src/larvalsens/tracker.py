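"""Offline passive 2-D Lagrangian tracker at fixed depth horizons.

Particles are advected horizontally with classical fourth-order Runge-Kutta
through a :class:`~larvalsens.synthetic_ocean.VelocityFieldSeries`.  Velocity
sampling is bicubic in the horizontal (falling back to bilinear next to
masked cells and domain edges), linear in depth between bracketing z-levels,
and linear in time between snapshots.  There is no vertical motion: depth is
a fixed horizon per particle, matching an ocean-model-output setting where
vertical velocity is unavailable and deep background values are negligible
over a larval drift.

Integration happens in degree space, d(lon)/dt = u / (m_deg * cos(lat)) and
d(lat)/dt = v / m_deg with m_deg = pi * R / 180 metres per degree, each RK
stage re-sampling the field at its own position and time.  A particle whose
stage position leaves the grid or time span is frozen at its last valid
position and flagged ``escaped``; one entering a cell whose seafloor is
shallower than its depth is frozen and flagged ``beached``.  Frozen particles
keep emitting their last position so replicate designs stay balanced.

The module is vectorized over particles: :func:`advect_batch` advances every
particle of an experiment simultaneously (each with its own release time),
which is what makes multi-thousand-track sensitivity suites tractable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .synthetic_ocean import VelocityFieldSeries

__all__ = [
    "TrackerConfig",
    "ParticleState",
    "Track",
    "TrackSet",
    "DomainError",
    "sample_velocity",
    "rk4_step",
    "advect_particle",
    "advect_batch",
    "run_release_set",
    "tracks_to_dataframe",
    "write_tracks_csv",
    "read_tracks_csv",
]

ACTIVE, BEACHED, ESCAPED = 0, 1, 2
_STATUS_NAMES = {ACTIVE: "active", BEACHED: "beached", ESCAPED: "escaped"}


class DomainError(ValueError):
    """A velocity query fell outside the grid bounds or time span."""


@dataclass(frozen=True)
class TrackerConfig:
    timestep_s: float = 3600.0
    pld_days: float = 100.0
    output_interval_days: float = 1.0
    interp: str = "cubic"  # "cubic" | "linear"
    earth_radius_km: float = 6371.0

    def __post_init__(self):
        if self.timestep_s <= 0:
            raise ValueError("timestep_s must be positive")
        if self.pld_days < 1:
            raise ValueError("pld_days must be >= 1")
        out_s = self.output_interval_days * 86400.0
        if abs(out_s / self.timestep_s - round(out_s / self.timestep_s)) > 1e-9:
            raise ValueError("timestep must divide the output interval")
        if self.interp not in ("cubic", "linear"):
            raise ValueError("interp must be 'cubic' or 'linear'")

    @property
    def steps_per_record(self) -> int:
        return int(round(self.output_interval_days * 86400.0 / self.timestep_s))

    @property
    def n_records(self) -> int:
        """Daily records including the release position."""
        return int(round(self.pld_days / self.output_interval_days)) + 1

    @property
    def m_per_deg(self) -> float:
        return np.pi * self.earth_radius_km * 1000.0 / 180.0


@dataclass
class ParticleState:
    lon: float
    lat: float
    depth: float
    time_s: float
    status: str = "active"


@dataclass
class Track:
    """One particle's daily positions plus release metadata."""

    track_id: int
    lons: np.ndarray
    lats: np.ndarray
    days: np.ndarray
    depth: float
    release_day: float
    status: str = "active"
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.days)


class TrackSet(list):
    """A list of Tracks; per-release failures are collected in ``errors``."""

    def __init__(self, tracks: Iterable[Track] = (), errors: list[str] | None = None):
        super().__init__(tracks)
        self.errors: list[str] = list(errors or [])


# ---------------------------------------------------------------------------
# velocity sampling
# ---------------------------------------------------------------------------

def _cubic_weights(s: np.ndarray) -> np.ndarray:
    """4-point Lagrange cubic weights for fractional position s in [0, 1]."""
    w0 = -s * (s - 1.0) * (s - 2.0) / 6.0
    w1 = (s + 1.0) * (s - 1.0) * (s - 2.0) / 2.0
    w2 = -(s + 1.0) * s * (s - 2.0) / 2.0
    w3 = (s + 1.0) * s * (s - 1.0) / 6.0
    return np.stack([w0, w1, w2, w3], axis=-1)


def _sample_uv(series: VelocityFieldSeries, lon, lat, depth, t_days, mode="cubic"):
    """Vectorized velocity sample; returns (u, v, inbounds)."""
    g = series.grid
    lon = np.atleast_1d(np.asarray(lon, float))
    lat = np.atleast_1d(np.asarray(lat, float))
    depth = np.broadcast_to(np.atleast_1d(np.asarray(depth, float)), lon.shape)
    t_days = np.broadcast_to(np.atleast_1d(np.asarray(t_days, float)), lon.shape)
    nt, nz, ny, nx = g.shape

    fi = (lon - g.lons[0]) / g.spacing
    fj = (lat - g.lats[0]) / g.spacing
    tmax = g.times[-1]
    inb = ((fi >= 0) & (fi <= nx - 1) & (fj >= 0) & (fj <= ny - 1)
           & (t_days >= 0) & (t_days <= tmax + 1e-9))
    fi = np.clip(fi, 0.0, nx - 1.0)
    fj = np.clip(fj, 0.0, ny - 1.0)

    i1 = np.clip(np.floor(fi).astype(np.intp), 0, max(nx - 2, 0))
    j1 = np.clip(np.floor(fj).astype(np.intp), 0, max(ny - 2, 0))
    sx = fi - i1
    sy = fj - j1

    if nt > 1:
        ft = np.clip(t_days, 0.0, tmax) / g.snapshot_interval
        it0 = np.clip(np.floor(ft).astype(np.intp), 0, nt - 2)
        wt = ft - it0
        it1 = it0 + 1
    else:
        it0 = it1 = np.zeros(lon.shape, dtype=np.intp)
        wt = np.zeros(lon.shape)

    z = np.asarray(g.z_levels)
    kz = np.searchsorted(z, depth, side="left")
    k1 = np.clip(kz, 0, nz - 1)
    k0 = np.clip(kz - 1, 0, nz - 1)
    dz = z[k1] - z[k0]
    wz = np.where(dz > 0, np.clip((depth - z[k0]) / np.where(dz > 0, dz, 1.0), 0, 1), 0.0)

    ii = np.clip(i1[:, None] + np.arange(-1, 3), 0, nx - 1)
    jj = np.clip(j1[:, None] + np.arange(-1, 3), 0, ny - 1)

    def gather(a, it, kk):  # -> (n, 4, 4) stencils, rows = lat, cols = lon
        return a[it[:, None, None], kk[:, None, None], jj[:, :, None], ii[:, None, :]]

    wz_ = wz[:, None, None]
    wt_ = wt[:, None, None]
    U = ((1 - wt_) * ((1 - wz_) * gather(series.u, it0, k0) + wz_ * gather(series.u, it0, k1))
         + wt_ * ((1 - wz_) * gather(series.u, it1, k0) + wz_ * gather(series.u, it1, k1)))
    V = ((1 - wt_) * ((1 - wz_) * gather(series.v, it0, k0) + wz_ * gather(series.v, it0, k1))
         + wt_ * ((1 - wz_) * gather(series.v, it1, k0) + wz_ * gather(series.v, it1, k1)))

    # bilinear from the inner 2x2 of the stencil (always available)
    bx = np.stack([1 - sx, sx], axis=-1)
    by = np.stack([1 - sy, sy], axis=-1)
    u_lin = np.einsum("nij,ni,nj->n", U[:, 1:3, 1:3], by, bx)
    v_lin = np.einsum("nij,ni,nj->n", V[:, 1:3, 1:3], by, bx)

    if mode == "cubic":
        interior = (i1 >= 1) & (i1 <= nx - 3) & (j1 >= 1) & (j1 <= ny - 3)
        mvalid = series.valid[k0[:, None, None], jj[:, :, None], ii[:, None, :]]
        mvalid &= series.valid[k1[:, None, None], jj[:, :, None], ii[:, None, :]]
        cubic_ok = interior & mvalid.all(axis=(1, 2))
        if np.any(cubic_ok):
            wx = _cubic_weights(sx)
            wy = _cubic_weights(sy)
            u_cub = np.einsum("nij,ni,nj->n", U, wy, wx)
            v_cub = np.einsum("nij,ni,nj->n", V, wy, wx)
            u = np.where(cubic_ok, u_cub, u_lin)
            v = np.where(cubic_ok, v_cub, v_lin)
        else:
            u, v = u_lin, v_lin
    else:
        u, v = u_lin, v_lin
    return u, v, inb


def sample_velocity(series: VelocityFieldSeries, lon, lat, depth, time_days,
                    mode: str = "cubic"):
    """(u, v) in m/s at one or more query points.

    Bicubic horizontally (bilinear next to masked cells and domain edges, and
    in ``mode='linear'``), linear in depth between bracketing z-levels, linear
    in time between snapshots.  Raises :class:`DomainError` if any query lies
    outside the grid bounds or time span.
    """
    u, v, inb = _sample_uv(series, lon, lat, depth, time_days, mode=mode)
    if not np.all(inb):
        raise DomainError("velocity query outside grid bounds or time span")
    if np.isscalar(lon) or np.ndim(lon) == 0:
        return float(u[0]), float(v[0])
    return u, v


def _beach_tolerance_m(series: VelocityFieldSeries, depth):
    """Seafloor clearance a particle may lose before counting as beached.

    Half the local z-level spacing: the vertical granularity at which the
    emulated z-level model distinguishes water from seafloor.  Release
    points sit exactly on the seafloor interface, so a strict comparison
    would strand them on the first interpolation jitter.
    """
    z = np.asarray(series.grid.z_levels)
    if len(z) < 2:
        return np.full(np.shape(depth), 25.0)
    spacing = np.diff(z)
    k = np.clip(np.searchsorted(z, np.asarray(depth, float)) - 1, 0, len(spacing) - 1)
    return 0.5 * spacing[k]


def _cell_invalid(series: VelocityFieldSeries, lon, lat, depth):
    """True where the seafloor is shallower than the particle's depth.

    With topography attached the seafloor is evaluated at the particle
    position (analytic surface when available, bilinear otherwise); a series
    without topography falls back to the validity mask of the nearest cell
    at the deeper bracketing z-level.
    """
    if series.topo is not None:
        floor = series.topo.depth_at(np.asarray(lon, float), np.asarray(lat, float))
        return floor < np.asarray(depth, float) - _beach_tolerance_m(series, depth)
    g = series.grid
    nx, ny = len(g.lons), len(g.lats)
    i = np.clip(np.rint((np.asarray(lon, float) - g.lons[0]) / g.spacing).astype(np.intp), 0, nx - 1)
    j = np.clip(np.rint((np.asarray(lat, float) - g.lats[0]) / g.spacing).astype(np.intp), 0, ny - 1)
    z = np.asarray(g.z_levels)
    kdeep = np.clip(np.searchsorted(z, np.asarray(depth, float), side="left"),
                    0, len(z) - 1)
    return ~series.valid[kdeep, j, i]


# ---------------------------------------------------------------------------
# RK4 stepping
# ---------------------------------------------------------------------------

def _rk4_batch(series, lon, lat, depth, t_s, dt_s, config: TrackerConfig):
    """One RK4 step for arrays of particles.

    Returns (new_lon, new_lat, oob, beached) where flagged particles must be
    frozen by the caller (their returned positions are unreliable).
    """
    m_deg = config.m_per_deg
    mode = config.interp
    oob = np.zeros(lon.shape, dtype=bool)
    bea = np.zeros(lon.shape, dtype=bool)

    def f(x, y, ts):
        u, v, inb = _sample_uv(series, x, y, depth, ts / 86400.0, mode=mode)
        oob[:] |= ~inb
        bea[:] |= _cell_invalid(series, x, y, depth)
        dlat = v / m_deg
        dlon = u / (m_deg * np.cos(np.radians(y)))
        return dlon, dlat

    h = dt_s
    k1x, k1y = f(lon, lat, t_s)
    k2x, k2y = f(lon + 0.5 * h * k1x, lat + 0.5 * h * k1y, t_s + 0.5 * h)
    k3x, k3y = f(lon + 0.5 * h * k2x, lat + 0.5 * h * k2y, t_s + 0.5 * h)
    k4x, k4y = f(lon + h * k3x, lat + h * k3y, t_s + h)
    new_lon = lon + h * (k1x + 2 * k2x + 2 * k3x + k4x) / 6.0
    new_lat = lat + h * (k1y + 2 * k2y + 2 * k3y + k4y) / 6.0
    return new_lon, new_lat, oob, bea


def rk4_step(series: VelocityFieldSeries, state: ParticleState, dt_s: float,
             config: TrackerConfig | None = None) -> ParticleState:
    """Advance a single active particle by one RK4 step.

    On an out-of-bounds stage the particle is marked ``escaped``; on a stage
    in a seafloor/land cell it is marked ``beached``; either way it stays at
    its last valid position.
    """
    if state.status != "active":
        raise ValueError("rk4_step requires an active particle")
    if dt_s <= 0:
        raise ValueError("dt must be positive")
    config = config or TrackerConfig(timestep_s=dt_s, pld_days=1,
                                     output_interval_days=dt_s / 86400.0)
    lon = np.array([state.lon])
    lat = np.array([state.lat])
    dep = np.array([state.depth])
    nlon, nlat, oob, bea = _rk4_batch(series, lon, lat, dep,
                                      np.array([state.time_s]), dt_s, config)
    if oob[0]:
        return ParticleState(state.lon, state.lat, state.depth,
                             state.time_s + dt_s, "escaped")
    if bea[0]:
        return ParticleState(state.lon, state.lat, state.depth,
                             state.time_s + dt_s, "beached")
    return ParticleState(float(nlon[0]), float(nlat[0]), state.depth,
                         state.time_s + dt_s, "active")


def advect_batch(series: VelocityFieldSeries,
                 lons: Sequence[float], lats: Sequence[float],
                 depths: Sequence[float], release_days: Sequence[float],
                 config: TrackerConfig):
    """Advect many particles at once, each with its own release time.

    Returns ``(pos, status, status_day)`` where ``pos`` has shape
    ``(n, n_records, 2)`` holding (lon, lat) at every output interval
    (record 0 is the release position), ``status`` is an int code per
    particle (0 active, 1 beached, 2 escaped) and ``status_day`` the day a
    non-active status was acquired (NaN if active throughout).  Frozen
    particles repeat their last valid position in all later records.
    """
    lon = np.array(lons, dtype=float).copy()
    lat = np.array(lats, dtype=float).copy()
    dep = np.broadcast_to(np.asarray(depths, dtype=float), lon.shape).copy()
    rel = np.broadcast_to(np.asarray(release_days, dtype=float), lon.shape).copy()
    n = len(lon)

    g = series.grid
    if np.any((lon < g.lon_min) | (lon > g.lon_max) | (lat < g.lat_min) | (lat > g.lat_max)):
        raise DomainError("release position outside grid bounds")
    if np.any(rel < 0) or np.any(rel + config.pld_days > g.times[-1] + 1e-9):
        raise DomainError("release window exceeds the velocity-series time span")
    if np.any(_cell_invalid(series, lon, lat, dep)):
        raise ValueError("release position on land / inside the seamount")

    n_rec = config.n_records
    spr = config.steps_per_record
    n_steps = (n_rec - 1) * spr
    dt = config.timestep_s

    pos = np.empty((n, n_rec, 2), dtype=float)
    pos[:, 0, 0] = lon
    pos[:, 0, 1] = lat
    status = np.full(n, ACTIVE, dtype=np.int8)
    status_day = np.full(n, np.nan)

    active_idx = np.arange(n)
    for step in range(n_steps):
        if len(active_idx) == 0:
            rec = (step + 1) // spr if (step + 1) % spr == 0 else None
            if rec is not None:
                pos[:, rec, 0] = lon
                pos[:, rec, 1] = lat
            continue
        t_s = (rel[active_idx] + 0.0) * 86400.0 + step * dt
        nlon, nlat, oob, bea = _rk4_batch(series, lon[active_idx], lat[active_idx],
                                          dep[active_idx], t_s, dt, config)
        day_now = (step + 1) * dt / 86400.0
        newly_esc = active_idx[oob]
        newly_bea = active_idx[bea & ~oob]
        ok = ~(oob | bea)
        lon[active_idx[ok]] = nlon[ok]
        lat[active_idx[ok]] = nlat[ok]
        if len(newly_esc):
            status[newly_esc] = ESCAPED
            status_day[newly_esc] = day_now
        if len(newly_bea):
            status[newly_bea] = BEACHED
            status_day[newly_bea] = day_now
        if len(newly_esc) or len(newly_bea):
            active_idx = np.flatnonzero(status == ACTIVE)
        if (step + 1) % spr == 0:
            rec = (step + 1) // spr
            pos[:, rec, 0] = lon
            pos[:, rec, 1] = lat
    return pos, status, status_day


def advect_particle(series: VelocityFieldSeries, release, release_day: float,
                    config: TrackerConfig) -> Track:
    """Advect one release point; ``release`` needs lon/lat/depth attributes.

    Records a position every output interval (the release position is the
    day-0 record); a beached or escaped particle is frozen at its last valid
    position for the remaining records and flagged.
    """
    pos, status, status_day = advect_batch(
        series, [release.lon], [release.lat], [release.depth], [release_day], config)
    days = config.output_interval_days * np.arange(config.n_records)
    meta = {"point_id": getattr(release, "id", 0),
            "role": getattr(release, "role", "baseline"),
            "increment": getattr(release, "increment", None)}
    return Track(track_id=0, lons=pos[0, :, 0], lats=pos[0, :, 1], days=days,
                 depth=float(release.depth), release_day=float(release_day),
                 status=_STATUS_NAMES[int(status[0])], meta=meta)


def run_release_set(series: VelocityFieldSeries, design, config: TrackerConfig,
                    log=None) -> TrackSet:
    """One Track per (release point, release time) pair of an experiment design.

    ``design`` must provide ``release_units()`` yielding
    ``(ReleasePoint, release_day)`` pairs (see :mod:`larvalsens.design`).
    Tracks are ordered by (depth, point id, release time).  Invalid releases
    are reported in ``TrackSet.errors`` without aborting the batch.
    """
    units = sorted(design.release_units(),
                   key=lambda u: (u[0].depth, u[0].id, u[1]))
    if not units:
        return TrackSet()
    lons = np.array([p.lon for p, _ in units])
    lats = np.array([p.lat for p, _ in units])
    deps = np.array([p.depth for p, _ in units])
    rels = np.array([d for _, d in units])

    errors: list[str] = []
    keep = np.ones(len(units), dtype=bool)
    g = series.grid
    bad_pos = ((lons < g.lon_min) | (lons > g.lon_max)
               | (lats < g.lat_min) | (lats > g.lat_max))
    bad_pos |= _cell_invalid(series, lons, lats, deps)
    bad_time = (rels < 0) | (rels + config.pld_days > g.times[-1] + 1e-9)
    for i in np.flatnonzero(bad_pos | bad_time):
        p, d = units[i]
        why = "invalid release position" if bad_pos[i] else "release window outside span"
        errors.append(f"point {p.id} depth {p.depth} day {d}: {why}")
        keep[i] = False
    idx = np.flatnonzero(keep)
    tracks = TrackSet(errors=errors)
    if len(idx) == 0:
        return tracks
    if log:
        log(f"advecting {len(idx)} particles "
            f"({config.pld_days:g} d PLD, dt={config.timestep_s:g} s)")
    pos, status, _ = advect_batch(series, lons[idx], lats[idx], deps[idx],
                                  rels[idx], config)
    days = config.output_interval_days * np.arange(config.n_records)
    for out_i, i in enumerate(idx):
        p, d = units[i]
        tracks.append(Track(
            track_id=int(out_i), lons=pos[out_i, :, 0], lats=pos[out_i, :, 1],
            days=days.copy(), depth=float(p.depth), release_day=float(d),
            status=_STATUS_NAMES[int(status[out_i])],
            meta={"point_id": p.id, "role": getattr(p, "role", "baseline"),
                  "increment": getattr(p, "increment", None)}))
    return tracks


# ---------------------------------------------------------------------------
# trajectory I/O
# ---------------------------------------------------------------------------

def tracks_to_dataframe(tracks: Sequence[Track]):
    """Long-format trajectory table: one row per track per day."""
    import pandas as pd

    frames = []
    for tr in tracks:
        frames.append(pd.DataFrame({
            "track_id": tr.track_id,
            "point_id": tr.meta.get("point_id", -1),
            "depth_band": tr.depth,
            "release_day": tr.release_day,
            "day": tr.days,
            "lon": tr.lons,
            "lat": tr.lats,
            "status": tr.status,
        }))
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["track_id", "point_id", "depth_band", "release_day",
                 "day", "lon", "lat", "status"])


def write_tracks_csv(tracks: Sequence[Track], path) -> None:
    tracks_to_dataframe(tracks).to_csv(path, index=False)


def write_tracks_netcdf(tracks: Sequence[Track], path) -> None:
    """Trajectory file in (track x obs) layout with per-track metadata."""
    import xarray as xr

    if not tracks:
        raise ValueError("no tracks to write")
    n_obs = max(len(t) for t in tracks)
    lons = np.full((len(tracks), n_obs), np.nan)
    lats = np.full((len(tracks), n_obs), np.nan)
    for i, t in enumerate(tracks):
        lons[i, :len(t)] = t.lons
        lats[i, :len(t)] = t.lats
    ds = xr.Dataset(
        {
            "lon": (("track", "obs"), lons, {"units": "degrees_east"}),
            "lat": (("track", "obs"), lats, {"units": "degrees_north"}),
            "depth": (("track",), [t.depth for t in tracks], {"units": "m"}),
            "release_day": (("track",), [t.release_day for t in tracks]),
            "point_id": (("track",), [t.meta.get("point_id", -1) for t in tracks]),
            "status": (("track",), [t.status for t in tracks]),
        },
        coords={"track": [t.track_id for t in tracks],
                "obs": tracks[0].days[:n_obs]},
    )
    ds.to_netcdf(path, engine="scipy")


def read_tracks_csv(path) -> TrackSet:
    import pandas as pd

    df = pd.read_csv(path)
    out = TrackSet()
    for (tid, pid, depth, rel, status), sub in df.groupby(
            ["track_id", "point_id", "depth_band", "release_day", "status"],
            sort=True):
        sub = sub.sort_values("day")
        out.append(Track(track_id=int(tid), lons=sub["lon"].to_numpy(),
                         lats=sub["lat"].to_numpy(), days=sub["day"].to_numpy(),
                         depth=float(depth), release_day=float(rel),
                         status=str(status), meta={"point_id": int(pid)}))
    return out
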