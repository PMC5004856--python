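"""Experiment designs: release geometry, parameter sweeps, schedules, counts.

Builds the sensitivity-test designs the analysis engines consume: rings of
release points on a seamount depth contour, horizontal/vertical increment
placement, release schedules at standard frequencies, year-subset
combinations for temporal-range tests, and exact enumeration of particle
counts.

Horizontal-separation increments are specified in degrees (comparable to the
grid) and interpreted as a buffer radius: the increment point sits at
along-contour arc length ``offset_deg * (pi/180) * R`` clockwise from its
baseline, staying on the same depth contour so it keeps interfacing with the
seamount.  Vertical increments displace depth only.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from ._geo import (EARTH_RADIUS_KM, M_PER_DEG, azimuth_deg, destination,
                   haversine_km)
from .synthetic_ocean import Topography

__all__ = [
    "ReleasePoint",
    "ParameterSweep",
    "ReleaseSchedule",
    "ExperimentDesign",
    "DesignCounts",
    "YearCombo",
    "ring_release_points",
    "offset_along_contour",
    "offset_depth",
    "build_release_schedule",
    "year_combinations",
    "enumerate_design",
    "FREQUENCY_COUNTS",
    "DEFAULT_NAO_STATES",
]

#: releases per year for the standard frequency labels ("biweekly" follows
#: the twice-weekly reading, 104/yr)
FREQUENCY_COUNTS = {"daily": 365, "2-daily": 183, "biweekly": 104,
                    "weekly": 52, "monthly": 12, "seasonal": 4}

#: winter (Dec-Mar) North Atlantic Oscillation states for the simulation
#: years this toolkit's schedules are tagged with by default
DEFAULT_NAO_STATES = {2009: "neutral", 2010: "strong negative",
                      2012: "strong positive"}

_KM_PER_DEG = M_PER_DEG / 1000.0


@dataclass(frozen=True)
class ReleasePoint:
    id: int
    lon: float
    lat: float
    depth: float
    role: str = "baseline"  # "baseline" | "increment"
    increment: float | None = None
    parameter: str | None = None
    #: depth of the topographic contour the point geometrically sits on;
    #: equals ``depth`` for on-seafloor releases, deeper when the release is
    #: stood slightly off the wall
    contour_depth: float | None = None


@dataclass(frozen=True)
class ParameterSweep:
    """One tested parameter: its baseline value and increment list.

    Units: TS hours, HS degrees, VS metres (negative = shallower), RF
    releases per year, TR years.
    """

    parameter: str
    baseline: float
    increments: tuple[float, ...]

    def __post_init__(self):
        if self.parameter not in ("TS", "HS", "VS", "RF", "TR"):
            raise ValueError(f"unknown parameter {self.parameter!r}")
        inc = tuple(float(v) for v in self.increments)
        if len(set(inc)) != len(inc):
            raise ValueError("increments must be distinct")
        d = np.diff(inc)
        if len(d) and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("increments must be ordered")
        object.__setattr__(self, "increments", inc)

    @classmethod
    def default(cls, parameter: str) -> "ParameterSweep":
        """The standard sweeps: TS 1 h baseline vs 3/6/12/24 h; HS 0 vs
        +0.001/0.005/0.01/0.025 deg; VS 0 vs -0.1/-1/-10/-50 m; RF 365/yr vs
        183/104/52/12/4; TR 5 yr vs 1-4 yr."""
        table = {
            "TS": (1.0, (3.0, 6.0, 12.0, 24.0)),
            "HS": (0.0, (0.001, 0.005, 0.01, 0.025)),
            "VS": (0.0, (-0.1, -1.0, -10.0, -50.0)),
            "RF": (365.0, (183.0, 104.0, 52.0, 12.0, 4.0)),
            "TR": (5.0, (1.0, 2.0, 3.0, 4.0)),
        }
        base, inc = table[parameter]
        return cls(parameter=parameter, baseline=base, increments=inc)


@dataclass
class ReleaseSchedule:
    """Ordered release times (days since field-series origin) with metadata."""

    times: np.ndarray
    frequency: str = "custom"
    year_length_days: float = 365.0
    nao_states: dict[int, str] = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) and np.any(np.diff(self.times) <= 0):
            raise ValueError("release times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class ExperimentDesign:
    """Release points x schedule (x optional sweep), enumerable to counts."""

    points: list[ReleasePoint]
    schedule: ReleaseSchedule
    sweep: ParameterSweep | None = None

    @property
    def depths(self) -> list[float]:
        return sorted({p.depth for p in self.points})

    def release_units(self):
        """All (point, release_day) pairs of the baseline set."""
        return [(p, float(t)) for p in self.points for t in self.schedule.times]


@dataclass(frozen=True)
class DesignCounts:
    baseline_tracks: int
    increment_tracks: int
    total_particles: int
    points_per_depth: int
    n_depths: int
    n_releases: int
    n_increments: int


@dataclass(frozen=True)
class YearCombo:
    years: tuple[int, ...]
    nao_states: tuple[str, ...]


# ---------------------------------------------------------------------------
# contour geometry
# ---------------------------------------------------------------------------

def _closed_contours(topo: Topography, depth: float):
    """Closed depth contours as (lon, lat) vertex arrays, largest first."""
    from skimage import measure

    g = topo.grid
    out = []
    for c in measure.find_contours(topo.depth, depth):
        if len(c) > 3 and np.allclose(c[0], c[-1]):
            lats = g.lats[0] + c[:, 0] * g.spacing
            lons = g.lons[0] + c[:, 1] * g.spacing
            out.append(np.column_stack([lons, lats]))
    out.sort(key=len, reverse=True)
    return out


def _contour_centre(topo: Topography, depth: float,
                    ring: np.ndarray | None = None) -> tuple[float, float]:
    """Refined centre of the closed contour at a depth.

    The raw vertex centroid is biased by uneven marching-squares vertex
    density; it is re-estimated a few times from radially refined probe
    points so all contour operations share one well-centred origin.
    """
    if ring is None:
        contours = _closed_contours(topo, depth)
        if not contours:
            raise ValueError(f"no closed contour at {depth} m")
        ring = contours[0][:-1]  # drop duplicated closing vertex
    clon, clat = float(ring[:, 0].mean()), float(ring[:, 1].mean())
    bearings = 45.0 * np.arange(8)
    for _ in range(6):
        radii = []
        for bearing in bearings:
            r0 = _polyline_radius(ring, clon, clat, bearing)
            radii.append(_radius_at_bearing(topo, depth, clon, clat, bearing, r0))
        radii = np.asarray(radii)
        # an off-centre origin makes r(theta) = R - eps*cos(theta - theta0);
        # cancel that first harmonic to land on the circumcentre
        th = np.radians(bearings)
        a1 = 0.25 * np.sum(radii * np.cos(th))
        b1 = 0.25 * np.sum(radii * np.sin(th))
        eps = float(np.hypot(a1, b1))
        if eps < 1e-9:
            break
        back = np.degrees(np.arctan2(-b1, -a1)) + 180.0
        clon, clat = destination(clon, clat, back, eps)
    return clon, clat


def _radius_at_bearing(topo: Topography, depth: float,
                       clon: float, clat: float, bearing_deg: float,
                       r_guess_km: float) -> float:
    """Contour radius (km) along a great-circle bearing, by root-finding.

    Trial points are placed with the exact spherical destination formula, so
    a radially symmetric seamount's contour is a true spherical circle of
    constant radius.  Uses the topography's analytic surface when available
    (bilinear grid interpolation otherwise); falls back to the guess when
    the bracket does not straddle the contour.
    """

    def f(r_km):
        lon, lat = destination(clon, clat, bearing_deg, r_km)
        return float(topo.depth_at(lon, lat)) - depth

    lo, hi = 0.25 * r_guess_km, 2.0 * r_guess_km
    try:
        if f(lo) * f(hi) < 0:
            return brentq(f, lo, hi, xtol=1e-12)
    except ValueError:
        pass
    return r_guess_km


def _polyline_radius(ring_lonlat: np.ndarray, clon: float, clat: float,
                     bearing_deg: float) -> float:
    """Interpolated contour radius (km) at a bearing from the polyline."""
    x = (ring_lonlat[:, 0] - clon) * _KM_PER_DEG * np.cos(np.radians(clat))
    y = (ring_lonlat[:, 1] - clat) * _KM_PER_DEG
    ang = np.degrees(np.arctan2(x, y)) % 360.0
    r = np.hypot(x, y)
    order = np.argsort(ang)
    ang_s, r_s = ang[order], r[order]
    return float(np.interp(bearing_deg % 360.0,
                           np.concatenate([ang_s - 360.0, ang_s, ang_s + 360.0]),
                           np.concatenate([r_s, r_s, r_s])))


def ring_release_points(topo: Topography, depth: float, n: int = 16,
                        parameter: str | None = None) -> list[ReleasePoint]:
    """``n`` release points on the closed depth contour of a seamount.

    Points sit at equal angular spacing about the contour centroid, id 0 due
    north of the centroid and ids increasing clockwise.  Each point is
    radially refined so its topographic depth matches the requested contour
    depth.  Raises if no closed contour exists at that depth.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    contours = _closed_contours(topo, depth)
    if not contours:
        raise ValueError(f"no closed contour at {depth} m")
    ring = contours[0][:-1]
    clon, clat = _contour_centre(topo, depth, ring=ring)
    pts = []
    for k in range(n):
        bearing = 360.0 * k / n
        r0 = _polyline_radius(ring, clon, clat, bearing)
        r = _radius_at_bearing(topo, depth, clon, clat, bearing, r0)
        lon, lat = destination(clon, clat, bearing, r)
        pts.append(ReleasePoint(id=k, lon=float(lon), lat=float(lat),
                                depth=float(depth), role="baseline",
                                parameter=parameter, contour_depth=float(depth)))
    return pts


def offset_along_contour(point: ReleasePoint, offset_deg: float,
                         topo: Topography,
                         contour_depth: float | None = None) -> ReleasePoint:
    """Displace a release point along its depth contour, clockwise.

    ``offset_deg`` is a buffer radius in degrees; the point moves an
    along-contour arc length of ``offset_deg * (pi/180) * R`` (111.19 km per
    degree) and keeps its depth, so it still interfaces with the seamount.
    Raises if the offset exceeds half the contour length.
    """
    if offset_deg <= 0:
        raise ValueError("offset must be positive")
    cdepth = contour_depth if contour_depth is not None else (
        point.contour_depth if point.contour_depth is not None else point.depth)
    clon, clat = _contour_centre(topo, cdepth)
    r = float(haversine_km(clon, clat, point.lon, point.lat))
    if r <= 0:
        raise ValueError("point coincides with the contour centre")
    arc_km = offset_deg * _KM_PER_DEG
    if arc_km > np.pi * r:
        raise ValueError("offset exceeds half the contour length")
    # azimuth change along the spherical small circle of radius r
    small_circle_radius = EARTH_RADIUS_KM * np.sin(r / EARTH_RADIUS_KM)
    bearing = (azimuth_deg(clon, clat, point.lon, point.lat)
               + np.degrees(arc_km / small_circle_radius))
    r_new = _radius_at_bearing(topo, cdepth, clon, clat, bearing, r)
    lon, lat = destination(clon, clat, bearing, r_new)
    return replace(point, lon=float(lon), lat=float(lat), role="increment",
                   increment=float(offset_deg))


def offset_depth(point: ReleasePoint, dz_m: float) -> ReleasePoint:
    """Vertical increment: same lon/lat, depth shallower by ``|dz_m|``.

    Standard vertical sweeps use negative increments (-0.1/-1/-10/-50 m,
    i.e. shallower than baseline); a zero offset is the identity.
    """
    if dz_m == 0:
        return point
    new_depth = point.depth - abs(dz_m)
    if new_depth <= 0:
        raise ValueError("vertical offset would surface the release point")
    return replace(point, depth=float(new_depth), role="increment",
                   increment=float(dz_m))


def build_release_schedule(n_years: int = 1, frequency="monthly",
                           year_length_days: float = 365.0,
                           start_day: float = 0.0,
                           start_year: int | None = None,
                           nao_states: dict[int, str] | None = None
                           ) -> ReleaseSchedule:
    """Evenly spaced release times at a standard frequency.

    ``frequency`` is a label (daily 365/yr, 2-daily 183, biweekly 104,
    weekly 52, monthly 12, seasonal 4) or an explicit per-year count.  365
    daily releases are used regardless of leap years.  When ``start_year``
    is given, each simulated year is tagged with its winter NAO state
    (``nao_states`` mapping, defaulting to :data:`DEFAULT_NAO_STATES`).
    """
    if isinstance(frequency, str):
        if frequency not in FREQUENCY_COUNTS:
            raise ValueError(f"unknown frequency label {frequency!r}")
        count = FREQUENCY_COUNTS[frequency]
        label = frequency
    else:
        count = int(frequency)
        if count < 1:
            raise ValueError("per-year release count must be >= 1")
        label = f"{count}/yr"
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    per_year = year_length_days / count * np.arange(count)
    times = np.concatenate([start_day + y * year_length_days + per_year
                            for y in range(n_years)])
    tags = {}
    if start_year is not None:
        source = DEFAULT_NAO_STATES if nao_states is None else nao_states
        tags = {start_year + y: source.get(start_year + y, "unclassified")
                for y in range(n_years)}
    return ReleaseSchedule(times=times, frequency=label,
                           year_length_days=year_length_days, nao_states=tags)


def year_combinations(years: Sequence[int], k: int,
                      nao_states: dict[int, str] | None = None) -> list[YearCombo]:
    """All k-subsets of simulation years, lexicographic, NAO-tagged.

    With five years this yields the standard 5/10/10/5/1 subset counts for
    k = 1..5.
    """
    years = list(years)
    if not (1 <= k <= len(years)):
        raise ValueError("k must be between 1 and the number of years")
    source = DEFAULT_NAO_STATES if nao_states is None else nao_states
    return [YearCombo(years=combo,
                      nao_states=tuple(source.get(y, "unclassified") for y in combo))
            for combo in itertools.combinations(years, k)]


def enumerate_design(design: ExperimentDesign) -> DesignCounts:
    """Exact combinatorial particle counts for a design.

    ``total = baseline * (1 + n_increments)``: the standard spatial test (16
    points x 3 depths x 12 releases, 4 increments) enumerates to 576 baseline
    tracks and 2880 particles per baseline/increment pairing.
    """
    depths = design.depths
    n_depths = max(len(depths), 1)
    per_depth = len(design.points) // n_depths if design.points else 0
    n_rel = len(design.schedule)
    baseline = len(design.points) * n_rel
    n_inc = len(design.sweep.increments) if design.sweep else 0
    return DesignCounts(baseline_tracks=baseline,
                        increment_tracks=baseline * n_inc,
                        total_particles=baseline * (1 + n_inc),
                        points_per_depth=per_depth, n_depths=len(depths),
                        n_releases=n_rel, n_increments=n_inc)


def save_design(design: ExperimentDesign, path) -> None:
    """Persist a design (points, schedule, sweep) as YAML."""
    import yaml

    payload = {
        "points": [{"id": p.id, "lon": p.lon, "lat": p.lat, "depth": p.depth,
                    "role": p.role, "increment": p.increment,
                    "parameter": p.parameter, "contour_depth": p.contour_depth}
                   for p in design.points],
        "schedule": {"times": [float(t) for t in design.schedule.times],
                     "frequency": design.schedule.frequency,
                     "year_length_days": design.schedule.year_length_days,
                     "nao_states": {int(k): v for k, v
                                    in design.schedule.nao_states.items()}},
    }
    if design.sweep is not None:
        payload["sweep"] = {"parameter": design.sweep.parameter,
                            "baseline": design.sweep.baseline,
                            "increments": list(design.sweep.increments)}
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def load_design(path) -> ExperimentDesign:
    """Read a design written by :func:`save_design`."""
    import yaml

    with open(path) as fh:
        payload = yaml.safe_load(fh)
    points = [ReleasePoint(**p) for p in payload["points"]]
    s = payload["schedule"]
    schedule = ReleaseSchedule(times=np.asarray(s["times"], dtype=float),
                               frequency=s.get("frequency", "custom"),
                               year_length_days=s.get("year_length_days", 365.0),
                               nao_states=s.get("nao_states", {}))
    sweep = None
    if "sweep" in payload:
        sw = payload["sweep"]
        sweep = ParameterSweep(parameter=sw["parameter"], baseline=sw["baseline"],
                               increments=tuple(sw["increments"]))
    return ExperimentDesign(points=points, schedule=schedule, sweep=sweep)


def points_to_dataframe(points: Sequence[ReleasePoint]):
    """Release-point table (id, lon, lat, depth, role, increment)."""
    import pandas as pd

    return pd.DataFrame([{
        "id": p.id, "lon": p.lon, "lat": p.lat, "depth": p.depth,
        "role": p.role, "increment": p.increment, "parameter": p.parameter,
    } for p in points])
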