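"""Suite orchestration, Courant utilities and Table-style optima reports.

Runs the five sensitivity tests — simulator timestep (TS), release frequency
(RF), horizontal (HS) and vertical (VS) separation of release points, and
temporal range (TR) — against a velocity-field series, in the dependency
order TS first (a wrong timestep would contaminate every other test), then
RF (an under-seeded release schedule would understate current variability),
then the spatial tests, then TR.  TS/HS/VS are analysed with pooled-median
DST against a distance threshold; RF/TR with the 95 % FUV envelope against a
saturation threshold.  The result is an optima table with one row per
parameter and depth band, flagged "approx." where the interpolant had to be
extrapolated beyond the tested increments.

Every configuration is explicit in :class:`SuiteConfig`; a single master
seed drives the synthetic ocean, so a re-run with the same config is
byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from . import design as dz
from . import dst_analysis as dst
from . import saturation_analysis as sat
from . import synthetic_ocean as ocean
from . import tracker
from ._geo import M_PER_DEG

__all__ = [
    "CourantInputs",
    "SuiteConfig",
    "OptimaReport",
    "SuiteResult",
    "courant_number",
    "domain_speed_stats",
    "implied_speed",
    "round_sig",
    "build_environment",
    "run_sensitivity_suite",
]


# ---------------------------------------------------------------------------
# small numeric utilities
# ---------------------------------------------------------------------------

def courant_number(mean_speed_ms: float, timestep_s: float,
                   grid_spacing_m: float) -> float:
    """Courant number C = V * dT / dL.

    A dimensionless check that a simulator timestep samples every grid cell
    along a path: C <= 1 means a particle moving at the given speed cannot
    skip a cell between interrogations.
    """
    if mean_speed_ms <= 0 or timestep_s <= 0 or grid_spacing_m <= 0:
        raise ValueError("Courant inputs must all be positive")
    return mean_speed_ms * timestep_s / grid_spacing_m


@dataclass(frozen=True)
class CourantInputs:
    mean_speed_ms: float
    timestep_s: float
    grid_spacing_m: float

    @property
    def courant(self) -> float:
        return courant_number(self.mean_speed_ms, self.timestep_s,
                              self.grid_spacing_m)


def implied_speed(distance_m: float, time_s: float) -> float:
    """Speed implied by covering a distance in a time (m/s).

    Relates a horizontal-separation optimum (distance) to a timestep optimum
    (time): the current speed the model would need for the two results to be
    mutually consistent.
    """
    if distance_m <= 0 or time_s <= 0:
        raise ValueError("distance and time must be positive")
    return distance_m / time_s


def round_sig(x: float, sig: int = 2) -> float:
    """Round to a number of significant figures (report convention)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, sig - 1 - int(math.floor(math.log10(abs(x)))))


def domain_speed_stats(series: ocean.VelocityFieldSeries,
                       level_index: int | None = None,
                       tracks: Sequence[tracker.Track] | None = None):
    """Mean and max speed (m/s) over a level's valid cells or along tracks.

    With ``tracks``, only the grid cells the trajectories enter (at each
    track's depth level) contribute — the trajectory-encountered velocity
    range a post-hoc Courant check should use.
    """
    g = series.grid
    speed = np.sqrt(series.u ** 2 + series.v ** 2)
    if tracks is not None:
        if len(tracks) == 0:
            raise ValueError("empty track selection")
        z = np.asarray(g.z_levels)
        vals = []
        for tr in tracks:
            k = int(np.argmin(np.abs(z - tr.depth)))
            mark = sat.track_cells(tr, g.lons[0] - 0.5 * g.spacing,
                                   g.lats[0] - 0.5 * g.spacing, g.spacing,
                                   (len(g.lats), len(g.lons)))
            mark &= series.valid[k]
            if np.any(mark):
                vals.append(speed[:, k, mark].ravel())
        if not vals:
            raise ValueError("tracks enter no valid cells")
        allv = np.concatenate(vals)
    else:
        if level_index is None:
            raise ValueError("give either level_index or tracks")
        m = series.valid[level_index]
        if not np.any(m):
            raise ValueError("level has no valid cells")
        allv = speed[:, level_index, m].ravel()
    return float(allv.mean()), float(allv.max())


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SuiteConfig:
    """Everything a sensitivity suite needs, with scalable problem sizes.

    The defaults describe the study conditions of the standard design: a
    0.08-degree grid over a guyot spanning 600-2000 m, 16 release points per
    depth band at 700/1000/1500 m (200/1000/1750 m for the vertical test),
    monthly releases through one year, a 100-day PLD at a 1-hour timestep, a
    10 km DST threshold and a 0.05 FUV threshold.  ``demo`` builds a reduced
    configuration sized for interactive runs.
    """

    # synthetic ocean
    lon_min: float = -15.0
    lon_max: float = -7.0
    lat_min: float = 54.5
    lat_max: float = 60.5
    spacing: float = 0.08
    z_min: float = 150.0
    z_max: float = 2000.0
    guyot_summit_depth: float = 600.0
    guyot_base_depth: float = 2000.0
    guyot_summit_radius_km: float = 12.0
    guyot_base_radius_km: float = 35.0
    #: reference domain is ~2x the demo area; eddy count scales with area so
    #: the eddy density (what the release rings feel) stays the same
    eddy: ocean.EddyFieldParams = field(
        default_factory=lambda: ocean.EddyFieldParams(n_eddies=50))
    field_dtype: str = "float32"
    # design
    depths: tuple[float, ...] = (700.0, 1000.0, 1500.0)
    vs_depths: tuple[float, ...] = (200.0, 1000.0, 1750.0)
    n_points: int = 16
    releases_per_year: int = 12
    year_length_days: float = 365.0
    start_year: int = 2008
    tr_years: int = 5
    # tracker
    pld_days: float = 100.0
    timestep_s: float = 3600.0
    interp: str = "cubic"
    # sweeps & analysis
    sweeps: dict = field(default_factory=lambda: {
        p: dz.ParameterSweep.default(p) for p in ("TS", "HS", "VS", "RF", "TR")})
    dst_threshold_km: float = 10.0
    fuv_threshold: float = 0.05
    raster_cell_deg: float = 0.04
    tests: tuple[str, ...] = ("TS", "RF", "HS", "VS", "TR")
    #: releases stand off the seamount wall by this much seafloor clearance
    #: (their ring sits on the contour this much deeper than the release
    #: depth).  The emulated model cannot resolve seafloor contact below a
    #: grid cell, and releases placed exactly on the analytic wall strand on
    #: interpolation jitter instead of dispersing.
    release_clearance_m: float = 250.0
    seed: int = 0

    @classmethod
    def demo(cls, seed: int = 0, tests: tuple[str, ...] | None = None) -> "SuiteConfig":
        """A reduced suite sized for interactive runs and worked examples.

        8 points per band, 8 releases through one year, 60-day PLD at a
        2-hour timestep, a 5 x 4.5 degree domain, 2-year temporal range.
        The horizontal-separation sweep extends to 0.05 degrees (above the
        0.08-degree grid scale) so threshold crossings fall inside the
        tested range at this PLD, and the release-frequency sweep uses a
        weekly baseline.
        """
        cfg = cls(
            lon_min=-13.5, lon_max=-8.5, lat_min=55.0, lat_max=59.5,
            n_points=8, releases_per_year=8, pld_days=60.0, timestep_s=7200.0,
            tr_years=2, seed=seed,
            eddy=replace(ocean.EddyFieldParams(), seed=seed),
        )
        if tests is not None:
            cfg.tests = tests
        cfg.sweeps = dict(cfg.sweeps)
        cfg.sweeps["HS"] = dz.ParameterSweep("HS", 0.0, (0.005, 0.01, 0.025, 0.05))
        cfg.sweeps["RF"] = dz.ParameterSweep("RF", 52.0, (26.0, 12.0, 4.0))
        cfg.sweeps["TR"] = dz.ParameterSweep("TR", float(cfg.tr_years), (1.0,))
        return cfg

    def with_seed(self, seed: int) -> "SuiteConfig":
        cfg = replace(self, seed=seed, eddy=replace(self.eddy, seed=seed))
        return cfg

    def tracker_config(self, timestep_s: float | None = None) -> tracker.TrackerConfig:
        return tracker.TrackerConfig(
            timestep_s=timestep_s or self.timestep_s, pld_days=self.pld_days,
            output_interval_days=1.0, interp=self.interp)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["eddy"].pop("amplitude_profile", None)
        d["sweeps"] = {k: dataclasses.asdict(v) for k, v in self.sweeps.items()}
        return d


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

@dataclass
class OptimaRow:
    parameter: str
    test_type: str
    depth: float
    optimal: float
    units: str
    extrapolated: bool

    @property
    def display(self) -> str:
        v = round_sig(self.optimal, 3) if math.isfinite(self.optimal) else self.optimal
        return f"{v:g} {self.units}" + (" (approx.)" if self.extrapolated else "")


@dataclass
class OptimaReport:
    rows: list[OptimaRow] = field(default_factory=list)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame([{
            "parameter": r.parameter, "test_type": r.test_type,
            "depth_m": r.depth, "optimal": r.optimal, "units": r.units,
            "extrapolated": r.extrapolated} for r in self.rows])

    def to_markdown(self) -> str:
        lines = ["| Parameter | Test type | Depth | Optimal value |",
                 "|---|---|---|---|"]
        for r in self.rows:
            lines.append(f"| {r.parameter} | {r.test_type} | {r.depth:g} m "
                         f"| {r.display} |")
        return "\n".join(lines)

    def get(self, parameter: str, depth: float) -> OptimaRow | None:
        for r in self.rows:
            if r.parameter == parameter and abs(r.depth - depth) < 1e-9:
                return r
        return None


@dataclass
class SuiteResult:
    config: SuiteConfig
    report: OptimaReport
    curves: dict = field(default_factory=dict)       # parameter -> list of curves
    summaries: dict = field(default_factory=dict)    # parameter -> list of DstSummary
    errors: dict = field(default_factory=dict)       # parameter -> message
    speed_checks: dict = field(default_factory=dict)  # depth -> implied m/s


# ---------------------------------------------------------------------------
# environment & test machinery
# ---------------------------------------------------------------------------

def build_environment(config: SuiteConfig, n_snapshots: int | None = None):
    """Grid, guyot topography and velocity series for a suite config."""
    if n_snapshots is None:
        horizons = [config.year_length_days]
        if "TR" in config.tests:
            horizons.append(config.tr_years * config.year_length_days)
        n_snapshots = int(np.ceil(max(horizons) + config.pld_days)) + 2
    grid = ocean.GridSpec(
        lon_min=config.lon_min, lon_max=config.lon_max,
        lat_min=config.lat_min, lat_max=config.lat_max,
        spacing=config.spacing,
        z_levels=tuple(ocean.levitus_levels(config.z_min, config.z_max)),
        n_snapshots=n_snapshots)
    topo = ocean.make_guyot_topography(
        grid, summit_depth=config.guyot_summit_depth,
        base_depth=config.guyot_base_depth,
        summit_radius_km=config.guyot_summit_radius_km,
        base_radius_km=config.guyot_base_radius_km)
    params = replace(config.eddy, seed=config.seed)
    series = ocean.generate_velocity_series(
        grid, topo, params, dtype=np.dtype(config.field_dtype))
    return grid, topo, series


def _ring_points(topo: ocean.Topography, depth: float, n: int,
                 parameter: str | None = None,
                 clearance_m: float = 0.0) -> list[dz.ReleasePoint]:
    """Ring release points for a depth band.

    The ring is taken on the contour ``clearance_m`` deeper than the release
    depth (a stand-off from the wall); depths shallower than the summit
    release in open water above the summit-edge ring.
    """
    summit = float(topo.depth.min())
    contour_depth = depth + clearance_m
    if contour_depth <= summit:
        contour_depth = summit + 1.0
    try:
        ring = dz.ring_release_points(topo, contour_depth, n)
    except ValueError:
        ring = dz.ring_release_points(topo, summit + 1.0, n)
    return [replace(p, depth=depth, parameter=parameter) for p in ring]


def _run_tracks(series, points, schedule, cfg) -> tracker.TrackSet:
    return tracker.run_release_set(
        series, dz.ExperimentDesign(points=list(points), schedule=schedule), cfg)


def _pair_dst(baseline: tracker.TrackSet, increment: tracker.TrackSet,
              increment_value: float, band_of=None) -> list[dst.DstSeries]:
    """Pair tracks by (point id, release time); band label optionally remapped."""
    key = lambda t: (t.meta.get("point_id"), round(t.release_day, 6))
    inc_by_key = {}
    for t in increment:
        inc_by_key[key(t)] = t
    out = []
    for bt in baseline:
        it = inc_by_key.get(key(bt))
        if it is None:
            continue
        s = dst.dst_series(bt, it)
        s.increment = float(increment_value)
        s.depth = bt.depth if band_of is None else band_of(bt)
        out.append(s)
    return out


def _spatial_test(parameter: str, series, topo, config: SuiteConfig,
                  schedule, log: Callable[[str], None]):
    """TS / HS / VS: DST medians per increment per band, threshold crossing."""
    sweep = config.sweeps[parameter]
    bands = config.vs_depths if parameter == "VS" else config.depths
    points = []
    for d in bands:
        points += _ring_points(topo, d, config.n_points, parameter,
                               clearance_m=config.release_clearance_m)
    cfg0 = config.tracker_config(
        timestep_s=sweep.baseline * 3600.0 if parameter == "TS" else None)
    log(f"[{parameter}] baseline: {len(points)} points x {len(schedule)} releases")
    base = _run_tracks(series, points, schedule, cfg0)

    summaries, curves = [], []
    knots: dict[float, list[tuple[float, float]]] = {d: [] for d in bands}
    for inc in sweep.increments:
        if parameter == "TS":
            inc_tracks = _run_tracks(series, points, schedule,
                                     config.tracker_config(timestep_s=inc * 3600.0))
            x = float(inc)
        elif parameter == "HS":
            inc_points = [dz.offset_along_contour(p, inc, topo) for p in points]
            inc_tracks = _run_tracks(series, inc_points, schedule, cfg0)
            x = float(inc)
        else:  # VS: negative increments displace shallower; x-axis is |dz|
            inc_points = [dz.offset_depth(p, inc) for p in points]
            inc_tracks = _run_tracks(series, inc_points, schedule, cfg0)
            x = abs(float(inc))
        for d in bands:
            sel_b = tracker.TrackSet(t for t in base if abs(t.depth - d) < 1e-9)
            if parameter == "VS":
                sel_i = tracker.TrackSet(
                    t for t in inc_tracks if abs(t.depth - (d - abs(inc))) < 1e-9)
                pairs = _pair_dst(sel_b, sel_i, x, band_of=lambda t, d=d: d)
            else:
                sel_i = tracker.TrackSet(t for t in inc_tracks
                                         if abs(t.depth - d) < 1e-9)
                pairs = _pair_dst(sel_b, sel_i, x)
            summary = dst.pool_dst(pairs, depth=d, increment=x)
            summaries.append(summary)
            knots[d].append((x, summary.median_km))
    anchor_x = sweep.baseline if parameter == "TS" else 0.0
    for d in bands:
        opt, flag = dst.fit_threshold_crossing(
            knots[d], config.dst_threshold_km, anchor=(float(anchor_x), 0.0))
        xs = np.array([anchor_x] + [k[0] for k in knots[d]], dtype=float)
        ys = np.array([0.0] + [k[1] for k in knots[d]], dtype=float)
        curves.append(dst.SensitivityCurve(
            depth=d, increments=xs, statistics=ys,
            threshold=config.dst_threshold_km, optimal=opt,
            extrapolated=flag, parameter=parameter))
    return curves, summaries, base


def _location_rasters(tracks, config: SuiteConfig, select=None):
    """One raster per (depth, point id), pooling that location's releases."""
    extent = (config.lon_min, config.lon_max, config.lat_min, config.lat_max)
    groups: dict[tuple, list] = {}
    for t in tracks:
        if select is not None and not select(t):
            continue
        groups.setdefault((t.depth, t.meta.get("point_id")), []).append(t)
    return {k: sat.rasterize_tracks(v, cell_deg=config.raster_cell_deg,
                                    extent=extent)
            for k, v in sorted(groups.items())}


def _rf_test(series, topo, config: SuiteConfig, log):
    """Release frequency: FUV of each frequency against the daily-style baseline."""
    sweep = config.sweeps["RF"]
    points = []
    for d in config.depths:
        points += _ring_points(topo, d, config.n_points, "RF",
                               clearance_m=config.release_clearance_m)
    cfg = config.tracker_config()
    sched_base = dz.build_release_schedule(
        1, int(sweep.baseline), config.year_length_days,
        start_year=config.start_year)
    log(f"[RF] baseline {int(sweep.baseline)}/yr: "
        f"{len(points) * len(sched_base)} tracks")
    base_tracks = _run_tracks(series, points, sched_base, cfg)
    base_rasters = _location_rasters(base_tracks, config)

    fuv_sets: dict[float, dict[float, list[float]]] = {
        d: {} for d in config.depths}
    for count in sweep.increments:
        sched = dz.build_release_schedule(1, int(count), config.year_length_days)
        inc_tracks = _run_tracks(series, points, sched, cfg)
        inc_rasters = _location_rasters(inc_tracks, config)
        for (d, pid), r_inc in inc_rasters.items():
            score = sat.fuv(base_rasters[(d, pid)], r_inc,
                            baseline_id=int(sweep.baseline),
                            increment_id=count, replicate_id=pid)
            fuv_sets[d].setdefault(float(count), []).append(score.fuv)
    curves = []
    for d in config.depths:
        incs = sorted(fuv_sets[d])
        x = np.array(incs + [float(sweep.baseline)])
        knots = np.array([np.percentile(fuv_sets[d][i], 95.0) for i in incs])
        env = np.concatenate([knots, [0.0]])  # baseline vs itself: FUV 0
        opt, flag = sat.optimal_from_envelope(x, env, config.fuv_threshold)
        curves.append(sat.SaturationCurve(
            depth=d, increments=x, envelope=env,
            threshold=config.fuv_threshold, optimal=opt, extrapolated=flag,
            parameter="RF", replicates={i: fuv_sets[d][i] for i in incs}))
    return curves


def _tr_test(series, topo, config: SuiteConfig, log):
    """Temporal range: FUV of k-year subsets against the full span."""
    points = []
    for d in config.depths:
        points += _ring_points(topo, d, config.n_points, "TR",
                               clearance_m=config.release_clearance_m)
    cfg = config.tracker_config()
    n_years = config.tr_years
    sched = dz.build_release_schedule(
        n_years, config.releases_per_year, config.year_length_days,
        start_year=config.start_year)
    log(f"[TR] {n_years} years x {config.releases_per_year}/yr: "
        f"{len(points) * len(sched)} tracks")
    tracks = _run_tracks(series, points, sched, cfg)
    yl = config.year_length_days
    year_of = lambda t: int(t.release_day // yl)
    full_rasters = _location_rasters(tracks, config)

    fuv_sets: dict[float, dict[float, list[float]]] = {d: {} for d in config.depths}
    years = list(range(n_years))
    for k in range(1, n_years):
        for combo in dz.year_combinations(years, k):
            sel = set(combo.years)
            sub = _location_rasters(tracks, config,
                                    select=lambda t: year_of(t) in sel)
            for (d, pid), r_sub in sub.items():
                score = sat.fuv(full_rasters[(d, pid)], r_sub,
                                baseline_id=n_years, increment_id=combo.years,
                                replicate_id=pid)
                fuv_sets[d].setdefault(float(k), []).append(score.fuv)
    curves = []
    for d in config.depths:
        ks = sorted(fuv_sets[d])
        x = np.array(ks + [float(n_years)])
        knots = np.array([np.percentile(fuv_sets[d][k], 95.0) for k in ks])
        env = np.concatenate([knots, [0.0]])
        opt, flag = sat.optimal_from_envelope(x, env, config.fuv_threshold)
        curves.append(sat.SaturationCurve(
            depth=d, increments=x, envelope=env,
            threshold=config.fuv_threshold, optimal=opt, extrapolated=flag,
            parameter="TR", replicates={k: fuv_sets[d][k] for k in ks}))
    return curves


_UNITS = {"TS": "hr", "HS": "deg", "VS": "m", "RF": "releases/yr", "TR": "yr"}
_TEST_TYPE = {"TS": "spatial autocorrelation", "HS": "spatial autocorrelation",
              "VS": "spatial autocorrelation", "RF": "model saturation",
              "TR": "model saturation"}
#: dependency order: timestep first, then release frequency, then geometry,
#: then temporal range
_ORDER = ("TS", "RF", "HS", "VS", "TR")


def run_sensitivity_suite(config: SuiteConfig, out_dir=None,
                          log: Callable[[str], None] | None = None,
                          series: ocean.VelocityFieldSeries | None = None,
                          topo: ocean.Topography | None = None) -> SuiteResult:
    """Run the configured sensitivity tests and compile the optima report.

    Tests run in dependency order (TS, RF, HS, VS, TR).  A failing test is
    recorded in ``result.errors`` and the suite continues.  Fully
    deterministic given ``config.seed``.  With ``out_dir``, persists the
    optima table (CSV + Markdown), per-test curves (JSON) and DST summary
    tables (CSV).
    """
    log = log or (lambda msg: None)
    if series is None or topo is None:
        _, topo, series = build_environment(config)
    schedule = dz.build_release_schedule(
        1, config.releases_per_year, config.year_length_days,
        start_year=config.start_year)

    result = SuiteResult(config=config, report=OptimaReport())
    for parameter in _ORDER:
        if parameter not in config.tests:
            continue
        try:
            if parameter in ("TS", "HS", "VS"):
                curves, summaries, _ = _spatial_test(
                    parameter, series, topo, config, schedule, log)
                result.summaries[parameter] = summaries
            elif parameter == "RF":
                curves = _rf_test(series, topo, config, log)
            else:
                curves = _tr_test(series, topo, config, log)
            result.curves[parameter] = curves
            for c in curves:
                result.report.rows.append(OptimaRow(
                    parameter=parameter, test_type=_TEST_TYPE[parameter],
                    depth=c.depth, optimal=float(c.optimal),
                    units=_UNITS[parameter], extrapolated=bool(c.extrapolated)))
        except Exception as exc:  # a failed test must not sink the suite
            result.errors[parameter] = f"{type(exc).__name__}: {exc}"
            log(f"[{parameter}] FAILED: {exc}")

    # back-computation closure: HS optimum (metres at ring latitude) over TS
    # optimum implies a current speed; finite and positive when both exist
    lat_ring = 0.5 * (config.lat_min + config.lat_max)
    for d in config.depths:
        hs = result.report.get("HS", d)
        ts = result.report.get("TS", d)
        if hs and ts and math.isfinite(hs.optimal) and math.isfinite(ts.optimal) \
                and hs.optimal > 0 and ts.optimal > 0 \
                and not (hs.extrapolated or ts.extrapolated):
            dist_m = hs.optimal * M_PER_DEG * math.cos(math.radians(lat_ring))
            result.speed_checks[d] = round_sig(
                implied_speed(dist_m, ts.optimal * 3600.0), 2)

    if out_dir is not None:
        _persist(result, Path(out_dir))
    return result


def _persist(result: SuiteResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    df = result.report.to_dataframe()
    df.to_csv(out_dir / "optima.csv", index=False)
    (out_dir / "optima.md").write_text(result.report.to_markdown() + "\n")
    payload = {"config": result.config.to_dict(),
               "speed_checks_ms": {str(k): v for k, v in result.speed_checks.items()},
               "errors": result.errors, "curves": {}}
    for parameter, curves in result.curves.items():
        payload["curves"][parameter] = [{
            "depth": c.depth,
            "increments": np.asarray(c.increments).tolist(),
            "statistic": np.asarray(getattr(c, "statistics", getattr(c, "envelope", []))).tolist(),
            "threshold": c.threshold, "optimal": c.optimal,
            "extrapolated": bool(c.extrapolated)} for c in curves]
    (out_dir / "curves.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
    rows = []
    for parameter, summaries in result.summaries.items():
        for s in summaries:
            rows.append({"parameter": parameter, "depth": s.depth,
                         "increment": s.increment, "median_km": s.median_km,
                         "q1_km": s.q1_km, "q3_km": s.q3_km, "n": s.n})
    if rows:
        import pandas as pd

        pd.DataFrame(rows).to_csv(out_dir / "dst_summaries.csv", index=False)
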