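"""Spatial-autocorrelation analysis: Distance Separation over Time (DST).

A baseline track and an increment track released together are compared by
their per-day great-circle separation.  Pooling those separations over
replicate release locations, release times and all tracking days gives one
distribution per (depth band, increment); the median against a reference
threshold (default 10 km, a typical larval habitat-detection distance)
defines whether the increment behaves as an independent sample or a
spatially autocorrelated duplicate of its baseline.

A shape-preserving piecewise cubic Hermite interpolant (PCHIP) through the
(increment, median DST) knots, anchored at zero separation for the baseline
increment, is intersected with the threshold to extract the "optimal value":
the smallest increment whose expected separation reaches the threshold.
Sweeps that never reach the threshold inside the tested range are
extrapolated linearly with the end Hermite slope and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator

from ._geo import haversine_km as _haversine_lonlat
from .tracker import Track

__all__ = [
    "DstSeries",
    "DstSummary",
    "SensitivityCurve",
    "haversine_km",
    "dst_series",
    "pool_dst",
    "fit_threshold_crossing",
    "threshold_crossing",
    "dst_by_day",
]


def haversine_km(p1, p2) -> float:
    """Great-circle distance (km) between two (lon, lat) points, R = 6371 km."""
    (lon1, lat1), (lon2, lat2) = p1, p2
    return float(_haversine_lonlat(lon1, lat1, lon2, lat2))


@dataclass
class DstSeries:
    """Per-day separation (km) of one baseline/increment track pair, days 1..PLD."""

    baseline_id: int
    increment_id: int
    distances_km: np.ndarray
    depth: float = np.nan
    increment: float = np.nan

    def __post_init__(self):
        self.distances_km = np.asarray(self.distances_km, dtype=float)
        if np.any(self.distances_km < 0):
            raise ValueError("separations must be non-negative")

    def __len__(self) -> int:
        return len(self.distances_km)


@dataclass(frozen=True)
class DstSummary:
    """Pooled DST distribution for one (depth band, increment)."""

    depth: float
    increment: float
    median_km: float
    q1_km: float
    q3_km: float
    lower_fence_km: float
    upper_fence_km: float
    n: int


@dataclass
class SensitivityCurve:
    """Per-depth (increment, statistic) knots with threshold crossing."""

    depth: float
    increments: np.ndarray
    statistics: np.ndarray
    threshold: float
    optimal: float
    extrapolated: bool
    parameter: str | None = None


def dst_series(baseline: Track, increment: Track) -> DstSeries:
    """Per-day haversine separation of a paired baseline/increment track.

    Both tracks must share their PLD (record count) and release time; frozen
    (beached/escaped) positions enter the comparison as recorded, which keeps
    replicate designs balanced.  Day 0 (the release positions) is excluded;
    the series covers days 1..PLD.
    """
    if len(baseline) != len(increment):
        raise ValueError("baseline and increment tracks differ in length")
    if abs(baseline.release_day - increment.release_day) > 1e-9:
        raise ValueError("baseline and increment tracks differ in release time")
    d = _haversine_lonlat(baseline.lons[1:], baseline.lats[1:],
                          increment.lons[1:], increment.lats[1:])
    return DstSeries(baseline_id=baseline.track_id, increment_id=increment.track_id,
                     distances_km=np.asarray(d, dtype=float),
                     depth=baseline.depth,
                     increment=(increment.meta.get("increment") or np.nan))


def pool_dst(series_set: Sequence[DstSeries], depth: float = np.nan,
             increment: float = np.nan) -> DstSummary:
    """Pool replicate pairs x all tracking days into one DST distribution.

    Reports median, quartiles and Tukey 1.5*IQR fences (the boxplot
    summaries); the pooled sample size is n_pairs * PLD when nothing is
    excluded upstream.
    """
    if len(series_set) == 0:
        raise ValueError("cannot pool an empty set of DST series")
    vals = np.concatenate([s.distances_km for s in series_set])
    q1, med, q3 = np.percentile(vals, [25, 50, 75])
    iqr = q3 - q1
    if np.isnan(depth):
        depths = {s.depth for s in series_set}
        depth = depths.pop() if len(depths) == 1 else np.nan
    if np.isnan(increment):
        incs = {s.increment for s in series_set if not np.isnan(s.increment)}
        increment = incs.pop() if len(incs) == 1 else np.nan
    return DstSummary(depth=float(depth), increment=float(increment),
                      median_km=float(med), q1_km=float(q1), q3_km=float(q3),
                      lower_fence_km=float(q1 - 1.5 * iqr),
                      upper_fence_km=float(q3 + 1.5 * iqr), n=len(vals))


# ---------------------------------------------------------------------------
# threshold crossing on a PCHIP interpolant (shared with the saturation engine)
# ---------------------------------------------------------------------------

def threshold_crossing(x: np.ndarray, y: np.ndarray, threshold: float,
                       direction: str = "up") -> tuple[float, bool]:
    """First crossing of a PCHIP interpolant through (x, y) with a threshold.

    ``direction='up'``: smallest x where the interpolant first reaches
    >= threshold; ``'down'``: where it first drops to <= threshold.  The
    crossing is bracketed on a dense grid (knots included) and refined by
    bisection to a relative tolerance of 1e-6.  If the interpolant never
    crosses inside the knot range, the crossing of the end-slope linear
    extrapolation is returned with the flag set (NaN if the end slope points
    away from the threshold).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 knots")
    if len(np.unique(x)) != len(x):
        raise ValueError("duplicate increments in knots")
    order = np.argsort(x)
    x, y = x[order], y[order]
    interp = PchipInterpolator(x, y, extrapolate=False)
    sgn = 1.0 if direction == "up" else -1.0

    def g(t):  # >= 0 once the threshold is reached
        return sgn * (interp(t) - threshold)

    # dense bracket search, knots included so exact-at-knot hits are found
    dense = np.unique(np.concatenate(
        [np.linspace(x[0], x[-1], 4097), x]))
    gy = sgn * (interp(dense) - threshold)
    hit = np.flatnonzero(gy >= 0)
    if len(hit):
        i = hit[0]
        if i == 0 or gy[i] == 0.0:
            return float(dense[i]), False
        lo, hi = dense[i - 1], dense[i]
        for _ in range(200):  # bisection to relative 1e-6
            mid = 0.5 * (lo + hi)
            if g(mid) >= 0:
                hi = mid
            else:
                lo = mid
            if hi - lo <= 1e-6 * max(abs(hi), 1.0):
                break
        return float(hi), False
    # linear extrapolation with the end Hermite slope
    slope = float(interp.derivative()(x[-1]))
    if sgn * slope > 0:
        est = x[-1] + (threshold - float(y[-1])) / slope
        return float(est), True
    return float("nan"), True


def fit_threshold_crossing(knots: Sequence[tuple[float, float]], threshold: float,
                           anchor: tuple[float, float] | None = None,
                           direction: str = "up") -> tuple[float, bool]:
    """Optimal value from (increment, statistic) knots vs a threshold.

    For DST sweeps pass ``anchor=(baseline_increment, 0.0)``: the baseline
    compared with itself separates by exactly zero, and anchoring stabilises
    the interpolant near the origin.  Returns ``(optimal, extrapolated)``.
    """
    pts = list(knots)
    if anchor is not None and not any(abs(p[0] - anchor[0]) < 1e-12 for p in pts):
        pts = [anchor] + pts
    if len(pts) < 2:
        raise ValueError("need at least 2 knots")
    x = np.array([p[0] for p in pts], dtype=float)
    y = np.array([p[1] for p in pts], dtype=float)
    return threshold_crossing(x, y, threshold, direction=direction)


def dst_by_day(series_set: Sequence[DstSeries], threshold: float = 10.0):
    """Per-day median DST curves and first-independence days, per increment.

    Returns ``(curves, first_day)``: ``curves`` maps increment -> median
    separation array over days 1..PLD (median across replicate pairs), and
    ``first_day`` maps increment -> the first day whose median reaches the
    threshold (None if it never does).  Shows how tracking time (PLD)
    interacts with separation sensitivity.
    """
    groups: dict[float, list[np.ndarray]] = {}
    plds = {len(s) for s in series_set}
    if len(plds) > 1:
        raise ValueError("all DST series must share the same PLD")
    for s in series_set:
        groups.setdefault(float(s.increment), []).append(s.distances_km)
    curves: dict[float, np.ndarray] = {}
    first_day: dict[float, int | None] = {}
    for inc, arrs in sorted(groups.items()):
        med = np.median(np.vstack(arrs), axis=0)
        curves[inc] = med
        idx = np.flatnonzero(med >= threshold)
        first_day[inc] = int(idx[0] + 1) if len(idx) else None
    return curves, first_day
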