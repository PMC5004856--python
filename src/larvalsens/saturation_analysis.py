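"""Model-saturation analysis: track-density rasters and FUV = 1 - r^2.

Release-frequency and temporal-range sweeps cannot be compared track by
track (baseline and increment hold different numbers of tracks), so each
side is compiled into a track-density raster: a grid of 2-D cells, by
default 0.04 degrees (half a typical 0.08-degree hydrodynamic-model
resolution), each counting the number of *distinct* tracks whose polyline
enters it — no track is counted twice per cell, so counts measure pathway
coverage rather than residence time.

The fraction of unexplained variance between a baseline/increment raster
pair is ``FUV = 1 - r^2`` with r the Pearson correlation of cell counts.
Replicate FUVs (one per release location) per increment are summarised by
their 95th percentile; a PCHIP interpolant through those envelope knots,
intersected with a 0.05 FUV threshold, gives the coarsest setting that still
saturates the baseline's predicted dispersal pathways.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator

from .dst_analysis import threshold_crossing
from .tracker import Track

__all__ = [
    "DensityRaster",
    "FuvScore",
    "SaturationCurve",
    "UndefinedCorrelationError",
    "rasterize_tracks",
    "track_cells",
    "fuv",
    "fuv_envelope",
    "optimal_from_envelope",
    "fuv_to_correlation",
    "write_ascii_grid",
]


class UndefinedCorrelationError(ValueError):
    """Pearson correlation undefined (a raster has zero variance)."""


@dataclass
class DensityRaster:
    """Distinct-track counts per cell on a regular lon/lat raster.

    ``lon0``/``lat0`` is the lower-left cell corner; both are integer
    multiples of ``cell_deg`` so rasters built independently align exactly.
    """

    lon0: float
    lat0: float
    cell_deg: float
    counts: np.ndarray  # (ny, nx) int

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if np.any(self.counts < 0):
            raise ValueError("track counts must be non-negative")

    @property
    def shape(self):
        return self.counts.shape


@dataclass(frozen=True)
class FuvScore:
    baseline_id: object
    increment_id: object
    replicate_id: object
    r: float
    fuv: float


@dataclass
class SaturationCurve:
    """Per-depth FUV replicate sets with 95 %-envelope threshold crossing."""

    depth: float
    increments: np.ndarray
    envelope: np.ndarray
    threshold: float
    optimal: float
    extrapolated: bool
    parameter: str | None = None
    replicates: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# rasterization: exact segment-grid traversal
# ---------------------------------------------------------------------------

def _segment_cells(x0, y0, x1, y1, mark):
    """Mark every cell a segment passes through (coords in cell units).

    Amanatides-Woo grid marching: exact traversal, so daily positions that
    jump across a cell still credit the cells the straight path crosses.
    """
    ny, nx = mark.shape
    i, j = int(np.floor(x0)), int(np.floor(y0))
    i1, j1 = int(np.floor(x1)), int(np.floor(y1))
    dx, dy = x1 - x0, y1 - y0
    step_i = 1 if dx > 0 else -1
    step_j = 1 if dy > 0 else -1
    t_max_x = ((i + (step_i > 0)) - x0) / dx if dx != 0 else np.inf
    t_max_y = ((j + (step_j > 0)) - y0) / dy if dy != 0 else np.inf
    t_dx = abs(1.0 / dx) if dx != 0 else np.inf
    t_dy = abs(1.0 / dy) if dy != 0 else np.inf
    for _ in range(abs(i1 - i) + abs(j1 - j) + 1):
        if 0 <= j < ny and 0 <= i < nx:
            mark[j, i] = True
        if i == i1 and j == j1:
            return
        if t_max_x < t_max_y:
            i += step_i
            t_max_x += t_dx
        else:
            j += step_j
            t_max_y += t_dy
    if 0 <= j1 < ny and 0 <= i1 < nx:
        mark[j1, i1] = True


def track_cells(track: Track, lon0: float, lat0: float, cell_deg: float,
                shape: tuple[int, int]) -> np.ndarray:
    """Boolean indicator of the cells a track's daily polyline enters."""
    mark = np.zeros(shape, dtype=bool)
    xs = (track.lons - lon0) / cell_deg
    ys = (track.lats - lat0) / cell_deg
    for k in range(len(xs) - 1):
        _segment_cells(xs[k], ys[k], xs[k + 1], ys[k + 1], mark)
    if len(xs) == 1:
        _segment_cells(xs[0], ys[0], xs[0], ys[0], mark)
    return mark


def rasterize_tracks(tracks: Sequence[Track], cell_deg: float = 0.04,
                     extent: tuple[float, float, float, float] | None = None
                     ) -> DensityRaster:
    """Compile tracks into a track-density raster.

    Each track's daily positions form a polyline; every cell the polyline
    enters gets that track's indicator once (loops through a visited cell do
    not double-count).  With ``extent=None`` the raster covers all positions,
    corners snapped to multiples of ``cell_deg`` so independently built
    rasters align; an explicit extent ``(lon_min, lon_max, lat_min, lat_max)``
    is expanded the same way if positions fall outside it.
    """
    if cell_deg <= 0:
        raise ValueError("cell size must be positive")
    if len(tracks) == 0:
        if extent is None:
            return DensityRaster(0.0, 0.0, cell_deg, np.zeros((1, 1), dtype=int))
        lon_min, lon_max, lat_min, lat_max = extent
    else:
        lon_lo = min(t.lons.min() for t in tracks)
        lon_hi = max(t.lons.max() for t in tracks)
        lat_lo = min(t.lats.min() for t in tracks)
        lat_hi = max(t.lats.max() for t in tracks)
        if extent is None:
            lon_min, lon_max, lat_min, lat_max = lon_lo, lon_hi, lat_lo, lat_hi
        else:
            lon_min = min(extent[0], lon_lo)
            lon_max = max(extent[1], lon_hi)
            lat_min = min(extent[2], lat_lo)
            lat_max = max(extent[3], lat_hi)
    lon0 = np.floor(lon_min / cell_deg) * cell_deg
    lat0 = np.floor(lat_min / cell_deg) * cell_deg
    nx = max(int(np.floor(lon_max / cell_deg)) - int(np.floor(lon_min / cell_deg)) + 1, 1)
    ny = max(int(np.floor(lat_max / cell_deg)) - int(np.floor(lat_min / cell_deg)) + 1, 1)
    counts = np.zeros((ny, nx), dtype=int)
    for tr in tracks:
        counts += track_cells(tr, lon0, lat0, cell_deg, (ny, nx))
    return DensityRaster(lon0=float(lon0), lat0=float(lat0),
                         cell_deg=cell_deg, counts=counts)


def _align(a: DensityRaster, b: DensityRaster):
    """Pad two rasters onto their union grid (requires equal cell size)."""
    if abs(a.cell_deg - b.cell_deg) > 1e-12:
        raise ValueError("rasters have different cell sizes")
    cell = a.cell_deg
    ia = (round(a.lon0 / cell), round(a.lat0 / cell))
    ib = (round(b.lon0 / cell), round(b.lat0 / cell))
    i0 = min(ia[0], ib[0])
    j0 = min(ia[1], ib[1])
    nx = max(ia[0] + a.shape[1], ib[0] + b.shape[1]) - i0
    ny = max(ia[1] + a.shape[0], ib[1] + b.shape[0]) - j0
    out = []
    for r, (ri, rj) in ((a, ia), (b, ib)):
        c = np.zeros((ny, nx), dtype=float)
        c[rj - j0: rj - j0 + r.shape[0], ri - i0: ri - i0 + r.shape[1]] = r.counts
        out.append(c)
    return out[0], out[1]


def fuv(a: DensityRaster, b: DensityRaster,
        baseline_id=None, increment_id=None, replicate_id=None) -> FuvScore:
    """FUV = 1 - r^2 between two track-density rasters.

    r is the Pearson correlation of cell counts over the cells that are
    nonzero in at least one raster (jointly empty cells depend only on the
    arbitrary raster extent and would inflate r).  Identical or affinely
    rescaled rasters give r = 1, FUV = 0; a zero-variance raster raises
    :class:`UndefinedCorrelationError`.  r is reported alongside so
    anti-correlation stays detectable.
    """
    ca, cb = _align(a, b)
    sel = (ca != 0) | (cb != 0)
    xa, xb = ca[sel], cb[sel]
    if len(xa) < 2 or np.std(xa) == 0 or np.std(xb) == 0:
        raise UndefinedCorrelationError(
            "Pearson correlation undefined: a raster has zero variance over "
            "the occupied cells")
    r = float(np.corrcoef(xa, xb)[0, 1])
    return FuvScore(baseline_id=baseline_id, increment_id=increment_id,
                    replicate_id=replicate_id, r=r, fuv=1.0 - r * r)


# ---------------------------------------------------------------------------
# envelope and optimum
# ---------------------------------------------------------------------------

def fuv_envelope(increments: Sequence[float],
                 fuv_sets: Sequence[Sequence[float]]):
    """95th-percentile FUV envelope per increment, with PCHIP interpolant.

    Percentiles use linear interpolation between order statistics.  Returns
    ``(knots, interpolant)`` where ``knots[i]`` is the envelope value at
    ``increments[i]``; fitting so that 95 % of replicate FUVs fall below the
    line makes the crossing account for replicate spread, not just the mean.
    """
    if len(increments) != len(fuv_sets):
        raise ValueError("one replicate set per increment is required")
    if any(len(s) == 0 for s in fuv_sets):
        raise ValueError("each increment needs at least one replicate FUV")
    x = np.asarray(increments, dtype=float)
    knots = np.array([np.percentile(np.asarray(s, dtype=float), 95.0,
                                    method="linear") for s in fuv_sets])
    order = np.argsort(x)
    return knots, PchipInterpolator(x[order], knots[order], extrapolate=False)


def optimal_from_envelope(increments: Sequence[float],
                          envelope: Sequence[float],
                          threshold: float = 0.05) -> tuple[float, bool]:
    """Coarsest setting whose FUV envelope drops to the saturation threshold.

    FUV decreases toward the baseline resolution, so this is a down-crossing:
    the smallest increment at which the envelope first reaches <= threshold.
    If every knot is already below the threshold the smallest increment is
    returned; if the envelope never reaches it, an end-slope extrapolation
    estimate is returned with the flag set.
    """
    x = np.asarray(increments, dtype=float)
    y = np.asarray(envelope, dtype=float)
    order = np.argsort(x)
    x, y = x[order], y[order]
    if y[0] <= threshold:
        return float(x[0]), False
    return threshold_crossing(x, y, threshold, direction="down")


def fuv_to_correlation(value: float) -> float:
    """Back-compute the Pearson correlation implied by an FUV: r = sqrt(1 - FUV)."""
    if not 0.0 <= value <= 1.0:
        raise ValueError("FUV must lie in [0, 1]")
    return float(np.sqrt(1.0 - value))


def write_raster_netcdf(raster: DensityRaster, path) -> None:
    """Export a density raster as a 2-D netCDF grid (cell-centre coords)."""
    import xarray as xr

    ny, nx = raster.shape
    lons = raster.lon0 + raster.cell_deg * (np.arange(nx) + 0.5)
    lats = raster.lat0 + raster.cell_deg * (np.arange(ny) + 0.5)
    xr.Dataset(
        {"track_count": (("lat", "lon"), raster.counts,
                         {"long_name": "distinct tracks per cell"})},
        coords={"lon": lons, "lat": lats},
        attrs={"cell_deg": raster.cell_deg},
    ).to_netcdf(path, engine="scipy")


def write_ascii_grid(raster: DensityRaster, path) -> None:
    """Export a density raster as an ESRI ASCII grid."""
    ny, nx = raster.shape
    header = (f"ncols {nx}\nnrows {ny}\nxllcorner {raster.lon0}\n"
              f"yllcorner {raster.lat0}\ncellsize {raster.cell_deg}\n"
              f"NODATA_value -9999\n")
    rows = "\n".join(" ".join(str(int(v)) for v in row)
                     for row in raster.counts[::-1])
    with open(path, "w") as fh:
        fh.write(header + rows + "\n")
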