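"""Optional matplotlib views of sensitivity and saturation results."""

from __future__ import annotations

import numpy as np


def plot_sensitivity_curves(curves, ax=None):
    """Median DST vs increment per depth band, with the threshold line."""
    import matplotlib.pyplot as plt
    from scipy.interpolate import PchipInterpolator

    if ax is None:
        _, ax = plt.subplots()
    for c in curves:
        xs = np.linspace(c.increments.min(), c.increments.max(), 200)
        interp = PchipInterpolator(c.increments, c.statistics)
        ax.plot(xs, interp(xs), label=f"{c.depth:g} m")
        ax.plot(c.increments, c.statistics, "o", ms=4,
                color=ax.lines[-1].get_color())
    if curves:
        ax.axhline(curves[0].threshold, color="k", ls="--", lw=1,
                   label=f"{curves[0].threshold:g} km threshold")
        ax.set_xlabel(f"{curves[0].parameter} increment")
    ax.set_ylabel("median DST (km)")
    ax.legend(fontsize=8)
    return ax


def plot_saturation_curves(curves, ax=None):
    """Replicate FUVs, 95 % envelope and saturation threshold per depth."""
    import matplotlib.pyplot as plt
    from scipy.interpolate import PchipInterpolator

    if ax is None:
        _, ax = plt.subplots()
    for c in curves:
        for inc, vals in c.replicates.items():
            ax.plot([inc] * len(vals), vals, ".", ms=3, alpha=0.4,
                    color=f"C{int(c.depth) % 10}")
        interp = PchipInterpolator(c.increments, c.envelope)
        xs = np.linspace(c.increments.min(), c.increments.max(), 200)
        ax.plot(xs, interp(xs), label=f"{c.depth:g} m envelope")
    if curves:
        ax.axhline(curves[0].threshold, color="k", ls="--", lw=1)
        ax.set_xlabel(f"{curves[0].parameter} increment")
    ax.set_ylabel("FUV = 1 - r$^2$")
    ax.legend(fontsize=8)
    return ax


def plot_track_density(raster, ax=None):
    """Track-density raster as an image with geographic extent."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ny, nx = raster.shape
    extent = (raster.lon0, raster.lon0 + nx * raster.cell_deg,
              raster.lat0, raster.lat0 + ny * raster.cell_deg)
    im = ax.imshow(raster.counts, origin="lower", extent=extent, aspect="auto",
                   cmap="viridis")
    plt.colorbar(im, ax=ax, label="distinct tracks per cell")
    ax.set_xlabel("longitude")
    ax.set_ylabel("latitude")
    return ax
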