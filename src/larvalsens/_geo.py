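"""Spherical-earth helpers shared across modules.

All distances use a spherical earth of radius 6371.0 km, the convention the
rest of the toolkit (tracker metric conversion, haversine separations,
along-contour offsets) is defined against.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0
#: metres per degree of latitude (and of longitude at the equator)
M_PER_DEG = np.pi * EARTH_RADIUS_KM * 1000.0 / 180.0


def haversine_km(lon1, lat1, lon2, lat2, radius_km: float = EARTH_RADIUS_KM):
    """Great-circle distance in km between (lon1, lat1) and (lon2, lat2).

    Inputs in decimal degrees; accepts scalars or broadcastable arrays.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * radius_km * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def destination(lon: float, lat: float, bearing_deg: float, distance_km: float,
                radius_km: float = EARTH_RADIUS_KM):
    """Point reached from (lon, lat) on a great circle.

    ``bearing_deg`` is clockwise from north; returns (lon, lat) in degrees.
    """
    d = distance_km / radius_km
    b = np.radians(bearing_deg)
    phi1 = np.radians(lat)
    lam1 = np.radians(lon)
    phi2 = np.arcsin(np.sin(phi1) * np.cos(d) + np.cos(phi1) * np.sin(d) * np.cos(b))
    lam2 = lam1 + np.arctan2(np.sin(b) * np.sin(d) * np.cos(phi1),
                             np.cos(d) - np.sin(phi1) * np.sin(phi2))
    return np.degrees(lam2), np.degrees(phi2)


def azimuth_deg(lon1: float, lat1: float, lon2: float, lat2: float):
    """Initial great-circle bearing from point 1 to point 2, clockwise from north."""
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dlam = np.radians(lon2 - lon1)
    x = np.sin(dlam) * np.cos(phi2)
    y = np.cos(phi1) * np.sin(phi2) - np.sin(phi1) * np.cos(phi2) * np.cos(dlam)
    return np.degrees(np.arctan2(x, y))


def local_xy_km(lon, lat, lon0: float, lat0: float):
    """Project (lon, lat) to local tangent-plane km offsets about (lon0, lat0).

    Equirectangular with the cosine factor frozen at lat0; adequate for the
    few-degree domains this toolkit works in.
    """
    kx = M_PER_DEG / 1000.0
    x = (np.asarray(lon, dtype=float) - lon0) * kx * np.cos(np.radians(lat0))
    y = (np.asarray(lat, dtype=float) - lat0) * kx
    return x, y
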