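"""Local planar coordinates for study-area-scale geometry.

All kinematics and raster math in this package run in a local east/north
meter frame anchored at a reference lon/lat.  Conversion to and from
geographic coordinates uses an equirectangular approximation, which is
accurate to well under a meter over the tens-of-kilometers extents these
analyses cover; geodesic precision is deliberately out of scope.
"""

from __future__ import annotations

import numpy as np

#: meters per degree of latitude (spherical Earth, mean radius)
M_PER_DEG_LAT = 111_320.0


def lonlat_to_local(lon, lat, ref_lon: float, ref_lat: float):
    """Project lon/lat (degrees) to east/north meters about a reference point."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    x = (lon - ref_lon) * M_PER_DEG_LAT * np.cos(np.radians(ref_lat))
    y = (lat - ref_lat) * M_PER_DEG_LAT
    return x, y


def local_to_lonlat(x, y, ref_lon: float, ref_lat: float):
    """Inverse of :func:`lonlat_to_local`."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    lon = ref_lon + x / (M_PER_DEG_LAT * np.cos(np.radians(ref_lat)))
    lat = ref_lat + y / M_PER_DEG_LAT
    return lon, lat


def bearing_deg(dx, dy):
    """Compass bearing (degrees clockwise from north) of displacement (east, north)."""
    return np.degrees(np.arctan2(dx, dy)) % 360.0
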