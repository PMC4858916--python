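"""Small geodesy and grid helpers shared across the pipeline."""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_M = 6_371_000.0


def haversine_m(lat1, lon1, lat2, lon2):
    """Great-circle distance in metres between WGS84 points (vectorised)."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(a, dtype=float)) for a in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def offset_latlon(lat, lon, east_m, north_m):
    """Displace a WGS84 point by metric offsets using a local equirectangular frame.

    Adequate at neighbourhood scale (km); error is O((d/R)^2).
    """
    lat = np.asarray(lat, dtype=float)
    dlat = np.asarray(north_m, dtype=float) / EARTH_RADIUS_M
    dlon = np.asarray(east_m, dtype=float) / (EARTH_RADIUS_M * np.cos(np.radians(lat)))
    return lat + np.degrees(dlat), np.asarray(lon, dtype=float) + np.degrees(dlon)


def floor_to_grid(timestamps, epoch_s: int):
    """Floor pandas datetime values to the epoch grid (epoch-start convention)."""
    import pandas as pd

    ts = pd.to_datetime(timestamps)
    return ts.dt.floor(f"{epoch_s}s") if hasattr(ts, "dt") else ts.floor(f"{epoch_s}s")
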