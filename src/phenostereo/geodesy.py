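"""Great-circle baseline lengths between RTK-GNSS shooting positions.

The stereo baseline of the airborne pair is not a fixed rig parameter: it is
the distance between the two camera centres at the moments of exposure,
recovered from the RTK-GNSS fix geotagged to each shot.  Fixes are
latitude/longitude in decimal degrees; separations are a metre or two, so a
spherical Earth model is entirely adequate (the haversine error against an
ellipsoid is parts in 10^3 of the distance, i.e. micrometres here).

The distance between fixes 1 and 2 uses the half-angle (haversine) form

    b = 2 r asin( sqrt( sin^2((La1-La2)/2)
                        + cos(La1) cos(La2) sin^2((Lo1-Lo2)/2) ) )

with ``r`` the Earth radius.  ``asin`` is the numerically correct inverse for
the half-angle argument: it is exact at zero separation and well-conditioned
for the centimetre-to-metre separations of a shooting sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EARTH_RADIUS_M",
    "GeoPosition",
    "EarthModel",
    "baseline_length",
    "pairwise_baselines",
    "read_gnss_log",
]

#: Mean Earth radius in metres, fixed for a whole run.
EARTH_RADIUS_M = 6_371_000.0


@dataclass(frozen=True)
class GeoPosition:
    """A single RTK-GNSS fix tied to one shot of the shooting sequence."""

    sequence_index: int
    latitude: float
    longitude: float
    timestamp: float | None = None

    def __post_init__(self) -> None:
        if self.sequence_index < 1:
            raise ValueError(f"sequence_index must be positive, got {self.sequence_index}")
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude {self.latitude} outside [-90, 90] degrees")
        if not -180.0 < self.longitude <= 180.0:
            raise ValueError(f"longitude {self.longitude} outside (-180, 180] degrees")


@dataclass(frozen=True)
class EarthModel:
    """Spherical Earth of fixed radius (metres)."""

    radius: float = EARTH_RADIUS_M

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError(f"Earth radius must be positive, got {self.radius}")


def baseline_length(p1: GeoPosition, p2: GeoPosition, earth: EarthModel = EarthModel()) -> float:
    """Great-circle distance in metres between two GNSS fixes (the baseline).

    Symmetric in its arguments and exactly zero for coincident fixes.
    """
    la1, lo1 = np.deg2rad(p1.latitude), np.deg2rad(p1.longitude)
    la2, lo2 = np.deg2rad(p2.latitude), np.deg2rad(p2.longitude)
    la3 = (la1 - la2) / 2.0
    lo3 = (lo1 - lo2) / 2.0
    h = np.sin(la3) ** 2 + np.cos(la1) * np.cos(la2) * np.sin(lo3) ** 2
    # clip guards rounding for antipodal points
    return float(2.0 * earth.radius * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0))))


def pairwise_baselines(
    track: Sequence[GeoPosition], earth: EarthModel = EarthModel()
) -> np.ndarray:
    """Symmetric matrix of baseline lengths (metres) between all fixes of a track.

    Entry ``(i, j)`` is ``baseline_length(track[i], track[j])``; the diagonal
    is zero.  Needs at least two fixes.
    """
    if len(track) < 2:
        raise ValueError(f"need at least 2 positions, got {len(track)}")
    n = len(track)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = baseline_length(track[i], track[j], earth)
    return out


def read_gnss_log(path: str | Path) -> list[GeoPosition]:
    """Read a GNSS shooting log.

    CSV with header ``sequence,latitude,longitude[,timestamp]``, decimal
    degrees, one row per shot.
    """
    df = pd.read_csv(path)
    required = {"sequence", "latitude", "longitude"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"GNSS log missing columns: {sorted(missing)}")
    has_ts = "timestamp" in df.columns
    track = [
        GeoPosition(
            sequence_index=int(row.sequence),
            latitude=float(row.latitude),
            longitude=float(row.longitude),
            timestamp=float(row.timestamp) if has_ts else None,
        )
        for row in df.itertuples(index=False)
    ]
    seen = [p.sequence_index for p in track]
    if len(set(seen)) != len(seen):
        raise ValueError("duplicate sequence indices in GNSS log")
    return track
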