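"""Sand-darkness scoring and beach geometry.

Beach sand colour is an inverse proxy for albedo: dark (volcanic) sand
absorbs more solar radiation and incubates nests at higher temperature
than light (biogenic) sand.  Each beach is scored from a small pixel
block sampled at the centre of the beach in a satellite image, together
with the lightest and darkest zones of the same image, which anchor a
standardized darkness index in [0, 1] (0 = white endpoint, 1 = black
endpoint).  Per-image standardization corrects for illumination and
cloud cover differences between images.

Geometry helpers (haversine distance, beach midpoint, nearest-volcano
distance) support the spatial analyses: beach length from its two
endpoints, and the distance from each beach to the closest Holocene
volcano, which is expected to predict sand darkness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

EARTH_RADIUS_KM = 6371.0

__all__ = [
    "EARTH_RADIUS_KM",
    "BeachRecord",
    "VolcanoRecord",
    "modal_rgb",
    "darkness_index",
    "haversine_km",
    "beach_midpoint",
    "nearest_volcano_km",
]


def _check_latlon(lat: float, lon: float) -> None:
    if not (-90.0 <= lat <= 90.0) or not (-180.0 <= lon <= 180.0):
        raise ValueError(f"coordinates out of range: lat={lat}, lon={lon}")


@dataclass(frozen=True)
class BeachRecord:
    """One beach: endpoint coordinates, darkness index, length.

    ``darkness`` lies in [0, 1]; ``length_km`` defaults to the haversine
    distance between the two endpoints when not given.
    """

    id: str
    lat1: float
    lon1: float
    lat2: float
    lon2: float
    darkness: float
    length_km: float | None = None
    image_date: str | None = None

    def __post_init__(self) -> None:
        _check_latlon(self.lat1, self.lon1)
        _check_latlon(self.lat2, self.lon2)
        if not (0.0 <= self.darkness <= 1.0):
            raise ValueError(f"darkness must be in [0,1], got {self.darkness}")
        if self.length_km is None:
            object.__setattr__(
                self,
                "length_km",
                haversine_km(self.lat1, self.lon1, self.lat2, self.lon2),
            )
        elif self.length_km < 0:
            raise ValueError("length_km must be >= 0")

    @property
    def midpoint(self) -> tuple[float, float]:
        return beach_midpoint(self)


@dataclass(frozen=True)
class VolcanoRecord:
    name: str
    lat: float
    lon: float

    def __post_init__(self) -> None:
        _check_latlon(self.lat, self.lon)


def _as_pixel_array(block) -> np.ndarray:
    arr = np.asarray(block)
    if arr.size == 0:
        raise ValueError("pixel block is empty")
    if arr.ndim == 2 and arr.shape[1] == 3:
        arr = arr[None, :, :]
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(
            f"expected an (h, w, 3) RGB array, got shape {arr.shape}"
        )
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("RGB channel values must lie in [0, 255]")
    return arr.astype(np.int64, copy=False)


def modal_rgb(block) -> tuple[int, int, int]:
    """Per-channel histogram mode of a rectangular RGB pixel block.

    Each of R, G, B is reduced independently to its most frequent value
    over all pixels, emulating per-channel colour histograms.  Ties are
    broken toward the smaller (darker) channel value, deterministically.
    """
    arr = _as_pixel_array(block)
    flat = arr.reshape(-1, 3)
    mode = []
    for c in range(3):
        counts = np.bincount(flat[:, c], minlength=256)
        mode.append(int(counts.argmax()))  # argmax takes the first (smallest) tie
    return tuple(mode)


def darkness_index(
    center: Sequence[float],
    lightest: Sequence[float],
    darkest: Sequence[float],
) -> float:
    """Standardized sand darkness in [0, 1] from three RGB colours.

    With D_light and D_dark the Euclidean RGB distances from the beach
    centre colour to the image's lightest and darkest endpoint colours,

        d = D_light / (D_light + D_dark)

    so d = 0 at the white endpoint and d = 1 at the black endpoint.
    Raises if the two endpoints coincide (no colour range to scale by).
    """
    c = np.asarray(center, dtype=float)
    li = np.asarray(lightest, dtype=float)
    da = np.asarray(darkest, dtype=float)
    if c.shape != (3,) or li.shape != (3,) or da.shape != (3,):
        raise ValueError("center, lightest, darkest must each be RGB triples")
    if np.array_equal(li, da):
        raise ValueError("degenerate endpoints: lightest equals darkest")
    d_light = float(np.linalg.norm(c - li))
    d_dark = float(np.linalg.norm(c - da))
    return d_light / (d_light + d_dark)


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in km on a sphere of radius 6371 km."""
    _check_latlon(lat1, lon1)
    _check_latlon(lat2, lon2)
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlam = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2.0) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(a)))


def beach_midpoint(beach: BeachRecord) -> tuple[float, float]:
    """Arithmetic midpoint of the beach endpoints in degrees.

    Adequate at the regional scale of a Central American coastline; no
    antimeridian handling.
    """
    return (
        0.5 * (beach.lat1 + beach.lat2),
        0.5 * (beach.lon1 + beach.lon2),
    )


def nearest_volcano_km(
    beach: BeachRecord, volcanos: Sequence[VolcanoRecord]
) -> float:
    """Minimum haversine distance from the beach midpoint to any volcano."""
    if len(volcanos) == 0:
        raise ValueError("volcano list is empty")
    lat, lon = beach_midpoint(beach)
    return min(haversine_km(lat, lon, v.lat, v.lon) for v in volcanos)
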