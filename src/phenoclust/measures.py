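"""Distances for modalities that map to real-world measurements.

Some qualitative trait variables have modalities that denote measurable
things rather than abstract categories: petal colours (points in the
CIE L*a*b* space), regions of origin (geographic coordinates) and breeding
periods (year intervals).  For these, the distance between two modalities
is computed from what the modalities *represent* instead of being read off
an expert-annotated ontology:

* colours    -> colour difference ΔE between L*a*b* coordinates,
* regions    -> great-circle distance between representative points,
* periods    -> years between interval midpoints.

The labels are resolved through offline lookup tables (plain CSV) so that
no network access is ever required.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.color import deltaE_ciede2000

EARTH_RADIUS_KM = 6371.0


@dataclass(frozen=True)
class LabColor:
    """A colour in CIE L*a*b* coordinates.

    L is perceptual lightness (0-100), a the green-red opponent axis and
    b the blue-yellow opponent axis.
    """

    L: float
    a: float
    b: float

    def __post_init__(self) -> None:
        for field in ("L", "a", "b"):
            v = getattr(self, field)
            if not math.isfinite(v):
                raise ValueError(f"LabColor.{field} must be finite, got {v!r}")


@dataclass(frozen=True)
class GeoPoint:
    """A point on the globe in decimal degrees."""

    lat: float
    lon: float

    def __post_init__(self) -> None:
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"latitude {self.lat} outside [-90, 90]")
        if not -180.0 < self.lon <= 180.0:
            raise ValueError(f"longitude {self.lon} outside (-180, 180]")


@dataclass(frozen=True)
class TimePeriod:
    """A labelled year interval [start, end].

    Open-ended labels (e.g. "<1700") must already be resolved to explicit
    bounds in the lookup table; the bounds are data, not code.
    """

    label: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"period {self.label!r}: start {self.start} > end {self.end}"
            )

    @property
    def midpoint(self) -> float:
        return self.start + (self.end - self.start) / 2


def delta_e(c1: LabColor, c2: LabColor, method: str = "euclidean") -> float:
    """Perceptual colour difference between two L*a*b* colours.

    ``euclidean`` is the plain Euclidean distance in L*a*b* space
    (the CIE76 formula); ``ciede2000`` is the CIEDE2000 revision, which
    better matches perception but is not a metric (no triangle inequality).
    """
    if method == "euclidean":
        return math.sqrt(
            (c2.L - c1.L) ** 2 + (c2.a - c1.a) ** 2 + (c2.b - c1.b) ** 2
        )
    if method == "ciede2000":
        return float(
            deltaE_ciede2000(
                np.array([c1.L, c1.a, c1.b], dtype=float),
                np.array([c2.L, c2.a, c2.b], dtype=float),
            )
        )
    raise ValueError(f"unknown delta_e method {method!r}")


def period_distance(p1: TimePeriod, p2: TimePeriod) -> int:
    """Whole years between the midpoints of two periods (floored)."""
    return int(math.floor(abs(p1.midpoint - p2.midpoint)))


def geo_distance(g1: GeoPoint, g2: GeoPoint) -> float:
    """Great-circle (haversine) distance in kilometres, sphere R=6371 km."""
    lat1, lon1, lat2, lon2 = map(
        math.radians, (g1.lat, g1.lon, g2.lat, g2.lon)
    )
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = math.sin(dlat / 2) ** 2 + math.cos(lat1) * math.cos(lat2) * math.sin(
        dlon / 2
    ) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))


def composite_region_location(points: list[GeoPoint]) -> GeoPoint:
    """Represent a composite region by the mean of its sub-areas' coordinates.

    Longitudes are averaged arithmetically, which is adequate away from the
    antimeridian; regions straddling ±180° are not handled.
    """
    if not points:
        raise ValueError("composite region needs at least one sub-area point")
    return GeoPoint(
        lat=sum(p.lat for p in points) / len(points),
        lon=sum(p.lon for p in points) / len(points),
    )


def _parse_float(row_label: str, field: str, raw: str) -> float:
    try:
        return float(raw)
    except ValueError:
        raise ValueError(
            f"lookup row {row_label!r}: malformed numeric {field}={raw!r}"
        ) from None


def read_lookup_table(path: str | Path, kind: str) -> dict:
    """Read an offline label -> measurement lookup table.

    Expected CSV headers:

    * ``colour``: ``label,L,a,b``
    * ``geo``:    ``label,lat,lon`` with an optional ``areas`` column; a row
      whose ``areas`` field is non-empty lists semicolon-separated sub-area
      labels and is resolved to their mean coordinates
      (:func:`composite_region_location`); sub-areas may themselves be
      composite.
    * ``period``: ``label,start,end`` (integer years)
    """
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.DictReader(fh))

    if kind == "colour":
        return {
            r["label"]: LabColor(
                _parse_float(r["label"], "L", r["L"]),
                _parse_float(r["label"], "a", r["a"]),
                _parse_float(r["label"], "b", r["b"]),
            )
            for r in rows
        }

    if kind == "period":
        out = {}
        for r in rows:
            start = int(_parse_float(r["label"], "start", r["start"]))
            end = int(_parse_float(r["label"], "end", r["end"]))
            out[r["label"]] = TimePeriod(r["label"], start, end)
        return out

    if kind == "geo":
        plain: dict[str, GeoPoint] = {}
        composite: dict[str, list[str]] = {}
        for r in rows:
            areas = (r.get("areas") or "").strip()
            if areas:
                composite[r["label"]] = [
                    a.strip() for a in areas.split(";") if a.strip()
                ]
            else:
                plain[r["label"]] = GeoPoint(
                    _parse_float(r["label"], "lat", r["lat"]),
                    _parse_float(r["label"], "lon", r["lon"]),
                )

        def resolve(label: str, seen: tuple[str, ...]) -> GeoPoint:
            if label in plain:
                return plain[label]
            if label in composite:
                if label in seen:
                    raise ValueError(
                        f"circular composite region definition at {label!r}"
                    )
                pts = [resolve(a, seen + (label,)) for a in composite[label]]
                return composite_region_location(pts)
            raise ValueError(
                f"geo lookup: unresolvable sub-area label {label!r}"
            )

        out = dict(plain)
        for label in composite:
            out[label] = resolve(label, ())
        return out

    raise ValueError(f"unknown lookup kind {kind!r}")
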