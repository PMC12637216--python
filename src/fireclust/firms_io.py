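"""Read and write FIRMS-dialect active-fire CSV tables and base-site tables.

The column dialect follows the public FIRMS archive export:

    latitude, longitude, brightness, scan, track, acq_date, acq_time,
    satellite, instrument, confidence, version, bright_t31, frp, daynight

``brightness``, ``version`` and ``bright_t31`` are parsed and carried along
so a file round-trips, but the analysis never uses them. Rows that violate
the record invariants (coordinates, confidence, FRP, pixel dimensions) are
rejected individually with a logged reason; a bad row never aborts a read.

VIIRS archive files report categorical confidence (l/n/h); these are mapped
to the numeric class midpoints 15/55/90 so a single 0-100 field serves both
instruments.
"""

from __future__ import annotations

import csv
import datetime as _dt
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd

from .geodesy import GeoPoint, medoid

__all__ = [
    "FireDetection",
    "BaseSite",
    "FirmsFormatError",
    "FirmsReadResult",
    "FIRMS_COLUMNS",
    "confidence_class",
    "read_firms_csv",
    "write_firms_csv",
    "read_bases_csv",
    "write_bases_csv",
    "filter_detections",
    "links_to_frame",
    "write_links_csv",
    "read_links_csv",
    "write_clusters_geojson",
]

log = logging.getLogger(__name__)

FIRMS_COLUMNS = [
    "latitude",
    "longitude",
    "brightness",
    "scan",
    "track",
    "acq_date",
    "acq_time",
    "satellite",
    "instrument",
    "confidence",
    "version",
    "bright_t31",
    "frp",
    "daynight",
]

SATELLITES = ("Terra", "Aqua", "SNPP")
INSTRUMENTS = ("MODIS", "VIIRS")

#: VIIRS categorical confidence -> numeric class midpoints of the 0-30/30-80/80-100 bands.
VIIRS_CONFIDENCE_MAP = {"l": 15, "n": 55, "h": 90}


class FirmsFormatError(ValueError):
    """A file-level format problem (missing column, duplicate base id)."""


@dataclass(frozen=True)
class FireDetection:
    """One satellite active-fire record.

    ``frp`` is the fire radiative power in megawatts; ``confidence`` is the
    0-100 detection-quality score; ``scan``/``track`` are the pixel
    dimensions in km at the detection location.
    """

    lat: float
    lon: float
    acq_date: _dt.date
    acq_time: str  # UTC "HHMM"
    satellite: str
    instrument: str
    confidence: int
    frp: float
    scan: float
    track: float
    daynight: str
    brightness: float | None = None
    version: str | None = None
    bright_t31: float | None = None

    @property
    def point(self) -> GeoPoint:
        return GeoPoint(self.lat, self.lon)

    def validate(self) -> None:
        if not (-90.0 <= self.lat <= 90.0):
            raise ValueError(f"latitude out of range: {self.lat}")
        if not (-180.0 <= self.lon <= 180.0):
            raise ValueError(f"longitude out of range: {self.lon}")
        if not (0 <= self.confidence <= 100):
            raise ValueError(f"confidence out of range: {self.confidence}")
        if self.frp < 0:
            raise ValueError(f"negative FRP: {self.frp}")
        if self.scan <= 0 or self.track <= 0:
            raise ValueError(f"non-positive pixel size: scan={self.scan} track={self.track}")
        if self.satellite not in SATELLITES:
            raise ValueError(f"unknown satellite: {self.satellite}")
        if self.instrument not in INSTRUMENTS:
            raise ValueError(f"unknown instrument: {self.instrument}")
        if self.daynight not in ("D", "N"):
            raise ValueError(f"daynight must be D or N: {self.daynight}")
        if (
            len(self.acq_time) != 4
            or not self.acq_time.isdigit()
            or not (0 <= int(self.acq_time[:2]) <= 23 and 0 <= int(self.acq_time[2:]) <= 59)
        ):
            raise ValueError(f"acq_time not HHMM: {self.acq_time}")


@dataclass(frozen=True)
class BaseSite:
    """One geocoded military base (point location, decimal degrees WGS84)."""

    base_id: str
    name: str
    lat: float
    lon: float
    country: str

    @property
    def point(self) -> GeoPoint:
        return GeoPoint(self.lat, self.lon)


def confidence_class(confidence: int) -> str:
    """Classify a 0-100 confidence value as ``low``/``nominal``/``high``.

    Band boundaries 30 and 80 are assigned to ``nominal``: the published
    bands (0-30 / 30-80 / 80-100) overlap at their endpoints, so a fixed
    convention is needed for reproducibility.
    """
    if not 0 <= confidence <= 100:
        raise ValueError(f"confidence out of range: {confidence}")
    if confidence < 30:
        return "low"
    if confidence <= 80:
        return "nominal"
    return "high"


@dataclass
class FirmsReadResult:
    """Accepted detections plus a per-row rejection log.

    Iterating or indexing the result yields the accepted detections, so it
    can be used anywhere a plain detection list is expected. The invariant
    ``len(detections) + len(rejected) == number of data rows`` always holds.
    """

    detections: list[FireDetection] = field(default_factory=list)
    rejected: list[tuple[int, str]] = field(default_factory=list)  # (line number, reason)

    def __iter__(self) -> Iterator[FireDetection]:
        return iter(self.detections)

    def __len__(self) -> int:
        return len(self.detections)

    def __getitem__(self, i):
        return self.detections[i]

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)


def _parse_row(row: dict[str, str]) -> FireDetection:
    conf_raw = row["confidence"].strip()
    if conf_raw.lower() in VIIRS_CONFIDENCE_MAP:
        confidence = VIIRS_CONFIDENCE_MAP[conf_raw.lower()]
    else:
        confidence = int(round(float(conf_raw)))
    det = FireDetection(
        lat=float(row["latitude"]),
        lon=float(row["longitude"]),
        acq_date=_dt.date.fromisoformat(row["acq_date"].strip()),
        acq_time=row["acq_time"].strip().zfill(4),
        satellite=row["satellite"].strip(),
        instrument=row["instrument"].strip(),
        confidence=confidence,
        frp=float(row["frp"]),
        scan=float(row["scan"]),
        track=float(row["track"]),
        daynight=row["daynight"].strip(),
        brightness=float(row["brightness"]) if row.get("brightness", "").strip() else None,
        version=(row.get("version", "").strip() or None),
        bright_t31=float(row["bright_t31"]) if row.get("bright_t31", "").strip() else None,
    )
    det.validate()
    return det


def read_firms_csv(path: str | Path, instrument_filter: str | None = None) -> FirmsReadResult:
    """Read a FIRMS-dialect CSV; invalid rows are rejected, not fatal.

    Parameters
    ----------
    path:
        CSV file with a header row using the FIRMS archive column names.
    instrument_filter:
        Optional ``"MODIS"`` or ``"VIIRS"``; other instruments' rows are
        silently dropped (they are not counted as rejects).
    """
    path = Path(path)
    result = FirmsReadResult()
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        required = [c for c in FIRMS_COLUMNS if c not in ("brightness", "version", "bright_t31")]
        missing = [c for c in required if c not in header]
        if missing:
            raise FirmsFormatError(f"missing required column(s): {', '.join(missing)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                det = _parse_row(row)
            except (ValueError, KeyError, TypeError) as exc:
                result.rejected.append((lineno, str(exc)))
                log.warning("rejected row %d of %s: %s", lineno, path, exc)
                continue
            if instrument_filter is not None and det.instrument != instrument_filter:
                continue
            result.detections.append(det)
    return result


def _fmt(x: float | None, nd: int = 6) -> str:
    if x is None:
        return ""
    return f"{x:.{nd}f}".rstrip("0").rstrip(".")


def write_firms_csv(detections: Iterable[FireDetection], path: str | Path) -> None:
    """Write detections in the FIRMS archive dialect (6-decimal coordinates)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(FIRMS_COLUMNS)
        for d in detections:
            w.writerow(
                [
                    f"{d.lat:.6f}",
                    f"{d.lon:.6f}",
                    _fmt(d.brightness, 1),
                    _fmt(d.scan, 2),
                    _fmt(d.track, 2),
                    d.acq_date.isoformat(),
                    d.acq_time,
                    d.satellite,
                    d.instrument,
                    str(d.confidence),
                    d.version or "",
                    _fmt(d.bright_t31, 1),
                    _fmt(d.frp, 2),
                    d.daynight,
                ]
            )


def read_bases_csv(path: str | Path) -> list[BaseSite]:
    """Read a base-site table (columns base_id, name, lat, lon, country)."""
    path = Path(path)
    bases: list[BaseSite] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames
        if header is None:
            return []
        missing = [c for c in ("base_id", "name", "lat", "lon", "country") if c not in header]
        if missing:
            raise FirmsFormatError(f"missing required column(s): {', '.join(missing)}")
        for row in reader:
            site = BaseSite(
                base_id=row["base_id"].strip(),
                name=row["name"].strip(),
                lat=float(row["lat"]),
                lon=float(row["lon"]),
                country=row["country"].strip(),
            )
            if not (-90.0 <= site.lat <= 90.0 and -180.0 <= site.lon <= 180.0):
                raise FirmsFormatError(f"coordinates out of range for base {site.base_id}")
            bases.append(site)
    seen: dict[str, int] = {}
    for b in bases:
        seen[b.base_id] = seen.get(b.base_id, 0) + 1
    dups = sorted(k for k, v in seen.items() if v > 1)
    if dups:
        raise FirmsFormatError(f"duplicate base_id(s): {', '.join(dups)}")
    return bases


def write_bases_csv(bases: Iterable[BaseSite], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["base_id", "name", "lat", "lon", "country"])
        for b in bases:
            w.writerow([b.base_id, b.name, f"{b.lat:.6f}", f"{b.lon:.6f}", b.country])


def filter_detections(
    detections: Sequence[FireDetection],
    date_range: tuple[_dt.date, _dt.date] | None = None,
    bbox: tuple[float, float, float, float] | None = None,
) -> list[FireDetection]:
    """Subset detections by inclusive date interval and/or lat/lon rectangle.

    ``bbox`` is (south, west, north, east) in decimal degrees. Order is
    preserved; with no filters the input is returned unchanged (as a list).
    Year stratification is this function with a calendar-year date range.
    No confidence filter exists anywhere: all confidence levels are kept so
    that low-confidence smoldering fires are not discarded.
    """
    if date_range is not None and date_range[0] > date_range[1]:
        raise ValueError(f"inverted date range: {date_range[0]} > {date_range[1]}")
    if bbox is not None:
        south, west, north, east = bbox
        if south > north or west > east:
            raise ValueError(f"inverted bbox: {bbox}")
    out = []
    for d in detections:
        if date_range is not None and not (date_range[0] <= d.acq_date <= date_range[1]):
            continue
        if bbox is not None and not (south <= d.lat <= north and west <= d.lon <= east):
            continue
        out.append(d)
    return out


# ---------------------------------------------------------------------------
# Result serialisation

LINK_COLUMNS = [
    "base_id",
    "year",
    "cluster_id",
    "n_member_fires_within_radius",
    "distance_to_medoid_km",
    "min_member_distance_km",
]


def links_to_frame(links) -> pd.DataFrame:
    """Cluster-base links as a DataFrame with a stable, documented column order."""
    rows = [
        {
            "base_id": l.base_id,
            "year": l.year,
            "cluster_id": l.cluster_id,
            "n_member_fires_within_radius": l.n_member_fires_within_radius,
            "distance_to_medoid_km": round(l.distance_to_medoid, 6),
            "min_member_distance_km": round(l.min_member_distance, 6),
        }
        for l in links
    ]
    return pd.DataFrame(rows, columns=LINK_COLUMNS)


def write_links_csv(links, path: str | Path) -> None:
    links_to_frame(links).to_csv(path, index=False)


def read_links_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"base_id": str})


def write_clusters_geojson(clusterings, detections, path: str | Path) -> None:
    """Write an RFC 7946 FeatureCollection of member fires and cluster medoids.

    One point feature per clustered fire (properties: cluster id, year,
    membership probability) and one per cluster medoid. Noise fires are not
    features. Coordinates carry 6 decimals (~0.1 m).
    """
    features = []
    for year in sorted(clusterings):
        yc = clusterings[year]
        idx = yc.indices if yc.indices is not None else range(len(yc.labels))
        members: dict[int, list[int]] = {}
        for pos, gi in enumerate(idx):
            lab = int(yc.labels[pos])
            if lab < 0:
                continue
            members.setdefault(lab, []).append(pos)
            d = detections[gi]
            features.append(
                {
                    "type": "Feature",
                    "geometry": {
                        "type": "Point",
                        "coordinates": [round(d.lon, 6), round(d.lat, 6)],
                    },
                    "properties": {
                        "kind": "fire",
                        "cluster": lab,
                        "year": int(year),
                        "membership_prob": round(float(yc.membership_prob[pos]), 6),
                    },
                }
            )
        for lab in sorted(members):
            pts = [detections[idx[pos]].point for pos in members[lab]]
            m = medoid(pts)
            features.append(
                {
                    "type": "Feature",
                    "geometry": {
                        "type": "Point",
                        "coordinates": [round(m.lon, 6), round(m.lat, 6)],
                    },
                    "properties": {
                        "kind": "medoid",
                        "cluster": lab,
                        "year": int(year),
                        "n_fires": len(pts),
                    },
                }
            )
    collection = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(collection, indent=None, separators=(",", ":")))
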