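import datetime as dt

import numpy as np
import pytest

from fireclust import FireDetection, GeoPoint
from fireclust.geodesy import offset_km

from fireclust.geodesy import EARTH_RADIUS_KM

#: km per degree of arc on the package's sphere (2*pi*R/360).
KM_PER_DEG = EARTH_RADIUS_KM * np.pi / 180.0


def tight_triplet(lat: float, lon: float, spacing_deg: float = 0.001) -> list[GeoPoint]:
    """Three points ~100 m apart: the smallest admissible cluster at k=3."""
    return [
        GeoPoint(lat, lon),
        GeoPoint(lat + spacing_deg, lon),
        GeoPoint(lat, lon + spacing_deg),
    ]


def make_detection(
    lat=33.0,
    lon=44.0,
    day=dt.date(2007, 6, 15),
    frp=21.6,
    confidence=85,
    instrument="MODIS",
    satellite="Terra",
    **kw,
) -> FireDetection:
    return FireDetection(
        lat=lat,
        lon=lon,
        acq_date=day,
        acq_time=kw.pop("acq_time", "0845"),
        satellite=satellite,
        instrument=instrument,
        confidence=confidence,
        frp=frp,
        scan=kw.pop("scan", 1.0),
        track=kw.pop("track", 1.0),
        daynight=kw.pop("daynight", "D"),
        **kw,
    )


def detection_at_km(base_point: GeoPoint, north_km: float, east_km: float = 0.0, **kw):
    p = offset_km(base_point, north_km, east_km)
    return make_detection(lat=p.lat, lon=p.lon, **kw)


@pytest.fixture
def rng():
    return np.random.default_rng(20070615)
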