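"""Stroke-care geographies and travel-time providers.

A geography ("environment") is a set of stroke centers — comprehensive
stroke centers (CSCs, thrombectomy-capable) and primary stroke centers
(PSCs, thrombolysis only) — placed in an incident region, together with a
travel-time model and a door-in-door-out (DIDO) time for secondary
transfers.

Two modes are supported:

* **abstract** — planar coordinates whose unit *is* driving time in
  minutes; travel time between two points is their Euclidean distance.
  Random geographies are drawn from a homogeneous spatial Poisson point
  process on a disc, conditioned on the center counts (i.e. i.i.d. uniform
  points on the disc).
* **geo** — latitude/longitude coordinates; travel time comes from a
  great-circle (haversine) speed model or from a user-supplied
  center-to-center travel-time matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from shapely import contains_xy
from shapely import wkt as shapely_wkt
from shapely.geometry import box as shapely_box
from shapely.geometry.base import BaseGeometry

from .errors import ParseError, ValidationError

EARTH_RADIUS_KM = 6371.0088

ABSTRACT = "abstract"
GEO = "geo"

CSC = "CSC"
PSC = "PSC"
LEVELS = (CSC, PSC)


# ---------------------------------------------------------------------------
# locations and centers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Location:
    """A point in the incident region.

    In abstract mode ``x``/``y`` are driving-time coordinates in minutes.
    In geo mode ``x`` is longitude and ``y`` is latitude, in degrees
    (build with :meth:`from_latlon` to avoid mixing them up).
    """

    x: float
    y: float
    mode: str = ABSTRACT

    def __post_init__(self) -> None:
        if self.mode not in (ABSTRACT, GEO):
            raise ValidationError(f"unknown location mode {self.mode!r}")
        if self.mode == GEO:
            if not -90.0 <= self.y <= 90.0:
                raise ValidationError(f"latitude {self.y} outside [-90, 90]")
            if not -180.0 <= self.x <= 180.0:
                raise ValidationError(f"longitude {self.x} outside [-180, 180]")

    @classmethod
    def from_latlon(cls, lat: float, lon: float) -> "Location":
        return cls(x=float(lon), y=float(lat), mode=GEO)

    @property
    def lat(self) -> float:
        return self.y

    @property
    def lon(self) -> float:
        return self.x


@dataclass(frozen=True)
class StrokeCenter:
    """A stroke center: ``level`` is ``"CSC"`` or ``"PSC"``."""

    id: str
    level: str
    location: Location

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValidationError(
                f"center {self.id!r}: level must be one of {LEVELS}, got {self.level!r}"
            )


def _center_xy(centers: Sequence[StrokeCenter]) -> np.ndarray:
    """(n, 2) coordinate array for a center list (x=lon, y=lat in geo mode)."""
    if not centers:
        return np.empty((0, 2))
    return np.array([[c.location.x, c.location.y] for c in centers], dtype=float)


# ---------------------------------------------------------------------------
# travel-time providers
# ---------------------------------------------------------------------------


def _require_mode(a: Location, b: Location, mode: str) -> None:
    if a.mode != mode or b.mode != mode:
        raise ValidationError(
            f"expected two {mode}-mode locations, got {a.mode!r} and {b.mode!r}"
        )


@dataclass(frozen=True)
class EuclideanTravelTime:
    """Planar travel time: coordinates are minutes, time = Euclidean distance."""

    tag = "euclidean"

    def __call__(self, a: Location, b: Location) -> float:
        _require_mode(a, b, ABSTRACT)
        return math.hypot(a.x - b.x, a.y - b.y)

    def times_to_centers(
        self, xs: np.ndarray, ys: np.ndarray, centers: Sequence[StrokeCenter]
    ) -> np.ndarray:
        cxy = _center_xy(centers)
        return np.hypot(xs[:, None] - cxy[None, :, 0], ys[:, None] - cxy[None, :, 1])

    def center_matrix(
        self, rows: Sequence[StrokeCenter], cols: Sequence[StrokeCenter]
    ) -> np.ndarray:
        a, b = _center_xy(rows), _center_xy(cols)
        return np.hypot(a[:, None, 0] - b[None, :, 0], a[:, None, 1] - b[None, :, 1])


def _haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km; arguments in degrees, array-friendly."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlmb = np.radians(lon2) - np.radians(lon1)
    h = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlmb / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


@dataclass(frozen=True)
class HaversineTravelTime:
    """Geo travel time: great-circle km x road_factor / speed, in minutes.

    ``road_factor`` inflates the great-circle distance to approximate road
    network length; ``speed_kmh`` is the assumed average driving speed.
    """

    speed_kmh: float = 60.0
    road_factor: float = 1.3

    tag = "haversine"

    def __post_init__(self) -> None:
        if self.speed_kmh <= 0:
            raise ValidationError(f"speed_kmh must be positive, got {self.speed_kmh}")
        if self.road_factor < 1.0:
            raise ValidationError(f"road_factor must be >= 1, got {self.road_factor}")

    def _minutes(self, km):
        return km * self.road_factor / self.speed_kmh * 60.0

    def __call__(self, a: Location, b: Location) -> float:
        _require_mode(a, b, GEO)
        return float(self._minutes(_haversine_km(a.lat, a.lon, b.lat, b.lon)))

    def times_to_centers(
        self, xs: np.ndarray, ys: np.ndarray, centers: Sequence[StrokeCenter]
    ) -> np.ndarray:
        cxy = _center_xy(centers)
        km = _haversine_km(
            ys[:, None], xs[:, None], cxy[None, :, 1], cxy[None, :, 0]
        )
        return self._minutes(km)

    def center_matrix(
        self, rows: Sequence[StrokeCenter], cols: Sequence[StrokeCenter]
    ) -> np.ndarray:
        a, b = _center_xy(rows), _center_xy(cols)
        km = _haversine_km(a[:, None, 1], a[:, None, 0], b[None, :, 1], b[None, :, 0])
        return self._minutes(km)


class MatrixTravelTime:
    """Center-to-center travel times from a stored matrix, in minutes.

    The matrix only knows the centers, so legs involving an arbitrary scene
    location (raster points) fall back to the geometric ``fallback``
    provider. Matrix entries need not be symmetric; the stored entry is
    returned verbatim.
    """

    tag = "matrix"

    def __init__(
        self,
        ids: Sequence[str],
        matrix: np.ndarray,
        fallback: EuclideanTravelTime | HaversineTravelTime,
    ) -> None:
        matrix = np.asarray(matrix, dtype=float)
        ids = tuple(ids)
        if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
            raise ValidationError(
                f"travel-time matrix must be square, got shape {matrix.shape}"
            )
        if len(ids) != matrix.shape[0]:
            raise ValidationError(
                f"{len(ids)} ids for a {matrix.shape[0]}x{matrix.shape[1]} matrix"
            )
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate ids in travel-time matrix")
        if (matrix < 0).any():
            raise ValidationError("travel-time matrix contains negative entries")
        self.ids = ids
        self.matrix = matrix
        self.fallback = fallback
        self._index = {cid: i for i, cid in enumerate(ids)}

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, MatrixTravelTime)
            and self.ids == other.ids
            and np.array_equal(self.matrix, other.matrix)
            and self.fallback == other.fallback
        )

    def entry(self, origin_id: str, destination_id: str) -> float:
        try:
            return float(self.matrix[self._index[origin_id], self._index[destination_id]])
        except KeyError as exc:
            raise ValidationError(f"unknown center id {exc.args[0]!r} in matrix lookup")

    def __call__(self, a: Location, b: Location) -> float:
        # scalar lookups between raw locations cannot know ids; use fallback
        return self.fallback(a, b)

    def times_to_centers(
        self, xs: np.ndarray, ys: np.ndarray, centers: Sequence[StrokeCenter]
    ) -> np.ndarray:
        return self.fallback.times_to_centers(xs, ys, centers)

    def center_matrix(
        self, rows: Sequence[StrokeCenter], cols: Sequence[StrokeCenter]
    ) -> np.ndarray:
        out = np.empty((len(rows), len(cols)))
        for i, r in enumerate(rows):
            for j, c in enumerate(cols):
                out[i, j] = self.entry(r.id, c.id)
        return out


def euclidean_travel_time(a: Location, b: Location) -> float:
    """Planar driving time in minutes between two abstract-mode locations."""
    return EuclideanTravelTime()(a, b)


def haversine_travel_time(
    a: Location, b: Location, speed_kmh: float = 60.0, road_factor: float = 1.3
) -> float:
    """Driving time in minutes between two geo-mode locations under a
    constant-speed road model."""
    return HaversineTravelTime(speed_kmh=speed_kmh, road_factor=road_factor)(a, b)


# ---------------------------------------------------------------------------
# incident regions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Disc:
    """Disc of given radius (driving-time minutes) centered at the origin."""

    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValidationError(f"disc radius must be positive, got {self.radius}")

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        r = self.radius
        return (-r, -r, r, r)

    @property
    def diameter(self) -> float:
        return 2.0 * self.radius

    def contains(self, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
        xs, ys = np.asarray(xs, float), np.asarray(ys, float)
        return xs * xs + ys * ys <= self.radius * self.radius


@dataclass(frozen=True)
class PolygonRegion:
    """Arbitrary polygonal incident region (shapely geometry); used for
    loaded geographies, where the region is a bounding box around the
    centers plus a margin."""

    polygon: BaseGeometry

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        return tuple(self.polygon.bounds)

    @property
    def diameter(self) -> float:
        xmin, ymin, xmax, ymax = self.bounds
        return math.hypot(xmax - xmin, ymax - ymin)

    def contains(self, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
        # covers == boundary-inclusive containment
        from shapely import covers, points

        return covers(self.polygon, points(np.asarray(xs, float), np.asarray(ys, float)))


# ---------------------------------------------------------------------------
# environment
# ---------------------------------------------------------------------------


@dataclass
class Environment:
    """A stroke-care geography: centers + incident region + travel times.

    ``dido`` is the door-in-door-out time in minutes — the delay between a
    patient's arrival at a PSC and departure toward a CSC for thrombectomy.
    """

    centers: list[StrokeCenter]
    region: Disc | PolygonRegion
    travel_time: EuclideanTravelTime | HaversineTravelTime | MatrixTravelTime
    dido: float = 60.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.dido <= 0:
            raise ValidationError(f"dido must be positive, got {self.dido}")
        ids = [c.id for c in self.centers]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate center ids: {dup}")
        if not any(c.level == CSC for c in self.centers):
            raise ValidationError("environment needs at least one CSC")
        modes = {c.location.mode for c in self.centers}
        if len(modes) > 1:
            raise ValidationError(f"mixed location modes in one environment: {modes}")

    @property
    def mode(self) -> str:
        return self.centers[0].location.mode

    @property
    def cscs(self) -> list[StrokeCenter]:
        return [c for c in self.centers if c.level == CSC]

    @property
    def pscs(self) -> list[StrokeCenter]:
        return [c for c in self.centers if c.level == PSC]

    def centers_of(self, level: str) -> list[StrokeCenter]:
        if level not in LEVELS:
            raise ValidationError(f"unknown center level {level!r}")
        return [c for c in self.centers if c.level == level]


# ---------------------------------------------------------------------------
# random generation
# ---------------------------------------------------------------------------


def replicate_rng(
    master_seed: int, n_csc: int, n_psc: int, rep: int
) -> np.random.Generator:
    """Independent, reproducible random stream for one study replicate.

    Keyed by (master seed, CSC count, PSC count, replicate index) so any
    single replicate can be regenerated in isolation.
    """
    return np.random.default_rng(
        np.random.SeedSequence(master_seed, spawn_key=(n_csc, n_psc, rep))
    )


def generate_random_environment(
    n_csc: int,
    n_psc: int,
    radius: float,
    dido: float = 60.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> Environment:
    """Draw a random abstract geography on a disc of the given radius.

    Center locations follow a homogeneous spatial Poisson point process
    conditioned on the counts, i.e. the ``n_csc + n_psc`` points are
    i.i.d. uniform on the disc (radial coordinate R*sqrt(U), angle
    uniform). CSCs and PSCs are drawn from the same law, independently.
    """
    if n_csc < 1 or n_psc < 0:
        raise ValidationError(
            f"need n_csc >= 1 and n_psc >= 0, got n_csc={n_csc}, n_psc={n_psc}"
        )
    if radius <= 0:
        raise ValidationError(f"radius must be positive, got {radius}")
    if rng is None:
        rng = np.random.default_rng(seed)

    n = n_csc + n_psc
    r = radius * np.sqrt(rng.random(n))
    theta = rng.random(n) * 2.0 * math.pi
    xs, ys = r * np.cos(theta), r * np.sin(theta)

    width_c = max(2, len(str(n_csc)))
    width_p = max(2, len(str(n_psc)))
    centers: list[StrokeCenter] = []
    for i in range(n_csc):
        centers.append(
            StrokeCenter(f"CSC{i + 1:0{width_c}d}", CSC, Location(float(xs[i]), float(ys[i])))
        )
    for j in range(n_psc):
        i = n_csc + j
        centers.append(
            StrokeCenter(f"PSC{j + 1:0{width_p}d}", PSC, Location(float(xs[i]), float(ys[i])))
        )
    return Environment(
        centers=centers,
        region=Disc(radius),
        travel_time=EuclideanTravelTime(),
        dido=dido,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# CSV loading / serialization
# ---------------------------------------------------------------------------


def load_centers_csv(path: str | Path) -> list[StrokeCenter]:
    """Read a stroke-center table.

    Header must be ``id,level,x,y`` (abstract, minutes) or
    ``id,level,lat,lon`` (geo, degrees); ``level`` is CSC or PSC.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"id": str}, float_precision="round_trip")
    except FileNotFoundError:
        raise ParseError(f"centers file not found: {path}")
    cols = set(df.columns)
    if not {"id", "level"} <= cols:
        missing = {"id", "level"} - cols
        raise ParseError(f"{path}: missing column(s) {sorted(missing)}")
    if {"lat", "lon"} <= cols:
        mode = GEO
    elif {"x", "y"} <= cols:
        mode = ABSTRACT
    else:
        missing = [c for c in ("lat", "lon", "x", "y") if c not in cols]
        raise ParseError(
            f"{path}: need coordinate columns lat,lon or x,y (missing {missing})"
        )
    if df["id"].duplicated().any():
        dup = sorted(df.loc[df["id"].duplicated(), "id"].unique())
        raise ParseError(f"{path}: duplicate center id(s) {dup}")
    bad = sorted(set(df["level"]) - set(LEVELS))
    if bad:
        raise ParseError(f"{path}: unknown level(s) {bad}; expected CSC or PSC")

    centers = []
    for row in df.itertuples(index=False):
        if mode == GEO:
            loc = Location.from_latlon(float(row.lat), float(row.lon))
        else:
            loc = Location(float(row.x), float(row.y))
        centers.append(StrokeCenter(str(row.id), str(row.level), loc))
    return centers


def write_centers_csv(centers: Sequence[StrokeCenter], path: str | Path) -> None:
    rows = []
    for c in centers:
        if c.location.mode == GEO:
            rows.append({"id": c.id, "level": c.level, "lat": c.location.lat, "lon": c.location.lon})
        else:
            rows.append({"id": c.id, "level": c.level, "x": c.location.x, "y": c.location.y})
    pd.DataFrame(rows).to_csv(path, index=False)


def load_travel_time_matrix(path: str | Path, ids: Sequence[str]) -> np.ndarray:
    """Read a square travel-time matrix CSV (first row/column are center
    ids, entries in minutes) and align it to ``ids`` order."""
    path = Path(path)
    try:
        df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    except FileNotFoundError:
        raise ParseError(f"travel-time matrix not found: {path}")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.shape[0] != df.shape[1]:
        raise ParseError(
            f"{path}: travel-time matrix must be square, got {df.shape[0]}x{df.shape[1]}"
        )
    if set(df.index) != set(df.columns):
        raise ParseError(f"{path}: matrix row ids and column ids differ")
    if set(df.index) != set(ids):
        missing = sorted(set(ids) - set(df.index))
        extra = sorted(set(df.index) - set(ids))
        raise ParseError(
            f"{path}: matrix ids do not match centers (missing {missing}, extra {extra})"
        )
    aligned = df.loc[list(ids), list(ids)].to_numpy(dtype=float)
    if np.isnan(aligned).any():
        raise ParseError(f"{path}: non-numeric or missing matrix entries")
    return aligned


def bounding_region(
    centers: Sequence[StrokeCenter], margin_frac: float = 0.1
) -> PolygonRegion:
    """Axis-aligned bounding box of the centers, expanded on every side by
    ``margin_frac`` of the larger box dimension."""
    xy = _center_xy(centers)
    xmin, ymin = xy.min(axis=0)
    xmax, ymax = xy.max(axis=0)
    span = max(xmax - xmin, ymax - ymin)
    pad = margin_frac * span if span > 0 else 1.0
    return PolygonRegion(shapely_box(xmin - pad, ymin - pad, xmax + pad, ymax + pad))


def load_environment(
    centers_csv: str | Path,
    ttm_csv: str | Path | None = None,
    dido: float = 60.0,
    speed_kmh: float = 60.0,
    road_factor: float = 1.3,
    margin_frac: float = 0.1,
) -> Environment:
    """Build an environment from a centers CSV and, optionally, a
    precomputed center-to-center travel-time matrix CSV.

    Without a matrix, travel times use the haversine speed model (geo
    mode) or Euclidean distance (abstract mode). With a matrix,
    center-to-center legs come from the matrix and scene legs from the
    geometric model. The incident region is the bounding box of the
    centers plus a margin.
    """
    centers = load_centers_csv(centers_csv)
    mode = centers[0].location.mode if centers else ABSTRACT
    base: EuclideanTravelTime | HaversineTravelTime
    if mode == GEO:
        base = HaversineTravelTime(speed_kmh=speed_kmh, road_factor=road_factor)
    else:
        base = EuclideanTravelTime()
    provider: EuclideanTravelTime | HaversineTravelTime | MatrixTravelTime = base
    if ttm_csv is not None:
        ids = [c.id for c in centers]
        matrix = load_travel_time_matrix(ttm_csv, ids)
        provider = MatrixTravelTime(ids, matrix, fallback=base)
    return Environment(
        centers=centers,
        region=bounding_region(centers, margin_frac=margin_frac),
        travel_time=provider,
        dido=dido,
    )


# -- YAML round-trip --------------------------------------------------------


def _provider_to_dict(p) -> dict:
    if isinstance(p, EuclideanTravelTime):
        return {"tag": "euclidean"}
    if isinstance(p, HaversineTravelTime):
        return {"tag": "haversine", "speed_kmh": p.speed_kmh, "road_factor": p.road_factor}
    if isinstance(p, MatrixTravelTime):
        return {
            "tag": "matrix",
            "ids": list(p.ids),
            "matrix": p.matrix.tolist(),
            "fallback": _provider_to_dict(p.fallback),
        }
    raise ValidationError(f"cannot serialize travel-time provider {p!r}")


def _provider_from_dict(d: dict):
    tag = d.get("tag")
    if tag == "euclidean":
        return EuclideanTravelTime()
    if tag == "haversine":
        return HaversineTravelTime(
            speed_kmh=d.get("speed_kmh", 60.0), road_factor=d.get("road_factor", 1.3)
        )
    if tag == "matrix":
        return MatrixTravelTime(
            d["ids"], np.array(d["matrix"], dtype=float), _provider_from_dict(d["fallback"])
        )
    raise ParseError(f"unknown travel-time provider tag {tag!r}")


def environment_to_dict(env: Environment) -> dict:
    if isinstance(env.region, Disc):
        region = {"shape": "disc", "radius": env.region.radius}
    else:
        region = {"shape": "polygon", "wkt": env.region.polygon.wkt}
    centers = []
    for c in env.centers:
        centers.append(
            {"id": c.id, "level": c.level, "x": c.location.x, "y": c.location.y, "mode": c.location.mode}
        )
    return {
        "centers": centers,
        "region": region,
        "travel_time": _provider_to_dict(env.travel_time),
        "dido": env.dido,
        "seed": env.seed,
    }


def environment_from_dict(d: dict) -> Environment:
    region_d = d["region"]
    region: Disc | PolygonRegion
    if region_d["shape"] == "disc":
        region = Disc(float(region_d["radius"]))
    elif region_d["shape"] == "polygon":
        region = PolygonRegion(shapely_wkt.loads(region_d["wkt"]))
    else:
        raise ParseError(f"unknown region shape {region_d.get('shape')!r}")
    centers = [
        StrokeCenter(c["id"], c["level"], Location(float(c["x"]), float(c["y"]), c.get("mode", ABSTRACT)))
        for c in d["centers"]
    ]
    return Environment(
        centers=centers,
        region=region,
        travel_time=_provider_from_dict(d["travel_time"]),
        dido=float(d["dido"]),
        seed=d.get("seed"),
    )


def save_environment(env: Environment, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(environment_to_dict(env), sort_keys=False))


def load_environment_file(path: str | Path) -> Environment:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"environment file not found: {path}")
    return environment_from_dict(yaml.safe_load(path.read_text()))
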