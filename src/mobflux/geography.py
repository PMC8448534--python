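"""Spatial units for trip modelling: districts, distances, urbanicity, aggregation.

Districts are the modelling unit (typically administrative level 2). Each
carries a population, a centroid (decimal degrees), the fraction of its grid
cells classified as urban, and the identifier of the level-1 region that
contains it. Pairwise separations are great-circle (haversine) distances
between centroids, in kilometres.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0

URBAN = "urban"
RURAL = "rural"

DISTRICT_COLUMNS = ["id", "name", "region_id", "population", "lat", "lon", "urban_fraction"]


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


def _check_range(name: str, value: float, lo: float, hi: float) -> None:
    if not np.all(np.isfinite(value)) or np.any(np.asarray(value) < lo) or np.any(np.asarray(value) > hi):
        raise ValidationError(f"{name} must lie in [{lo}, {hi}]; got {value!r}")


def haversine_distance(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in km between two points, on a sphere of radius 6371 km.

    Symmetric in its argument pairs and zero for coincident points.
    """
    _check_range("lat1", lat1, -90.0, 90.0)
    _check_range("lat2", lat2, -90.0, 90.0)
    _check_range("lon1", lon1, -180.0, 180.0)
    _check_range("lon2", lon2, -180.0, 180.0)
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlam = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2.0) ** 2
    return float(2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0))))


def classify_urbanicity(urban_fraction: float, threshold: float = 0.5) -> str:
    """Label a district ``urban`` iff its urban grid-cell fraction strictly exceeds ``threshold``.

    The default threshold is 0.5; 0.1 is the conventional lower sensitivity
    setting. Ties go to ``rural``.
    """
    _check_range("urban_fraction", urban_fraction, 0.0, 1.0)
    _check_range("threshold", threshold, 0.0, 1.0)
    return URBAN if urban_fraction > threshold else RURAL


@dataclass(frozen=True)
class District:
    """A spatial unit with population, centroid, region, and urbanicity."""

    id: str
    name: str
    region_id: str
    population: float
    lat: float
    lon: float
    urban_fraction: float
    urbanicity: str = field(default="")

    def __post_init__(self) -> None:
        if not self.population > 0:
            raise ValidationError(f"district {self.id!r}: population must be > 0, got {self.population}")
        _check_range(f"district {self.id!r}: lat", self.lat, -90.0, 90.0)
        _check_range(f"district {self.id!r}: lon", self.lon, -180.0, 180.0)
        _check_range(f"district {self.id!r}: urban_fraction", self.urban_fraction, 0.0, 1.0)

    def with_urbanicity(self, threshold: float = 0.5) -> "District":
        return replace(self, urbanicity=classify_urbanicity(self.urban_fraction, threshold))


@dataclass(frozen=True)
class Geography:
    """An ordered set of districts plus their pairwise haversine distance matrix (km)."""

    districts: tuple[District, ...]
    distance_matrix: np.ndarray  # (n, n), symmetric, zero diagonal
    urban_threshold: float = 0.5

    @property
    def n(self) -> int:
        return len(self.districts)

    @property
    def ids(self) -> list[str]:
        return [d.id for d in self.districts]

    @property
    def populations(self) -> np.ndarray:
        return np.array([d.population for d in self.districts], dtype=float)

    @property
    def total_population(self) -> float:
        return float(self.populations.sum())

    @property
    def region_ids(self) -> list[str]:
        return [d.region_id for d in self.districts]

    @property
    def urbanicity(self) -> list[str]:
        return [d.urbanicity for d in self.districts]

    def index_of(self, district_id: str) -> int:
        return self.ids.index(district_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "name": [d.name for d in self.districts],
                "region_id": self.region_ids,
                "population": self.populations,
                "lat": [d.lat for d in self.districts],
                "lon": [d.lon for d in self.districts],
                "urban_fraction": [d.urban_fraction for d in self.districts],
            }
        )


def _distance_matrix(lats: np.ndarray, lons: np.ndarray) -> np.ndarray:
    phi = np.radians(lats)[:, None]
    lam = np.radians(lons)[:, None]
    dphi = phi - phi.T
    dlam = lam - lam.T
    a = np.sin(dphi / 2.0) ** 2 + np.cos(phi) * np.cos(phi.T) * np.sin(dlam / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    np.fill_diagonal(d, 0.0)
    # enforce exact symmetry against floating-point asymmetry
    return (d + d.T) / 2.0


def build_geography(
    districts: Iterable[District] | pd.DataFrame,
    urban_threshold: float = 0.5,
) -> Geography:
    """Assemble a :class:`Geography` from districts or a district table.

    Districts keep their input order. Urbanicity labels are (re)derived from
    ``urban_fraction`` at ``urban_threshold``.
    """
    if isinstance(districts, pd.DataFrame):
        missing = [c for c in DISTRICT_COLUMNS if c not in districts.columns]
        if missing:
            raise ValidationError(f"district table missing columns: {missing}")
        districts = [
            District(
                id=str(r.id),
                name=str(r.name),
                region_id=str(r.region_id),
                population=float(r.population),
                lat=float(r.lat),
                lon=float(r.lon),
                urban_fraction=float(r.urban_fraction),
            )
            for r in districts.itertuples(index=False)
        ]
    dlist = [d.with_urbanicity(urban_threshold) for d in districts]
    if len(dlist) < 2:
        raise ValidationError("a geography needs at least 2 districts")
    ids = [d.id for d in dlist]
    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        raise ValidationError(f"duplicate district ids: {dupes}")
    lats = np.array([d.lat for d in dlist])
    lons = np.array([d.lon for d in dlist])
    return Geography(tuple(dlist), _distance_matrix(lats, lons), urban_threshold)


def read_district_csv(path, urban_threshold: float = 0.5) -> Geography:
    """Read the district table CSV (``id,name,region_id,population,lat,lon,urban_fraction``)."""
    return build_geography(pd.read_csv(path, dtype={"id": str, "region_id": str}), urban_threshold)


def write_district_csv(geo: Geography, path) -> None:
    geo.to_frame().to_csv(path, index=False)


def read_geojson_centroids(path, urban_threshold: float = 0.5) -> Geography:
    """Build a geography from a GeoJSON FeatureCollection of district polygons.

    Feature properties must supply ``id, name, region_id, population,
    urban_fraction``; centroids come from the polygon geometry (true area
    centroid, not a vertex average).
    """
    from shapely.geometry import shape

    with open(path) as fh:
        collection = json.load(fh)
    rows = []
    for feat in collection["features"]:
        props = feat["properties"]
        c = shape(feat["geometry"]).centroid
        rows.append(
            District(
                id=str(props["id"]),
                name=str(props.get("name", props["id"])),
                region_id=str(props["region_id"]),
                population=float(props["population"]),
                lat=float(c.y),
                lon=float(c.x),
                urban_fraction=float(props["urban_fraction"]),
            )
        )
    return build_geography(rows, urban_threshold)


def drop_districts(geo: Geography, ids: Sequence[str]) -> Geography:
    """Remove districts (e.g. units with no trip data) before fitting; logged."""
    keep = [d for d in geo.districts if d.id not in set(ids)]
    dropped = [d.id for d in geo.districts if d.id in set(ids)]
    if dropped:
        logger.info("dropping districts without usable trip data: %s", dropped)
    return build_geography(keep, geo.urban_threshold)


def aggregate_geography(
    geo: Geography,
    trips: "TripMatrix | None",
    mapping: Mapping[str, str],
):
    """Aggregate districts into coarser units (e.g. level-2 -> level-1).

    Unit population is the sum of member populations; the unit centroid is the
    population-weighted mean of member centroids; unit urban_fraction is the
    population-weighted mean of member fractions; unit trips are sums of
    member-pair trips with within-unit trips dropped. Useful for studying the
    modifiable areal unit problem by re-fitting models at coarser levels.

    Returns ``(Geography, TripMatrix | None)``.
    """
    from .trips import TripMatrix

    missing = [d.id for d in geo.districts if d.id not in mapping]
    if missing:
        raise ValidationError(f"aggregation mapping missing districts: {missing}")

    unit_ids: list[str] = []
    for d in geo.districts:  # preserve first-appearance order
        u = str(mapping[d.id])
        if u not in unit_ids:
            unit_ids.append(u)

    units = []
    for u in unit_ids:
        members = [d for d in geo.districts if str(mapping[d.id]) == u]
        pops = np.array([d.population for d in members])
        w = pops / pops.sum()
        regions = {d.region_id for d in members}
        units.append(
            District(
                id=u,
                name=u,
                region_id=regions.pop() if len(regions) == 1 else u,
                population=float(pops.sum()),
                lat=float(np.sum(w * [d.lat for d in members])),
                lon=float(np.sum(w * [d.lon for d in members])),
                urban_fraction=float(np.sum(w * [d.urban_fraction for d in members])),
            )
        )
    if len(units) == 1:
        # degenerate single-unit aggregation: allowed here (all travel internal)
        u = units[0].with_urbanicity(geo.urban_threshold)
        agg_geo = Geography((u,), np.zeros((1, 1)), geo.urban_threshold)
    else:
        agg_geo = build_geography(units, geo.urban_threshold)

    agg_trips = None
    if trips is not None:
        idx_of_unit = {u: k for k, u in enumerate(unit_ids)}
        member_unit = np.array([idx_of_unit[str(mapping[d.id])] for d in geo.districts])
        n_u = len(unit_ids)
        vals = np.zeros((n_u, n_u))
        seen = np.zeros((n_u, n_u), dtype=bool)
        v = trips.values
        for i in range(geo.n):
            for j in range(geo.n):
                if i == j or not np.isfinite(v[i, j]):
                    continue
                ui, uj = member_unit[i], member_unit[j]
                if ui == uj:
                    continue  # within-unit travel drops out
                vals[ui, uj] += v[i, j]
                seen[ui, uj] = True
        vals[~seen] = np.nan
        np.fill_diagonal(vals, np.nan)
        agg_trips = TripMatrix(unit_ids, vals)
    return agg_geo, agg_trips
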