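"""Synthetic geographies and trip matrices with known generating parameters.

Real district-level trip matrices derived from call data records are rarely
shareable, so every pipeline stage here is exercised on synthetic data that
mimics their structure: a country partitioned into level-1 regions whose
districts cluster spatially, heavy-tailed (log-normal) district populations
with a dominant capital, a minority of predominantly urban districts
concentrated where populations are large, and Poisson-distributed trip
counts whose expectations come from a known gravity or radiation model.

Everything is driven by a single integer seed and regenerates bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .geography import District, Geography, ValidationError, build_geography, write_district_csv
from .gravity import GravityParams, gravity_predict
from .radiation import RadiationParams, radiation_predict
from .trips import TripMatrix, write_trip_csv
from .typology import build_typology


@dataclass(frozen=True)
class GeographyConfig:
    """Knobs for the synthetic country.

    Region centres are drawn uniformly in the lat/lon box and district
    centroids are jittered around them, so intra-regional separations are
    stochastically smaller than inter-regional ones. Populations are
    log-normal (median ``pop_median`` persons, log-sd ``pop_log_sigma``) with
    one capital district inflated by ``capital_factor``. Urban status goes to
    the highest-population districts — either a national share
    (``urban_share``) or a fixed count per region (``urban_per_region``).
    """

    n_regions: int = 4
    districts_per_region: int = 6
    lat_range: tuple[float, float] = (-18.0, -10.0)
    lon_range: tuple[float, float] = (22.0, 30.0)
    district_spread_deg: float = 0.35
    pop_median: float = 5.0e4
    pop_log_sigma: float = 0.7
    capital_factor: float = 10.0
    urban_share: float = 0.25
    urban_per_region: int | None = None
    urban_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.n_regions * self.districts_per_region < 2:
            raise ValidationError("need at least 2 districts in total")
        if not (0.0 <= self.urban_share <= 1.0):
            raise ValidationError("urban_share must lie in [0, 1]")
        if self.urban_per_region is not None and self.urban_per_region > self.districts_per_region:
            raise ValidationError("urban_per_region exceeds districts_per_region")


def generate_geography(config: GeographyConfig | None = None, seed: int = 0) -> Geography:
    """Draw a clustered synthetic geography; deterministic given (config, seed)."""
    cfg = config or GeographyConfig()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    n = cfg.n_regions * cfg.districts_per_region

    centers_lat = rng.uniform(*cfg.lat_range, size=cfg.n_regions)
    centers_lon = rng.uniform(*cfg.lon_range, size=cfg.n_regions)
    region_of = np.repeat(np.arange(cfg.n_regions), cfg.districts_per_region)
    lat = centers_lat[region_of] + rng.normal(0.0, cfg.district_spread_deg, size=n)
    lon = centers_lon[region_of] + rng.normal(0.0, cfg.district_spread_deg, size=n)

    pop = rng.lognormal(np.log(cfg.pop_median), cfg.pop_log_sigma, size=n)
    pop[int(np.argmax(pop))] *= cfg.capital_factor  # the capital dominates

    urban = np.zeros(n, dtype=bool)
    if cfg.urban_per_region is not None:
        for r in range(cfg.n_regions):
            members = np.where(region_of == r)[0]
            top = members[np.argsort(pop[members])[::-1][: cfg.urban_per_region]]
            urban[top] = True
    else:
        k = int(round(cfg.urban_share * n))
        urban[np.argsort(pop)[::-1][:k]] = True

    frac = np.where(urban, rng.uniform(0.55, 0.95, size=n), rng.uniform(0.02, 0.45, size=n))

    districts = [
        District(
            id=f"d{i + 1:02d}",
            name=f"District {i + 1}",
            region_id=f"R{region_of[i] + 1}",
            population=float(np.round(pop[i])),
            lat=float(lat[i]),
            lon=float(lon[i]),
            urban_fraction=float(frac[i]),
        )
        for i in range(n)
    ]
    return build_geography(districts, cfg.urban_threshold)


def generate_trips(geo: Geography, true_params, seed: int = 0) -> TripMatrix:
    """Observed counts as independent Poisson draws around the model's expectations."""
    if isinstance(true_params, GravityParams):
        expected = gravity_predict(true_params, geo, build_typology(geo))
    elif isinstance(true_params, RadiationParams):
        expected = radiation_predict(true_params, geo)
    else:
        raise ValidationError(f"unsupported parameter type {type(true_params).__name__}")
    lam = expected.values
    off = np.isfinite(lam)
    if not np.all(np.isfinite(lam[off])):
        raise ValidationError("expected counts are not finite")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 202]))
    draws = np.full(lam.shape, np.nan)
    draws[off] = rng.poisson(lam[off]).astype(float)
    return TripMatrix(list(geo.ids), draws)


@dataclass(frozen=True)
class SyntheticScenario:
    """A geography, the generating parameters, and one Poisson trip realization."""

    name: str
    geography: Geography
    true_params: GravityParams | RadiationParams
    trips: TripMatrix
    seed: int
    config: GeographyConfig

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_district_csv(self.geography, outdir / "districts.csv")
        write_trip_csv(self.trips, outdir / "trips.csv")
        p = self.true_params
        if isinstance(p, GravityParams):
            pdoc = {
                "model": "gravity", "scheme": p.scheme, "kernel": p.kernel,
                "theta": p.theta, "alpha": p.alpha.tolist(),
                "beta": p.beta.tolist(), "decay": p.decay.tolist(),
            }
        else:
            pdoc = {"model": "radiation", "sigma": p.sigma}
        manifest = {
            "name": self.name,
            "seed": self.seed,
            "true_params": pdoc,
            "config": asdict(self.config),
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


# canonical generating parameters for the three benchmark worlds -------------

BASIC_WORLD_PARAMS = GravityParams(
    theta=0.01, alpha=np.array([0.9]), beta=np.array([0.7]), decay=np.array([1.5]),
    kernel="power", scheme="basic",
)

# Regional-urbanicity world: decays well separated and strictly increasing in
# category index, with intra-regional decay (n=1..4) below inter-regional
# (n=5..8) so within-region travel dominates; rural-rural exponents lowest.
# The inter-regional population exponents are higher so that the steeper
# inter-regional decay still leaves routes in the intended 10-10^5 count range.
REGURB_WORLD_PARAMS = GravityParams(
    theta=0.005,
    alpha=np.array([0.75, 0.80, 0.80, 0.90, 0.90, 0.95, 0.95, 1.00]),
    beta=np.array([0.75, 0.80, 0.80, 0.90, 0.90, 0.95, 0.95, 1.00]),
    decay=np.array([1.0, 1.2, 1.4, 1.6, 1.8, 2.0, 2.2, 2.4]),
    kernel="power", scheme="regional_urbanicity",
)

RADIATION_WORLD_PARAMS = RadiationParams(sigma=0.2)

BASIC_WORLD_CONFIG = GeographyConfig(n_regions=5, districts_per_region=6)
REGURB_WORLD_CONFIG = GeographyConfig(n_regions=4, districts_per_region=6, urban_per_region=2)
RADIATION_WORLD_CONFIG = GeographyConfig(
    n_regions=2, districts_per_region=5, pop_median=1.0e5, pop_log_sigma=0.5,
    capital_factor=3.0, urban_per_region=1,
)


def make_benchmark_suite(seed: int = 0) -> dict[str, SyntheticScenario]:
    """Three canonical worlds: basic gravity, regional-urbanicity gravity, radiation."""
    specs = [
        ("basic", BASIC_WORLD_CONFIG, BASIC_WORLD_PARAMS),
        ("regional_urbanicity", REGURB_WORLD_CONFIG, REGURB_WORLD_PARAMS),
        ("radiation", RADIATION_WORLD_CONFIG, RADIATION_WORLD_PARAMS),
    ]
    suite = {}
    for off, (name, cfg, params) in enumerate(specs):
        child = seed + 1000 * (off + 1)
        geo = generate_geography(cfg, seed=child)
        trips = generate_trips(geo, params, seed=child)
        suite[name] = SyntheticScenario(
            name=name, geography=geo, true_params=params, trips=trips,
            seed=child, config=cfg,
        )
    return suite
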