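import pytest
from hypothesis import settings

import mobflux as mf

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


def make_district(i, region="R1", pop=1000.0, lat=0.0, lon=0.0, frac=0.1):
    return mf.District(
        id=f"d{i}", name=f"District {i}", region_id=region,
        population=pop, lat=lat, lon=lon, urban_fraction=frac,
    )


@pytest.fixture(scope="session")
def five_district_geo():
    """Small handmade geography spanning two regions with one urban district."""
    rows = [
        make_district(1, "R1", 5.0e4, -12.0, 25.0, 0.10),
        make_district(2, "R1", 2.0e5, -12.3, 25.4, 0.80),
        make_district(3, "R1", 3.0e4, -11.6, 24.8, 0.05),
        make_district(4, "R2", 8.0e4, -14.1, 27.0, 0.30),
        make_district(5, "R2", 1.2e4, -14.5, 27.5, 0.02),
    ]
    return mf.build_geography(rows)


@pytest.fixture(scope="session")
def benchmark_suite():
    return mf.make_benchmark_suite(1)


def random_geography(rng, n=6, n_regions=2):
    """Random small geography for oracle comparisons."""
    per = max(1, n // n_regions)
    cfg = mf.GeographyConfig(
        n_regions=n_regions,
        districts_per_region=per,
        pop_median=float(rng.uniform(2e4, 2e5)),
        urban_share=float(rng.uniform(0.1, 0.5)),
    )
    return mf.generate_geography(cfg, seed=int(rng.integers(0, 2**31 - 1)))
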