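"""Build a geography from a district table and inspect distances and urbanicity.

Districts carry a population, a centroid, a level-1 region, and the fraction
of their grid cells classified as urban; a district is labelled "urban" when
that fraction exceeds the 50% threshold (10% is the usual sensitivity
setting). Distances are haversine (great-circle) kilometres between
centroids.
"""

import numpy as np

import mobflux as mf

districts = [
    mf.District("d1", "Riverside", "R1", 52_000, -12.00, 25.00, 0.10),
    mf.District("d2", "Capital", "R1", 210_000, -12.30, 25.40, 0.82),
    mf.District("d3", "Hillcrest", "R1", 31_000, -11.60, 24.80, 0.05),
    mf.District("d4", "Lakeview", "R2", 78_000, -14.10, 27.00, 0.31),
    mf.District("d5", "Far North", "R2", 12_500, -14.50, 27.50, 0.02),
]

geo = mf.build_geography(districts, urban_threshold=0.5)

print("district  region  population  urbanicity")
for d in geo.districts:
    print(f"{d.name:<9} {d.region_id:<7} {d.population:>10,.0f}  {d.urbanicity}")

print("\npairwise centroid distances (km):")
print(np.round(geo.distance_matrix, 1))

# Aggregate the five districts to their two level-1 regions: populations add,
# centroids are population-weighted, and within-region trips drop out.
mapping = {d.id: d.region_id for d in geo.districts}
region_geo, _ = mf.aggregate_geography(geo, None, mapping)
print("\nregion populations after aggregation:",
      dict(zip(region_geo.ids, region_geo.populations)))
print("region separation: %.1f km" % region_geo.distance_matrix[0, 1])
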