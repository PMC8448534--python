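"""The finite-system radiation model and its one-parameter fit.

Trips from i to j depend on the population s_ij living closer to i than j
does (the "intervening opportunities"), not on distance directly. The
finite-system normalization guarantees each origin sends out exactly
sigma * P_i trips, where sigma is the travelling fraction of the population.
"""

import numpy as np

import mobflux as mf

scenario = mf.make_benchmark_suite(seed=3)["radiation"]  # sigma = 0.2 world
geo, trips = scenario.geography, scenario.trips

s = mf.intervening_population(geo)
print("intervening population, first origin (persons):")
print(np.round(s[0]).astype(int))

pred = mf.radiation_predict(mf.RadiationParams(0.2), geo)
rows = np.nansum(pred.values, axis=1)
print("\nrow totals equal sigma * P_i exactly: max relative error %.2e"
      % np.max(np.abs(rows / (0.2 * geo.populations) - 1)))

fit = mf.fit_radiation(trips, geo)
print(f"\nsigma fitted to Poisson trip counts: {fit.params.sigma:.5f} (generating value 0.2)")
print(f"Poisson log-likelihood at the MLE: {fit.log_likelihood:.1f} over {fit.n_routes} routes")
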