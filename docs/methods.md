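# Methods

## Models

**Gravity.** Expected trips between districts *i* and *j* are
T_ij = θ P_i^α P_j^β f(d_ij) with populations in raw person counts (θ absorbs
scale) and d_ij in kilometres. Two deterrence kernels are supported, both
decaying: power f(d) = d^-γ and exponential f(d) = exp(−d/D), D being the
deterrence distance in km. Larger α, β mean stronger pull of population;
larger γ (or smaller D) means sharper distance decay. The stratified
variants index (α, β, γ/D) by a trip category while θ remains global:
urbanicity (k = 1..4, ordered rural→rural, rural→urban, urban→rural,
urban→urban), regional (m = 1 intra-, 2 inter-regional), and
regional-urbanicity (n = 4·(m−1)+k, so n 1–4 are the intra-regional
urbanicity cells and 5–8 the inter-regional ones; this row-major ordering is
declared in every export). Within-district travel is never modelled: the OD
diagonal is structurally absent.

Sharing θ is an identifiability choice: with per-category exponents free, a
per-category proportionality constant would trade off against them through
the category's population levels.

**Radiation.** The finite-system form
T_ij = σ P_i (1 − P_i/P)^{-1} P_i P_j / [(P_i + s_ij)(P_i + P_j + s_ij)],
with P the total population and σ ∈ (0, 1] the travelling fraction per
period. The intervening population s_ij uses the cumulative centroid
definition: destinations are ranked by centroid distance from the origin
(ties broken by district order, deterministically) and s_ij sums the
populations of strictly nearer destinations. Polygon-overlap definitions
need boundary data that point geographies lack; the cumulative definition
also makes the normalization exact — each origin's predicted outflow
telescopes to σ·P_i, which the tests assert to 1e−10 relative. Urbanicity
and region play no role in this model.

**Likelihood.** Observed counts are independent Poisson draws,
m_ij ~ Pois(T_ij). Counts arriving as period averages may be non-integer;
they are rounded to the nearest integer before fitting (logged). Observed
zeros are genuine data and enter the likelihood; routes never observed at
all are structurally missing (absent rows in the long CSV, NaN internally)
and are excluded from it. Districts with no observed route in or out are
dropped before fitting, with a warning in the run log.

## Inference

All parameters get independent Gamma(shape, rate) priors, default
(0.001, 0.001) — effectively flat on the positive axis at the scales
involved while enforcing positivity (so α, β ≥ 0 and decay > 0 by prior
support). The sampler exploits model structure:

* θ (and the radiation σ) is conditionally conjugate: given the remaining
  parameters the likelihood is Poisson in a scale factor, so the full
  conditional is Gamma(shape + Σm, rate + Σu) with u the θ-free prediction.
  θ is additionally *collapsed* (integrated analytically) out of every
  Metropolis step, which removes the narrow posterior ridge between θ and
  the population exponents; it is re-drawn from its exact conditional each
  sweep. For the radiation model this conjugacy is the whole posterior, so
  σ draws are i.i.d. exact samples — still reported through the same
  FitResult/DIC machinery so its DIC is on the same scale as the gravity
  models'.
* Each category's (log α, log β, log decay) triple is a joint adaptive
  random-walk Metropolis block. Proposal covariances are seeded with the
  inverse observed Fisher information at the MLE (the Poisson log link makes
  the log-likelihood concave in the natural parameterization, so the
  L-BFGS-B optimum used for seeding is global), then adapted during burn-in
  with a diminishing Robbins–Monro step targeting 23.4% acceptance and
  frozen afterwards.
* One additional joint move per sweep proposes all blocks at once using the
  full Fisher covariance; this tracks the cross-category correlation that
  the shared θ induces, which per-block moves alone follow slowly.

Chains start at the MLE with per-chain jitter of about two posterior
standard deviations. Defaults: 2 chains, 2000 burn-in iterations, 5000
retained draws per chain after thinning by 5. Convergence is summarized by
R-hat and effective sample size (via arviz) for every parameter; R-hat above
the configured threshold (default 1.1) raises a logged warning stored in the
result, never silenced. Everything is reproducible from the single config
seed (chain streams are spawned from it).

On the synthetic benchmark at default settings, R-hat ≤ 1.01 and p_D matches
the free-parameter count (e.g. ≈ 25 for the 8-category model) — the tests
assert the recovery and DIC-ordering consequences rather than these
diagnostics themselves.

**Model comparison.** DIC = D̄ + p_D with Spiegelhalter's
p_D = D̄ − D(posterior means), computed from the recorded deviance trace
(−2 log-likelihood including the log m! terms, a model-independent constant
for fixed data). Ranking ties break toward fewer parameters. Percent change
vs the basic model is 100·(DIC_basic − DIC_model)/DIC_basic, so positive
values are improvements and a worse-than-basic model (typically radiation on
gravity-generated data) is negative. Ratio accuracy reports, per trip type,
the median of predicted/observed and the fraction of routes within a ±10%
margin (configurable); routes with observed zero have an undefined ratio and
are excluded but counted.

## Geography

Distances are haversine on a sphere of radius 6371.0 km between district
centroids. Urbanicity uses strict inequality (fraction > threshold ⇒ urban),
so a district exactly at the threshold is rural. Aggregation to coarser
units (for modifiable-areal-unit analyses) sums populations, takes
population-weighted centroids and urban fractions, sums member-pair trips,
and drops the trips that become within-unit. GeoJSON polygon input is
reduced to true area centroids (shapely), not vertex averages.

## Synthetic data

The generator emulates the structure of district-level trip matrices
aggregated from call-data records: region centres uniform in a lat/lon box
with district centroids jittered around them (so intra-regional distances
are stochastically smaller), log-normal populations (default median 5·10⁴,
log-sd 0.7) with one capital district inflated ×10, and urban status
assigned to the highest-population districts (a national share, or a fixed
count per region when every category of the 8-way scheme must be populated).
Trip counts are exact Poisson draws at the model's expected counts — pure
model noise, matching the fitting assumption.

Three canonical worlds are fixed: (a) *basic*, 30 districts with θ = 0.01,
α = 0.9, β = 0.7, γ = 1.5 (power); (b) *regional-urbanicity*, 24 districts
with decays 1.0–2.4 strictly increasing across the 8 categories
(intra-regional below inter-regional) and inter-regional exponents raised
just enough that every category's routes stay in the 10–10⁵ count range;
(c) *radiation*, 10 districts with populations near 10⁵ and σ = 0.2.
Default scales keep full five-model fits to a couple of minutes on one CPU.

What passing on these worlds does **not** show: the generator has no
overdispersion, no observation biases (phone ownership, tower coverage), no
seasonality, and urban status is perfectly correlated with population size —
all departures that real CDR-derived matrices exhibit. Recovery results here
validate the machinery, not the models' adequacy for any particular country.

## Numerical choices and edge cases

* Power kernel at zero distance between distinct districts is singular and
  rejected with a validation error; coincident centroids are only legal with
  a flat (γ = 0) kernel.
* Distance ties in the intervening-population ranking break by district
  order; the matrix is symmetrized exactly and its diagonal forced to zero.
* σ's closed-form MLE Σm/Σu is clipped to 1 in the rare case more trips are
  observed than people exist; the numeric bounded optimizer agrees with the
  closed form to 1e−8 and serves as a cross-check.
* Deviance at posterior means (for p_D) is evaluated by a full likelihood
  pass with the posterior-mean parameter vector, not by averaging the trace.
* Byte-identical reproducibility of pipeline outputs is part of the
  contract: chain CSVs are written with fixed float formatting and reports
  with sorted JSON keys.

## Limitations

Only Poisson observation noise (no negative-binomial option yet); no
covariate-augmented gravity variants or radiation extensions; no ensemble
combination of models; MCMC for the gravity models assumes every category
has at least one observed route (it errors otherwise rather than dropping
the category).
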