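# mobflux

Spatial-interaction models for district-level origin–destination (OD) trip
matrices: stratified gravity models, a finite-system radiation model,
Bayesian Poisson fitting with DIC model selection, and trip-type accuracy
evaluation.

## The problem

Epidemiologists, transport planners, and demographers often need estimates of
how many people travel between administrative districts when direct mobility
data (e.g. trip matrices aggregated from mobile-phone records) are
unavailable or unshareable. The workhorse is the **gravity model**: expected
trips from origin *i* to destination *j* scale with the two populations and
decay with distance,

```
T_ij = θ · P_i^α · P_j^β · f(d_ij),    f(d) = d^-γ  or  exp(-d/D)
```

A single parameter set, however, misses systematic structure in real travel —
trips within an administrative region behave differently from trips between
regions, and travel between predominantly rural districts differs from
travel involving urban ones. mobflux therefore fits **stratified** gravity
models in which (α, β, γ or D) vary by trip category:

| scheme | categories |
|---|---|
| basic | 1 (all trips pooled) |
| urbanicity | 4: rural→rural, rural→urban, urban→rural, urban→urban |
| regional | 2: intra-regional, inter-regional |
| regional-urbanicity | 8: the full cross product |

θ stays shared across categories (a per-category θ would not be identifiable
alongside per-category exponents). A district is "urban" when its urban
grid-cell fraction exceeds a threshold (0.5 by default, 0.1 as a sensitivity
setting).

The package also implements the **finite-system radiation model**, in which
flow from *i* to *j* depends on the intervening population s_ij (people
living closer to *i* than *j* does):

```
T_ij = σ P_i / (1 − P_i/P) · P_i P_j / [(P_i + s_ij)(P_i + P_j + s_ij)]
```

whose single parameter σ is the fraction of the total population P
travelling per unit period; each origin's expected outflow is exactly σ·P_i.

Observed counts are modelled as m_ij ~ Poisson(T_ij). Gravity parameters get
vague Gamma priors and are sampled by MCMC (conjugate Gibbs for θ, adaptive
block Metropolis for the per-category triples); σ's posterior is an exact
Gamma. Models are compared by the Deviance Information Criterion
DIC = D̄ + p_D with p_D = D̄ − D(posterior means), and by the fraction of
routes whose prediction falls within ±10% of the observed count, broken down
by trip type.

Because real OD matrices are usually proprietary, the package ships a
synthetic-data generator (clustered regions, log-normal populations with a
dominant capital, urban status concentrated in large districts, Poisson trip
counts from known parameters) so the whole pipeline is testable end to end.

## Worked example

```python
import mobflux as mf

config = mf.RunConfig(
    scenario="regional_urbanicity",      # synthetic world, 24 districts
    models=("basic", "urbanicity", "regional", "regional_urbanicity", "radiation"),
    mcmc=mf.MCMCConfig(chains=2, burn_in=800, samples=1000, thin=2),
    outdir="scratch/example_run", seed=11,
)
report, fits = mf.run_pipeline(config)
print(report.dic_table.to_string(index=False))
```

prints

```
 rank               model          dic       p_d  n_parameters  pct_change_vs_basic
    1 regional_urbanicity 3.832396e+03 24.346345            25            98.630094
    2          urbanicity 3.588751e+04 13.122475            13            87.171857
    3            regional 2.307255e+05  6.759552             7            17.526179
    4               basic 2.797561e+05  4.136261             4             0.000000
    5           radiation 2.053424e+06  1.016826             1          -634.005092
```

The data were generated from the regional-urbanicity model, and DIC selects
it: rank 1, with p_D ≈ 25 matching its 25 free parameters, and a 98.6% DIC
reduction relative to the basic model (positive %change = improvement;
the radiation model, misspecified here, is negative). Its posterior-mean
predictions land within ±10% of the observed count on 54% of routes, with a
median predicted/observed ratio of 1.004.

The `examples/` directory holds short narrative scripts, one per capability:
geography construction and aggregation, gravity forward prediction,
the radiation model, and the full fit-and-compare pipeline. A thin CLI
(`mobflux simulate | fit | evaluate | run-all`) wraps the same library calls
for shell use.

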