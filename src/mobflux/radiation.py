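"""Finite-system radiation model.

The radiation model is a parameter-light alternative to the gravity model:
the chance that a trip from origin i ends at destination j depends on the
population "intervening" between them — the total population s_ij living
closer to i than j does — rather than on distance directly. The finite-system
normalization makes each origin's expected outflow exactly sigma * P_i, where
sigma is the fraction of the total population travelling per unit period:

    T_ij = sigma * P_i / (1 - P_i / P) * P_i * P_j / ((P_i + s_ij) (P_i + P_j + s_ij))

s_ij here is the cumulative, centroid-based intervening population: the sum
of the populations of districts strictly closer to i than j (ties broken by
district order, deterministically). Under this definition the row sums
telescope to sigma * P_i exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .geography import Geography, ValidationError
from .trips import TripMatrix


@dataclass(frozen=True)
class RadiationParams:
    """sigma: fraction of the total population making a trip per unit period."""

    sigma: float

    def __post_init__(self) -> None:
        if not (0.0 < self.sigma <= 1.0):
            raise ValidationError(f"sigma must lie in (0, 1], got {self.sigma}")


def intervening_population(geo: Geography) -> np.ndarray:
    """s_ij: total population strictly closer to origin i than destination j.

    Cumulative/centroid definition: for each origin, destinations are ranked
    by centroid distance (distance ties broken by district order) and s is the
    running sum of populations of nearer destinations; the nearest destination
    has s = 0 and the farthest has s = P - P_i - P_j.
    """
    if geo.n < 2:
        raise ValidationError("intervening population needs at least 2 districts")
    n = geo.n
    P = geo.populations
    s = np.zeros((n, n))
    for i in range(n):
        others = np.array([j for j in range(n) if j != i])
        order = others[np.lexsort((others, geo.distance_matrix[i, others]))]
        cum = np.concatenate([[0.0], np.cumsum(P[order])[:-1]])
        s[i, order] = cum
    np.fill_diagonal(s, 0.0)
    return s


def radiation_predict(
    params: RadiationParams, geo: Geography, s: np.ndarray | None = None
) -> TripMatrix:
    """Expected trips under the finite-system radiation model (diagonal absent)."""
    if s is None:
        s = intervening_population(geo)
    if s.shape != (geo.n, geo.n):
        raise ValidationError("intervening-population matrix does not match geography")
    P = geo.populations
    total = geo.total_population
    if np.any(P >= total):
        raise ValidationError("an origin holding the entire population makes the normalization degenerate")
    Pi = P[:, None]
    Pj = P[None, :]
    T = params.sigma * Pi / (1.0 - Pi / total) * Pi * Pj / ((Pi + s) * (Pi + Pj + s))
    np.fill_diagonal(T, np.nan)
    return TripMatrix(list(geo.ids), T)


@dataclass(frozen=True)
class RadiationFit:
    params: RadiationParams
    log_likelihood: float
    deviance: float
    n_routes: int
    total_observed: float
    total_unit_prediction: float


def fit_radiation(obs: TripMatrix, geo: Geography) -> RadiationFit:
    """Poisson maximum-likelihood fit of sigma.

    The likelihood is m_ij ~ Pois(sigma * u_ij), with u_ij the unit-sigma
    prediction, so the MLE has the closed form sigma_hat = sum(m) / sum(u)
    over observed routes. Routes with no observation are excluded.
    """
    obs = obs.align_to(geo.ids)
    unit = radiation_predict(RadiationParams(1.0), geo).values
    mask = obs.observed_mask
    m = np.round(obs.values[mask])
    u = unit[mask]
    if m.size == 0 or m.sum() <= 0:
        raise ValidationError("sigma is undefined for an all-zero or empty trip matrix")
    sigma_hat = float(m.sum() / u.sum())
    ll = float(np.sum(stats.poisson.logpmf(m.astype(int), sigma_hat * u)))
    return RadiationFit(
        params=RadiationParams(min(sigma_hat, 1.0)),
        log_likelihood=ll,
        deviance=-2.0 * ll,
        n_routes=int(m.size),
        total_observed=float(m.sum()),
        total_unit_prediction=float(u.sum()),
    )


def fit_radiation_numeric(obs: TripMatrix, geo: Geography) -> float:
    """sigma by bounded scalar optimization of the Poisson likelihood (cross-check)."""
    obs = obs.align_to(geo.ids)
    unit = radiation_predict(RadiationParams(1.0), geo).values
    mask = obs.observed_mask
    m = np.round(obs.values[mask])
    u = unit[mask]

    def nll(sigma: float) -> float:
        lam = sigma * u
        return float(-(np.sum(m * np.log(lam) - lam)))

    res = optimize.minimize_scalar(nll, bounds=(1e-12, 1.0), method="bounded",
                                   options={"xatol": 1e-12})
    return float(res.x)
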