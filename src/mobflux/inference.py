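"""Bayesian fitting of spatial-interaction models to observed trip counts.

Observed origin-destination counts m_ij are modelled as independent Poisson
draws around the model's expected counts, m_ij ~ Pois(T_ij), and all
parameters receive vague Gamma(shape, rate) priors (default 0.001, 0.001),
which keeps them positive while being nearly flat on the scales involved.

The sampler exploits the model's structure:

* theta (and the radiation model's sigma) is conditionally conjugate — for
  fixed remaining parameters the likelihood is Poisson in a scale factor, so
  its full conditional is an exact Gamma and is Gibbs-sampled;
* each trip category's (alpha, beta, decay) triple is updated jointly by an
  adaptive random-walk Metropolis step on the log scale, with the proposal
  covariance adapted to the block's posterior geometry during burn-in and
  frozen afterwards.

Chains are initialized at the (global) maximum-likelihood estimate — the
Poisson log-likelihood is concave in the natural parameterization, so the
MLE found by L-BFGS-B is global — with per-chain jitter, and the Gelman-Rubin
R-hat plus effective sample sizes are reported for every parameter.

Deviance (-2 log-likelihood, including the log m! terms) is recorded for
every retained draw; model comparison uses the Deviance Information
Criterion DIC = D_bar + p_D with the Spiegelhalter effective parameter count
p_D = D_bar - D(posterior means).
"""

from __future__ import annotations

import json
import logging
import warnings as _warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
import yaml
from scipy import optimize
from scipy.special import gammaln

from .geography import Geography, ValidationError
from .gravity import GravityParams, count_parameters, gravity_predict
from .radiation import RadiationParams, radiation_predict
from .trips import TripMatrix
from .typology import SCHEME_CATEGORIES, TripTypology

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# likelihood


def poisson_log_likelihood(pred: TripMatrix, obs: TripMatrix) -> float:
    """Poisson log-likelihood of observed counts under predicted expected counts.

    Summed over routes observed in ``obs`` (structurally missing routes and
    the diagonal contribute nothing). Returns ``-inf`` if any observed
    positive count sits on a zero prediction.
    """
    if pred.ids != obs.ids:
        pred = pred.align_to(obs.ids)
    mask = obs.observed_mask
    m = obs.values[mask]
    lam = pred.values[mask]
    if np.any(m < 0):
        raise ValidationError("observed counts must be non-negative")
    if np.any(~np.isfinite(lam)) or np.any(lam < 0):
        raise ValidationError("predictions must be finite and non-negative on observed routes")
    if np.any((lam == 0) & (m > 0)):
        return float("-inf")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(m > 0, m * np.log(lam), 0.0) - lam - gammaln(m + 1.0)
    return float(terms.sum())


# ---------------------------------------------------------------------------
# configuration and results


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler settings. ``samples`` counts retained draws per chain after thinning."""

    chains: int = 2
    burn_in: int = 2000
    samples: int = 5000
    thin: int = 5
    seed: int = 42
    prior_shape: float = 0.001
    prior_rate: float = 0.001
    rhat_threshold: float = 1.1

    def __post_init__(self) -> None:
        if self.chains < 1 or self.samples < 1 or self.thin < 1 or self.burn_in < 0:
            raise ValidationError("invalid MCMC configuration")

    @classmethod
    def from_yaml(cls, path) -> "MCMCConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


class DIC(NamedTuple):
    dic: float
    p_d: float
    mean_deviance: float


def compute_dic(deviance_trace: np.ndarray, deviance_at_posterior_mean: float) -> DIC:
    """Spiegelhalter DIC from a deviance trace and the deviance at posterior means.

    D_bar = mean of the trace; p_D = D_bar - D(posterior means);
    DIC = D_bar + p_D.
    """
    trace = np.asarray(deviance_trace, dtype=float).ravel()
    if trace.size == 0:
        raise ValidationError("empty deviance trace")
    if not (np.all(np.isfinite(trace)) and np.isfinite(deviance_at_posterior_mean)):
        raise ValidationError("non-finite deviance")
    d_bar = float(trace.mean())
    p_d = d_bar - float(deviance_at_posterior_mean)
    return DIC(dic=d_bar + p_d, p_d=p_d, mean_deviance=d_bar)


@dataclass
class FitResult:
    """Posterior draws, deviance trace, DIC, and diagnostics for one model fit."""

    model: str  # "gravity" | "radiation"
    scheme: str
    kernel: str
    param_names: list[str]
    draws: dict[str, np.ndarray]  # each (chains, samples)
    deviance: np.ndarray  # (chains, samples)
    posterior_means: dict[str, float]
    posterior_medians: dict[str, float]
    dic: float
    p_d: float
    mean_deviance: float
    deviance_at_means: float
    rhat: dict[str, float]
    ess: dict[str, float]
    n_parameters: int
    config: MCMCConfig
    data_n_routes: int
    data_total: float
    warnings: list[str] = field(default_factory=list)

    @property
    def label(self) -> str:
        return self.scheme if self.model == "gravity" else "radiation"

    def params(self):
        """Point parameters (posterior means) as a GravityParams / RadiationParams."""
        if self.model == "radiation":
            return RadiationParams(min(self.posterior_means["sigma"], 1.0))
        C = SCHEME_CATEGORIES[self.scheme]
        get = lambda nm: np.array([self.posterior_means[f"{nm}[{c + 1}]"] for c in range(C)])
        return GravityParams(
            theta=self.posterior_means["theta"],
            alpha=get("alpha"), beta=get("beta"), decay=get("decay"),
            kernel=self.kernel, scheme=self.scheme,
        )

    def save(self, outdir) -> None:
        """JSON metadata plus one CSV of draws per chain."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        meta = {
            "model": self.model,
            "scheme": self.scheme,
            "kernel": self.kernel,
            "param_names": self.param_names,
            "posterior_means": self.posterior_means,
            "posterior_medians": self.posterior_medians,
            "dic": self.dic,
            "p_d": self.p_d,
            "mean_deviance": self.mean_deviance,
            "deviance_at_means": self.deviance_at_means,
            "rhat": self.rhat,
            "ess": self.ess,
            "n_parameters": self.n_parameters,
            "config": asdict(self.config),
            "data_n_routes": self.data_n_routes,
            "data_total": self.data_total,
            "warnings": self.warnings,
        }
        (outdir / "meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
        for c in range(self.deviance.shape[0]):
            df = pd.DataFrame({nm: self.draws[nm][c] for nm in self.param_names})
            df["deviance"] = self.deviance[c]
            df.to_csv(outdir / f"chain_{c + 1:02d}.csv", index=False, float_format="%.12g")

    @classmethod
    def load(cls, outdir) -> "FitResult":
        outdir = Path(outdir)
        meta = json.loads((outdir / "meta.json").read_text())
        chain_files = sorted(outdir.glob("chain_*.csv"))
        frames = [pd.read_csv(f) for f in chain_files]
        names = meta["param_names"]
        draws = {nm: np.stack([f[nm].to_numpy() for f in frames]) for nm in names}
        dev = np.stack([f["deviance"].to_numpy() for f in frames])
        return cls(
            model=meta["model"], scheme=meta["scheme"], kernel=meta["kernel"],
            param_names=names, draws=draws, deviance=dev,
            posterior_means=meta["posterior_means"],
            posterior_medians=meta["posterior_medians"],
            dic=meta["dic"], p_d=meta["p_d"],
            mean_deviance=meta["mean_deviance"],
            deviance_at_means=meta["deviance_at_means"],
            rhat=meta["rhat"], ess=meta["ess"],
            n_parameters=meta["n_parameters"],
            config=MCMCConfig(**meta["config"]),
            data_n_routes=meta["data_n_routes"], data_total=meta["data_total"],
            warnings=meta["warnings"],
        )


# ---------------------------------------------------------------------------
# data preparation


class _PairData(NamedTuple):
    m: np.ndarray        # observed counts (ints as float)
    log_po: np.ndarray   # log origin population
    log_pd: np.ndarray   # log destination population
    dist: np.ndarray     # km
    cat: np.ndarray      # 0-based category per pair
    n_cat: int
    log_fact: float      # sum of log(m!)


def _prepare_pairs(obs: TripMatrix, geo: Geography, typology: TripTypology, scheme: str) -> _PairData:
    obs = obs.align_to(geo.ids).rounded()
    mask = obs.observed_mask
    if not mask.any():
        raise ValidationError("no observed routes to fit")
    cat_matrix = typology.index_for_scheme(scheme)
    i, j = np.where(mask)
    P = geo.populations
    d = geo.distance_matrix[i, j]
    if np.any(d <= 0):
        raise ValidationError("observed routes include zero-distance district pairs")
    m = obs.values[i, j]
    return _PairData(
        m=m,
        log_po=np.log(P[i]),
        log_pd=np.log(P[j]),
        dist=d,
        cat=cat_matrix[i, j],
        n_cat=SCHEME_CATEGORIES[scheme],
        log_fact=float(gammaln(m + 1.0).sum()),
    )


# ---------------------------------------------------------------------------
# maximum likelihood (concave natural parameterization)


def fit_gravity_mle(
    obs: TripMatrix,
    geo: Geography,
    typology: TripTypology,
    scheme: str = "basic",
    kernel: str = "power",
) -> tuple[GravityParams, float]:
    """Poisson maximum-likelihood gravity fit by direct numeric optimization.

    In the natural parameterization (log theta; per-category alpha, beta, and
    gamma or 1/D) the log link makes the Poisson log-likelihood concave, so
    the optimum is global. Returns the parameters and the maximized
    log-likelihood (including log m! terms).
    """
    data = _prepare_pairs(obs, geo, typology, scheme)
    C = data.n_cat
    dcov = np.log(data.dist) if kernel == "power" else data.dist
    cat_mask = [data.cat == c for c in range(C)]

    def unpack(x):
        return x[0], x[1:1 + C], x[1 + C:1 + 2 * C], x[1 + 2 * C:]

    def eta(x):
        log_theta, a, b, g = unpack(x)
        return log_theta + a[data.cat] * data.log_po + b[data.cat] * data.log_pd - g[data.cat] * dcov

    def negloglik(x):
        e = eta(x)
        return float(np.sum(np.exp(e)) - np.sum(data.m * e))

    def grad(x):
        r = data.m - np.exp(eta(x))  # residuals
        g = np.empty(1 + 3 * C)
        g[0] = -r.sum()
        for c in range(C):
            rc = r[cat_mask[c]]
            g[1 + c] = -np.sum(rc * data.log_po[cat_mask[c]])
            g[1 + C + c] = -np.sum(rc * data.log_pd[cat_mask[c]])
            g[1 + 2 * C + c] = np.sum(rc * dcov[cat_mask[c]])
        return g

    # start: unit exponents, unit decay coefficient, theta matched to totals
    x0 = np.concatenate([[0.0], np.ones(C), np.ones(C), np.full(C, 1.0 if kernel == "power" else 1.0 / max(data.dist.mean(), 1e-9))])
    x0[0] = np.log(data.m.sum()) - np.log(np.sum(np.exp(eta(x0) - x0[0])))
    bounds = [(None, None)] + [(0.0, None)] * (2 * C) + [(1e-12 if kernel == "exponential" else 0.0, None)] * C
    res = optimize.minimize(negloglik, x0, jac=grad, method="L-BFGS-B", bounds=bounds,
                            options={"maxiter": 2000, "ftol": 1e-12, "gtol": 1e-10})
    log_theta, a, b, g = unpack(res.x)
    decay = g if kernel == "power" else 1.0 / np.maximum(g, 1e-12)
    params = GravityParams(theta=float(np.exp(log_theta)), alpha=a, beta=b, decay=decay,
                           kernel=kernel, scheme=scheme)
    ll = -res.fun - data.log_fact
    return params, float(ll)


# ---------------------------------------------------------------------------
# MCMC


def _deviance(theta: float, eta: np.ndarray, data: _PairData) -> float:
    lam_sum = float(np.exp(eta).sum())
    return -2.0 * (float(np.sum(data.m * (np.log(theta) + eta))) - theta * lam_sum - data.log_fact)


def _proposal_covariances(data: _PairData, kernel: str, params: GravityParams):
    """Proposal covariances for the log-scale (alpha, beta, decay) parameters.

    Inverse observed Fisher information at the MLE in the natural
    parameterization (Poisson GLM: I = X' diag(lam) X), with theta
    marginalized out, mapped to the log scale by the delta method. Returns
    the full (3C, 3C) covariance (category-major order) and its per-category
    3x3 diagonal blocks; both seed the adaptive proposals.
    """
    C = params.n_categories
    dcov = np.log(data.dist) if kernel == "power" else data.dist
    natural = np.stack([
        params.alpha,
        params.beta,
        params.decay if kernel == "power" else 1.0 / params.decay,
    ], axis=1)  # (C, 3)
    X = np.zeros((data.m.size, 1 + 3 * C))
    X[:, 0] = 1.0
    rows = np.arange(data.m.size)
    X[rows, 1 + 3 * data.cat] = data.log_po
    X[rows, 2 + 3 * data.cat] = data.log_pd
    X[rows, 3 + 3 * data.cat] = -dcov
    a, b, g = natural[data.cat].T
    lam = params.theta * np.exp(a * data.log_po + b * data.log_pd - g * dcov)
    H = (X * lam[:, None]).T @ X
    cov = np.linalg.pinv(H + 1e-10 * np.eye(H.shape[0]))[1:, 1:]  # theta marginalized
    safe = np.clip(np.abs(natural), 1e-6, None).ravel()
    full = cov / np.outer(safe, safe)
    w, V = np.linalg.eigh((full + full.T) / 2.0)
    full = (V * np.clip(w, 1e-14, None)) @ V.T
    blocks = np.empty((C, 3, 3))
    for c in range(C):
        idx = slice(3 * c, 3 * c + 3)
        block = full[idx, idx]
        w, V = np.linalg.eigh((block + block.T) / 2.0)
        blocks[c] = (V * np.clip(w, 1e-14, None)) @ V.T
    return full, blocks


def _run_gravity_chain(
    data: _PairData,
    kernel: str,
    cfg: MCMCConfig,
    rng: np.random.Generator,
    y_init: np.ndarray,  # (C, 3) log-scale block starts
    cov_init: np.ndarray | None = None,  # (C, 3, 3) proposal covariance seeds
    cov_full: np.ndarray | None = None,  # (3C, 3C) joint proposal covariance
):
    """One chain: collapsed adaptive block Metropolis per category, Gibbs for theta.

    theta is integrated out of the block updates analytically (its Gamma
    prior is conjugate to the Poisson likelihood), which removes the narrow
    posterior ridge between theta and the exponents; it is then drawn from
    its exact Gamma full conditional each iteration.
    """
    C = data.n_cat
    dcov = np.log(data.dist) if kernel == "power" else None
    cat_idx = [np.where(data.cat == c)[0] for c in range(C)]
    k0, r0 = cfg.prior_shape, cfg.prior_rate
    m_sum = float(data.m.sum())

    y = y_init.copy()  # rows: (log alpha, log beta, log decay)

    def block_eta(c, yc):
        a, b, g = np.exp(yc)
        idx = cat_idx[c]
        if kernel == "power":
            kern = -g * dcov[idx]
        else:
            kern = -data.dist[idx] / g
        return a * data.log_po[idx] + b * data.log_pd[idx] + kern

    etas = [block_eta(c, y[c]) for c in range(C)]
    u_sums = np.array([np.exp(e).sum() for e in etas])
    m_etas = np.array([float(np.sum(data.m[cat_idx[c]] * etas[c])) for c in range(C)])

    def log_prior(yc):  # Gamma prior on each positive parameter + log Jacobian
        return float(np.sum(k0 * yc - r0 * np.exp(yc)))

    # adaptive proposal state per block
    scale = np.full(C, 2.38 / np.sqrt(3.0))
    mean_y = y.copy()
    if cov_init is None:
        cov_y = np.tile(np.eye(3) * 1e-4, (C, 1, 1))
    else:
        cov_y = cov_init.copy()
    chol = np.linalg.cholesky(cov_y + 1e-12 * np.eye(3))

    post_shape = k0 + m_sum  # shape of theta's full conditional / collapsed exponent

    # joint move across all blocks: captures the cross-category correlation
    # that theta induces, which per-block moves cannot follow
    if cov_full is None:
        cov_full = np.eye(3 * C) * 1e-4
    chol_full = np.linalg.cholesky(cov_full + 1e-14 * np.eye(3 * C))
    scale_full = 2.38 / np.sqrt(3.0 * C)

    n_iter = cfg.burn_in + cfg.samples * cfg.thin
    keep_theta = np.empty(cfg.samples)
    keep_y = np.empty((cfg.samples, C, 3))
    keep_dev = np.empty(cfg.samples)
    kept = 0
    accepts = np.zeros(C)

    for t in range(n_iter):
        adapting = t < cfg.burn_in
        for c in range(C):
            z = rng.standard_normal(3)
            y_prop = y[c] + scale[c] * (chol[c] @ z)
            eta_prop = block_eta(c, y_prop)
            u_prop = float(np.exp(eta_prop).sum())
            m_eta_prop = float(np.sum(data.m[cat_idx[c]] * eta_prop))
            u_total_old = u_sums.sum()
            u_total_new = u_total_old - u_sums[c] + u_prop
            # collapsed (theta-marginal) likelihood ratio
            log_acc = (
                (m_eta_prop - m_etas[c])
                - post_shape * (np.log(r0 + u_total_new) - np.log(r0 + u_total_old))
                + log_prior(y_prop) - log_prior(y[c])
            )
            if np.log(rng.uniform()) < log_acc:
                y[c] = y_prop
                etas[c] = eta_prop
                u_sums[c] = u_prop
                m_etas[c] = m_eta_prop
                accepts[c] += 1
                acc = 1.0
            else:
                acc = 0.0
            if adapting:
                # Robbins-Monro on scale toward 0.234, running covariance on y;
                # the diminishing step keeps the seeded covariance from being
                # swamped by early samples
                step = (t + 10.0) ** -0.6
                scale[c] *= np.exp(step * (acc - 0.234))
                delta = y[c] - mean_y[c]
                mean_y[c] += step * delta
                cov_y[c] = (1 - step) * cov_y[c] + step * np.outer(delta, delta)
                ridge = max(1e-12, 1e-9 * np.trace(cov_y[c]) / 3.0)
                chol[c] = np.linalg.cholesky(cov_y[c] + ridge * np.eye(3))
        # joint move over all (alpha, beta, decay) blocks
        z = rng.standard_normal(3 * C)
        y_prop_all = y + (scale_full * (chol_full @ z)).reshape(C, 3)
        etas_prop = [block_eta(c, y_prop_all[c]) for c in range(C)]
        u_prop_all = np.array([float(np.exp(e).sum()) for e in etas_prop])
        m_etas_prop = np.array([
            float(np.sum(data.m[cat_idx[c]] * etas_prop[c])) for c in range(C)
        ])
        log_acc = (
            (m_etas_prop.sum() - m_etas.sum())
            - post_shape * (np.log(r0 + u_prop_all.sum()) - np.log(r0 + u_sums.sum()))
            + sum(log_prior(y_prop_all[c]) - log_prior(y[c]) for c in range(C))
        )
        acc_full = 0.0
        if np.log(rng.uniform()) < log_acc:
            y = y_prop_all
            etas = etas_prop
            u_sums = u_prop_all
            m_etas = m_etas_prop
            acc_full = 1.0
        if adapting:
            scale_full *= np.exp((t + 10.0) ** -0.6 * (acc_full - 0.234))

        theta = float(rng.gamma(post_shape, 1.0 / (r0 + u_sums.sum())))

        if t >= cfg.burn_in and (t - cfg.burn_in) % cfg.thin == cfg.thin - 1:
            keep_theta[kept] = theta
            keep_y[kept] = y
            keep_dev[kept] = -2.0 * (
                float(np.sum(data.m)) * np.log(theta) + m_etas.sum()
                - theta * u_sums.sum() - data.log_fact
            )
            kept += 1

    return keep_theta, np.exp(keep_y), keep_dev, accepts / n_iter


def _diagnostics(draws: dict[str, np.ndarray]):
    """R-hat and bulk ESS per parameter via arviz."""
    import arviz as az

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        idata = az.from_dict(posterior={k: v for k, v in draws.items()})
        rhat_ds = az.rhat(idata)
        ess_ds = az.ess(idata)
    rhat = {k: float(rhat_ds[k].values) for k in draws}
    ess = {k: float(ess_ds[k].values) for k in draws}
    return rhat, ess


def fit_gravity(
    obs: TripMatrix,
    geo: Geography,
    typology: TripTypology,
    scheme: str = "basic",
    kernel: str = "power",
    config: MCMCConfig | None = None,
) -> FitResult:
    """Bayesian gravity-model fit: Poisson likelihood, vague Gamma priors, MCMC.

    Chains start from the (global) MLE with per-chain log-scale jitter;
    theta is Gibbs-sampled from its exact Gamma full conditional and each
    category's (alpha, beta, decay) block is updated by adaptive Metropolis.
    Reproducible given ``config.seed``.
    """
    cfg = config or MCMCConfig()
    if scheme not in SCHEME_CATEGORIES:
        raise ValidationError(f"unknown scheme {scheme!r}")
    data = _prepare_pairs(obs, geo, typology, scheme)
    C = data.n_cat
    empty = [c + 1 for c in range(C) if not np.any(data.cat == c)]
    if empty:
        raise ValidationError(f"scheme {scheme!r}: no observed routes in categories {empty}")

    mle, _ = fit_gravity_mle(obs, geo, typology, scheme, kernel)
    y_mle = np.log(np.clip(np.stack([mle.alpha, mle.beta, mle.decay], axis=1), 1e-6, None))
    cov_full, cov0 = _proposal_covariances(data, kernel, mle)
    chol0 = np.linalg.cholesky(cov0 + 1e-12 * np.eye(3))

    ss = np.random.SeedSequence(cfg.seed)
    chain_seeds = ss.spawn(cfg.chains)
    thetas, parblocks, devs = [], [], []
    for c_seed in chain_seeds:
        rng = np.random.default_rng(c_seed)
        # overdispersed starts: ~2 posterior standard deviations around the MLE
        jitter = 2.0 * np.einsum("cij,cj->ci", chol0, rng.standard_normal((C, 3)))
        th, pb, dv, acc = _run_gravity_chain(data, kernel, cfg, rng, y_mle + jitter, cov0, cov_full)
        thetas.append(th)
        parblocks.append(pb)
        devs.append(dv)
        logger.debug("chain block acceptance rates: %s", np.round(acc, 3))

    theta_draws = np.stack(thetas)                       # (chains, samples)
    blocks = np.stack(parblocks)                         # (chains, samples, C, 3)
    deviance = np.stack(devs)

    # stable, readable ordering: theta, then per-category (alpha, beta, decay)
    names = ["theta"] + [f"{nm}[{c + 1}]" for c in range(C) for nm in ("alpha", "beta", "decay")]
    draws = {"theta": theta_draws}
    for c in range(C):
        for ni, nm in enumerate(("alpha", "beta", "decay")):
            draws[f"{nm}[{c + 1}]"] = blocks[:, :, c, ni]

    post_mean = {nm: float(draws[nm].mean()) for nm in names}
    post_med = {nm: float(np.median(draws[nm])) for nm in names}

    mean_params = GravityParams(
        theta=post_mean["theta"],
        alpha=np.array([post_mean[f"alpha[{c + 1}]"] for c in range(C)]),
        beta=np.array([post_mean[f"beta[{c + 1}]"] for c in range(C)]),
        decay=np.array([post_mean[f"decay[{c + 1}]"] for c in range(C)]),
        kernel=kernel, scheme=scheme,
    )
    pred = gravity_predict(mean_params, geo, typology)
    d_at_means = -2.0 * poisson_log_likelihood(pred, obs.align_to(geo.ids).rounded())
    dic = compute_dic(deviance, d_at_means)

    rhat, ess = _diagnostics(draws)
    warns = []
    bad = {k: v for k, v in rhat.items() if np.isfinite(v) and v > cfg.rhat_threshold}
    if bad:
        msg = f"convergence warning: R-hat above {cfg.rhat_threshold} for {sorted(bad)}"
        logger.warning(msg)
        warns.append(msg)

    return FitResult(
        model="gravity", scheme=scheme, kernel=kernel,
        param_names=names, draws=draws, deviance=deviance,
        posterior_means=post_mean, posterior_medians=post_med,
        dic=dic.dic, p_d=dic.p_d, mean_deviance=dic.mean_deviance,
        deviance_at_means=float(d_at_means),
        rhat=rhat, ess=ess,
        n_parameters=count_parameters(mean_params),
        config=cfg,
        data_n_routes=int(data.m.size), data_total=float(data.m.sum()),
        warnings=warns,
    )


def fit_radiation_bayes(
    obs: TripMatrix,
    geo: Geography,
    config: MCMCConfig | None = None,
) -> FitResult:
    """Bayesian radiation fit: sigma's posterior is an exact Gamma (conjugate).

    With m_ij ~ Pois(sigma u_ij) and a Gamma(shape, rate) prior, the posterior
    is Gamma(shape + sum m, rate + sum u); draws are taken i.i.d. from it so
    the resulting DIC is directly comparable with the gravity models'.
    """
    cfg = config or MCMCConfig()
    obs_a = obs.align_to(geo.ids).rounded()
    unit = radiation_predict(RadiationParams(1.0), geo).values
    mask = obs_a.observed_mask
    m = obs_a.values[mask]
    u = unit[mask]
    if m.sum() <= 0:
        raise ValidationError("sigma is undefined for an all-zero trip matrix")
    shape = cfg.prior_shape + m.sum()
    rate = cfg.prior_rate + u.sum()
    log_fact = float(gammaln(m + 1.0).sum())
    m_logu = float(np.sum(m * np.log(u)))

    rng_chains = np.random.SeedSequence(cfg.seed).spawn(cfg.chains)
    sig = np.stack([
        np.random.default_rng(s).gamma(shape, 1.0 / rate, size=cfg.samples)
        for s in rng_chains
    ])
    deviance = -2.0 * (m.sum() * np.log(sig) + m_logu - sig * u.sum() - log_fact)

    post_mean = {"sigma": float(sig.mean())}
    post_med = {"sigma": float(np.median(sig))}
    d_at_means = float(-2.0 * (m.sum() * np.log(post_mean["sigma"]) + m_logu
                               - post_mean["sigma"] * u.sum() - log_fact))
    dic = compute_dic(deviance, d_at_means)
    rhat, ess = _diagnostics({"sigma": sig})

    return FitResult(
        model="radiation", scheme="radiation", kernel="none",
        param_names=["sigma"], draws={"sigma": sig}, deviance=deviance,
        posterior_means=post_mean, posterior_medians=post_med,
        dic=dic.dic, p_d=dic.p_d, mean_deviance=dic.mean_deviance,
        deviance_at_means=d_at_means,
        rhat=rhat, ess=ess,
        n_parameters=1,
        config=cfg,
        data_n_routes=int(m.size), data_total=float(m.sum()),
        warnings=[],
    )


def credible_interval(fit: FitResult, name: str, level: float = 0.95) -> tuple[float, float]:
    """Equal-tailed posterior credible interval for one parameter."""
    x = fit.draws[name].ravel()
    lo = (1.0 - level) / 2.0
    return float(np.quantile(x, lo)), float(np.quantile(x, 1.0 - lo))
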