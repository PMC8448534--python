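import math

import numpy as np
import pytest
from scipy import optimize, stats

import mobflux as mf
from mobflux.inference import DIC
from tests.conftest import make_district, random_geography


def matrix(ids, cells):
    n = len(ids)
    v = np.full((n, n), np.nan)
    for (i, j), x in cells.items():
        v[i, j] = x
    return mf.TripMatrix(ids, v)


class TestPoissonLogLikelihood:
    def test_single_zero_count_unit_mean(self):
        pred = matrix(["a", "b"], {(0, 1): 1.0})
        obs = matrix(["a", "b"], {(0, 1): 0.0})
        assert mf.poisson_log_likelihood(pred, obs) == pytest.approx(-1.0)

    def test_maximized_when_prediction_equals_observation(self):
        obs = matrix(["a", "b"], {(0, 1): 7.0})
        at_m = mf.poisson_log_likelihood(matrix(["a", "b"], {(0, 1): 7.0}), obs)
        for lam in (5.0, 6.9, 7.1, 9.0):
            assert mf.poisson_log_likelihood(matrix(["a", "b"], {(0, 1): lam}), obs) < at_m

    def test_matches_per_cell_series_oracle(self):
        rng = np.random.default_rng(5)
        ids = [f"d{i}" for i in range(5)]
        n = len(ids)
        lam = np.full((n, n), np.nan)
        m = np.full((n, n), np.nan)
        off = ~np.eye(n, dtype=bool)
        lam[off] = rng.uniform(0.5, 20.0, off.sum())
        m[off] = rng.integers(0, 30, off.sum()).astype(float)
        # independent oracle: explicit series for log(m!) and direct summation
        want = 0.0
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                log_fact = sum(math.log(r) for r in range(1, int(m[i, j]) + 1))
                want += m[i, j] * math.log(lam[i, j]) - lam[i, j] - log_fact
        got = mf.poisson_log_likelihood(mf.TripMatrix(ids, lam), mf.TripMatrix(ids, m))
        assert got == pytest.approx(want, rel=1e-12)

    def test_zero_prediction_with_positive_count_is_minus_inf(self):
        pred = matrix(["a", "b"], {(0, 1): 0.0})
        obs = matrix(["a", "b"], {(0, 1): 3.0})
        assert mf.poisson_log_likelihood(pred, obs) == -np.inf

    def test_invariant_to_district_ordering(self, benchmark_suite):
        sc = benchmark_suite["basic"]
        typ = mf.build_typology(sc.geography)
        pred = mf.gravity_predict(sc.true_params, sc.geography, typ)
        ll = mf.poisson_log_likelihood(pred, sc.trips.rounded())
        order = list(reversed(sc.geography.ids))
        ll2 = mf.poisson_log_likelihood(pred.align_to(order), sc.trips.rounded().align_to(order))
        assert ll == pytest.approx(ll2, rel=1e-12)


class TestDIC:
    def test_constant_trace_has_zero_complexity(self):
        out = mf.compute_dic(np.array([4.0, 4.0, 4.0]), 4.0)
        assert out == DIC(dic=4.0, p_d=0.0, mean_deviance=4.0)

    def test_two_point_trace_arithmetic(self):
        out = mf.compute_dic(np.array([2.0, 4.0]), 2.0)
        assert out.mean_deviance == pytest.approx(3.0)
        assert out.p_d == pytest.approx(1.0)
        assert out.dic == pytest.approx(4.0)

    def test_non_finite_deviance_rejected(self):
        with pytest.raises(mf.ValidationError):
            mf.compute_dic(np.array([np.inf, 2.0]), 2.0)

    def test_conjugate_gamma_poisson_toy_matches_sampling_oracle(self):
        """Two-district radiation fit vs a brute-force posterior-sampling DIC."""
        geo = mf.build_geography([
            make_district(1, pop=400.0, lat=0.0), make_district(2, pop=600.0, lat=1.0),
        ])
        obs = matrix(geo.ids, {(0, 1): 90.0, (1, 0): 110.0})
        cfg = mf.MCMCConfig(chains=2, samples=20000, seed=3)
        fit = mf.fit_radiation_bayes(obs, geo, cfg)
        # oracle: known conjugate posterior Gamma(a + sum m, b + sum u); u_ij = P_i
        u = geo.populations.sum()  # unit-sigma outflow sums to P_i per origin
        a_post, b_post = cfg.prior_shape + 200.0, cfg.prior_rate + u
        draws = stats.gamma(a_post, scale=1.0 / b_post).rvs(40000, random_state=7)
        m = np.array([90.0, 110.0])
        uu = geo.populations  # unit-sigma prediction u_ij equals the origin population
        dev = -2.0 * np.sum(stats.poisson.logpmf(m.astype(int)[None, :], draws[:, None] * uu[None, :]), axis=1)
        post_mean = a_post / b_post
        d_hat = -2.0 * np.sum(stats.poisson.logpmf(m.astype(int), post_mean * uu))
        want = mf.compute_dic(dev, d_hat)
        assert fit.dic == pytest.approx(want.dic, abs=0.1)
        assert fit.p_d == pytest.approx(want.p_d, abs=0.05)


@pytest.fixture(scope="module")
def small_fit(benchmark_suite):
    sc = benchmark_suite["basic"]
    typ = mf.build_typology(sc.geography)
    cfg = mf.MCMCConfig(chains=2, burn_in=500, samples=500, thin=2, seed=11)
    fit = mf.fit_gravity(sc.trips, sc.geography, typ, "basic", "power", cfg)
    return sc, typ, cfg, fit


class TestFitGravity:
    def test_same_seed_reproduces_chains_exactly(self, small_fit):
        sc, typ, cfg, fit = small_fit
        fit2 = mf.fit_gravity(sc.trips, sc.geography, typ, "basic", "power", cfg)
        for nm in fit.param_names:
            assert np.array_equal(fit.draws[nm], fit2.draws[nm])
        assert np.array_equal(fit.deviance, fit2.deviance)

    def test_posterior_concentrates_near_generating_values(self, small_fit):
        sc, typ, cfg, fit = small_fit
        true = {"theta": 0.01, "alpha[1]": 0.9, "beta[1]": 0.7, "decay[1]": 1.5}
        for nm, val in true.items():
            assert fit.posterior_means[nm] == pytest.approx(val, rel=0.05)

    def test_posterior_mean_tracks_mle(self, small_fit):
        sc, typ, cfg, fit = small_fit
        mle, _ = mf.fit_gravity_mle(sc.trips, sc.geography, typ, "basic", "power")
        assert fit.posterior_means["alpha[1]"] == pytest.approx(mle.alpha[0], rel=0.01)
        assert fit.posterior_means["decay[1]"] == pytest.approx(mle.decay[0], rel=0.01)

    def test_deviance_trace_consistent_with_likelihood(self, small_fit):
        """A retained draw's recorded deviance equals -2 x the Poisson log-likelihood."""
        sc, typ, cfg, fit = small_fit
        c, t = 0, 42
        params = mf.GravityParams(
            theta=fit.draws["theta"][c, t],
            alpha=np.array([fit.draws["alpha[1]"][c, t]]),
            beta=np.array([fit.draws["beta[1]"][c, t]]),
            decay=np.array([fit.draws["decay[1]"][c, t]]),
            kernel="power", scheme="basic",
        )
        pred = mf.gravity_predict(params, sc.geography, typ)
        want = -2.0 * mf.poisson_log_likelihood(pred, sc.trips.rounded())
        assert fit.deviance[c, t] == pytest.approx(want, rel=1e-9)

    def test_save_load_roundtrip(self, small_fit, tmp_path):
        _, _, _, fit = small_fit
        fit.save(tmp_path / "fit")
        back = mf.FitResult.load(tmp_path / "fit")
        assert back.param_names == fit.param_names
        assert back.dic == pytest.approx(fit.dic, rel=1e-9)
        for nm in fit.param_names:
            assert np.allclose(back.draws[nm], fit.draws[nm], rtol=1e-10)

    def test_effective_parameters_grow_with_category_count(self, benchmark_suite):
        """On basic-generated data, p_D rises with the stratification's parameter count."""
        sc = benchmark_suite["basic"]
        typ = mf.build_typology(sc.geography)
        cfg = mf.MCMCConfig(chains=2, burn_in=800, samples=800, thin=2, seed=13)
        p_ds = []
        for scheme in ("basic", "regional", "urbanicity"):
            p_ds.append(mf.fit_gravity(sc.trips, sc.geography, typ, scheme, "power", cfg).p_d)
        assert p_ds[0] < p_ds[1] < p_ds[2]

    def test_empty_observations_rejected(self, benchmark_suite):
        sc = benchmark_suite["basic"]
        typ = mf.build_typology(sc.geography)
        empty = mf.TripMatrix(sc.geography.ids, np.full((sc.geography.n,) * 2, np.nan))
        with pytest.raises(mf.ValidationError):
            mf.fit_gravity(empty, sc.geography, typ, "basic", "power")


class TestMLE:
    def test_mle_matches_generic_optimizer(self, benchmark_suite):
        """Analytic-gradient L-BFGS fit equals an independent Nelder-Mead optimization."""
        rng = np.random.default_rng(17)
        geo = random_geography(rng, n=8, n_regions=2)
        typ = mf.build_typology(geo)
        true = mf.GravityParams(theta=0.05, alpha=np.array([0.8]), beta=np.array([0.6]),
                                decay=np.array([1.2]), kernel="power", scheme="basic")
        trips = mf.generate_trips(geo, true, seed=8)
        mle, ll = mf.fit_gravity_mle(trips, geo, typ, "basic", "power")

        obs = trips.rounded()

        def nll(x):
            p = mf.GravityParams(theta=np.exp(x[0]), alpha=np.array([x[1]]),
                                 beta=np.array([x[2]]), decay=np.array([x[3]]),
                                 kernel="power", scheme="basic")
            return -mf.poisson_log_likelihood(mf.gravity_predict(p, geo, typ), obs)

        res = optimize.minimize(nll, [np.log(0.05), 0.8, 0.6, 1.2], method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-10, "maxiter": 20000})
        assert -res.fun == pytest.approx(ll, abs=1e-4)
        assert mle.alpha[0] == pytest.approx(res.x[1], abs=1e-4)
        assert mle.decay[0] == pytest.approx(res.x[3], abs=1e-4)
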