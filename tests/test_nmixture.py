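"""Zero-inflated N-mixture likelihood against exhaustive latent-N
enumeration, truncation behaviour, and density arithmetic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit
from scipy.stats import binom, poisson

from streamoccu import (CountHistory, CovariateBundle, NMixtureSpec,
                        fit_nmixture, nmixture_negloglik, site_density)


def brute_force_negloglik(params, spec, counts, bundle, K_max):
    """Direct latent-N sum with scipy pmfs, one site at a time."""
    beta = params[:spec.n_beta]
    alpha = params[spec.n_beta:spec.n_beta + spec.n_alpha]
    phi = expit(params[-1]) if spec.zero_inflated else 0.0
    total = 0.0
    for i in range(counts.n_sites):
        x = [1.0] + [bundle.site_table[c].iloc[i] for c in spec.lambda_covariates]
        lam = np.exp(np.dot(x, beta))
        L = 0.0
        for N in range(K_max + 1):
            if N == 0:
                pz = phi + (1 - phi) * np.exp(-lam)
            else:
                pz = (1 - phi) * poisson.pmf(N, lam)
            cond = 1.0
            for j in range(counts.n_occasions):
                c = counts.c[i, j]
                if np.isnan(c):
                    continue
                w = [1.0] + [bundle.obs_matrix(cv, counts.n_occasions)[i, j]
                             for cv in spec.p_covariates]
                cond *= binom.pmf(c, N, expit(np.dot(w, alpha)))
            L += pz * cond
        total += np.log(L)
    return -total


class TestNegloglik:
    def test_perfect_detection_pins_latent_abundance(self, empty_bundle):
        b = empty_bundle(["a"])
        c = CountHistory(["a"], [[2.0, 2.0, 2.0]])
        spec = NMixtureSpec()
        # lam = 1, p -> 1, phi -> 0: L = Pois(2; 1)
        v = nmixture_negloglik([0.0, 40.0, -40.0], spec, c, b, K_max=60)
        assert np.exp(-v) == pytest.approx(np.exp(-1) / 2, rel=1e-9)

    def test_all_zero_counts_closed_form_series(self, empty_bundle):
        b = empty_bundle(["a"])
        c = CountHistory(["a"], [[0.0, 0.0, 0.0]])
        spec = NMixtureSpec()
        # lam=1, p=0.5, phi=0: L = sum_n e^-1 (1/8)^n / n! = e^(-7/8)
        v = nmixture_negloglik([0.0, 0.0, -40.0], spec, c, b, K_max=300)
        assert np.exp(-v) == pytest.approx(np.exp(-0.875), rel=1e-9)

    def test_full_zero_inflation_explains_zero_counts(self, empty_bundle):
        b = empty_bundle(["a"])
        c = CountHistory(["a"], [[0.0, 0.0, 0.0]])
        v = nmixture_negloglik([0.0, 0.0, 40.0], NMixtureSpec(), c, b, K_max=60)
        assert np.exp(-v) == pytest.approx(1.0)

    def test_k_max_below_max_count_raises(self, empty_bundle):
        b = empty_bundle(["a"])
        c = CountHistory(["a"], [[5.0, 2.0]])
        with pytest.raises(ValueError, match="K_max"):
            nmixture_negloglik([0.0, 0.0, 0.0], NMixtureSpec(), c, b, K_max=4)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n, J = int(rng.integers(1, 4)), int(rng.integers(1, 4))
        ids = [f"s{i}" for i in range(n)]
        site = pd.DataFrame({"x": rng.standard_normal(n)},
                            index=pd.Index(ids, name="site"))
        bundle = CovariateBundle(site)
        c = rng.integers(0, 5, size=(n, J)).astype(float)
        counts = CountHistory(ids, c)
        spec = NMixtureSpec(lambda_covariates=("x",))
        params = rng.normal(0, 1, spec.n_params)
        K = 40
        ours = nmixture_negloglik(params, spec, counts, bundle, K_max=K)
        assert ours == pytest.approx(
            brute_force_negloglik(params, spec, counts, bundle, K), abs=1e-6)

    def test_doubling_k_max_beyond_adequacy_is_stable(self, empty_bundle):
        b = empty_bundle(["a", "b"])
        c = CountHistory(["a", "b"], [[1.0, 3.0], [0.0, 2.0]])
        params = [np.log(2.0), 0.0, -2.0]
        v1 = nmixture_negloglik(params, NMixtureSpec(), c, b, K_max=80)
        v2 = nmixture_negloglik(params, NMixtureSpec(), c, b, K_max=160)
        assert abs(v1 - v2) < 1e-8

    def test_phi_zero_reduces_to_plain_poisson_mixture(self, empty_bundle):
        b = empty_bundle(["a"])
        c = CountHistory(["a"], [[1.0, 2.0]])
        zip_spec = NMixtureSpec(zero_inflated=True)
        pois_spec = NMixtureSpec(zero_inflated=False)
        v_zip = nmixture_negloglik([0.3, 0.1, -40.0], zip_spec, c, b, K_max=80)
        v_pois = nmixture_negloglik([0.3, 0.1], pois_spec, c, b, K_max=80)
        assert v_zip == pytest.approx(v_pois, abs=1e-8)


class TestFit:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(21)
        n, J = 500, 3
        zi = rng.random(n) < 0.2
        N = np.where(zi, 0, rng.poisson(5.0, n))
        c = rng.binomial(N[:, None], 0.4, size=(n, J)).astype(float)
        ids = [f"s{i}" for i in range(n)]
        b = CovariateBundle(pd.DataFrame(index=pd.Index(ids, name="site")))
        fit = fit_nmixture(NMixtureSpec(), CountHistory(ids, c), b)
        lam_hat = np.exp(fit.beta_lambda[0])
        p_hat = expit(fit.alpha_p[0])
        assert abs(lam_hat - 5.0) / 5.0 < 0.15
        assert abs(p_hat - 0.4) / 0.4 < 0.15
        assert abs(fit.phi - 0.2) / 0.2 < 0.35  # phi is weakly identified

    def test_tight_fixed_bound_raises(self):
        rng = np.random.default_rng(8)
        ids = [f"s{i}" for i in range(30)]
        N = rng.poisson(12.0, 30)
        c = rng.binomial(N[:, None], 0.3, size=(30, 3)).astype(float)
        b = CovariateBundle(pd.DataFrame(index=pd.Index(ids, name="site")))
        spec = NMixtureSpec(K_max=int(c.max()))
        with pytest.raises(ValueError, match="truncates"):
            fit_nmixture(spec, CountHistory(ids, c), b)

    def test_matches_enumeration_oracle_at_optimum(self):
        rng = np.random.default_rng(14)
        ids = [f"s{i}" for i in range(10)]
        N = rng.poisson(2.0, 10)
        c = rng.binomial(N[:, None], 0.6, size=(10, 2)).astype(float)
        b = CovariateBundle(pd.DataFrame(index=pd.Index(ids, name="site")))
        counts = CountHistory(ids, c)
        fit = fit_nmixture(NMixtureSpec(), counts, b)
        oracle = brute_force_negloglik(fit.params, NMixtureSpec(), counts, b,
                                       fit.K_max_used)
        assert -fit.loglik == pytest.approx(oracle, abs=1e-6)


class TestSiteDensity:
    def _setup(self, lam):
        ids = ["a"]
        b = CovariateBundle(pd.DataFrame(index=pd.Index(ids, name="site")))
        from streamoccu.nmixture import NMixtureFit
        fit = NMixtureFit(NMixtureSpec(), np.array([np.log(lam)]),
                          np.array([0.0]), None, 0.0, 2, 1, 100, None, True)
        return b, fit

    def test_single_model_arithmetic(self):
        b, fit = self._setup(10.0)
        est = site_density([fit], [1.0], b, {"a": 5000.0})
        assert est[0].density == pytest.approx(0.002)

    def test_identical_models_average_to_same(self):
        b, fit = self._setup(10.0)
        one = site_density([fit], [1.0], b, {"a": 5000.0})[0].density
        two = site_density([fit, fit], [0.3, 0.7], b, {"a": 5000.0})[0].density
        assert two == pytest.approx(one)

    def test_degenerate_weights_pick_first_model(self):
        b, fit1 = self._setup(10.0)
        _, fit2 = self._setup(20.0)
        est = site_density([fit1, fit2], [1.0, 0.0], b, {"a": 5000.0})
        assert est[0].density == pytest.approx(0.002)

    def test_missing_volume_raises(self):
        b, fit = self._setup(10.0)
        with pytest.raises(KeyError, match="volume"):
            site_density([fit], [1.0], b, {})
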