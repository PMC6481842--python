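"""Occupancy likelihood against brute-force latent-state enumeration,
MLE recovery, and prediction behaviour."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit, logit

from streamoccu import (CovariateBundle, DetectionHistory, OccupancySpec,
                        fit_occupancy, occupancy_negloglik, predict_detection,
                        predict_occupancy, simulate_study, default_study_preset)
from dataclasses import replace


def brute_force_negloglik(params, spec, history, bundle):
    """Enumerate the latent occupied/unoccupied state per site."""
    n_beta = spec.n_beta
    beta, alpha = params[:n_beta], params[n_beta:]
    total = 0.0
    for i in range(history.n_sites):
        if spec.fix_psi_to_one:
            psi = 1.0
        else:
            x = [1.0] + [bundle.site_table[c].iloc[i] for c in spec.psi_covariates]
            psi = expit(np.dot(x, beta))
        site_L = 0.0
        for z in (0, 1):
            prob_state = psi if z else 1.0 - psi
            if spec.fix_psi_to_one and z == 0:
                continue
            cond = 1.0
            for j in range(history.n_occasions):
                y = history.y[i, j]
                if np.isnan(y):
                    continue
                w = [1.0] + [bundle.obs_matrix(c, history.n_occasions)[i, j]
                             for c in spec.p_covariates]
                p = expit(np.dot(w, alpha)) if z else 0.0
                cond *= p if y == 1 else 1.0 - p
            site_L += prob_state * cond
        total += np.log(site_L)
    return -total


def _bundle_for(ids, rng, n_occ):
    site = pd.DataFrame({"x": rng.standard_normal(len(ids))},
                        index=pd.Index(ids, name="site"))
    obs = {"w": pd.DataFrame(rng.standard_normal((len(ids), n_occ)),
                             index=site.index,
                             columns=[f"occ{j+1}" for j in range(n_occ)])}
    return CovariateBundle(site, obs)


class TestNegloglik:
    def test_single_site_mixture_by_hand(self, empty_bundle):
        b = empty_bundle(["a"])
        spec = OccupancySpec()
        h = DetectionHistory(["a"], [[1.0, 0.0]])
        # psi = p = 0.5: L = 0.5 * 0.5 * 0.5
        assert occupancy_negloglik([0.0, 0.0], spec, h, b) == \
            pytest.approx(-np.log(0.125))
        h0 = DetectionHistory(["a"], [[0.0, 0.0]])
        assert np.exp(-occupancy_negloglik([0.0, 0.0], spec, h0, b)) == \
            pytest.approx(0.625)

    def test_certain_detection_with_psi_fixed(self, empty_bundle):
        b = empty_bundle(["a"])
        spec = OccupancySpec(fix_psi_to_one=True)
        h = DetectionHistory(["a"], [[1.0, 1.0]])
        assert occupancy_negloglik([30.0], spec, h, b) == pytest.approx(0.0, abs=1e-8)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_matches_latent_state_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n, J = int(rng.integers(1, 4)), int(rng.integers(1, 4))
        ids = [f"s{i}" for i in range(n)]
        bundle = _bundle_for(ids, rng, J)
        y = rng.choice([0.0, 1.0, np.nan], size=(n, J), p=[0.4, 0.4, 0.2])
        for i in range(n):
            if np.isnan(y[i]).all():
                y[i, 0] = 0.0
        h = DetectionHistory(ids, y)
        spec = OccupancySpec(("x",), ("w",))
        params = rng.normal(0, 1.5, spec.n_params)
        assert occupancy_negloglik(params, spec, h, bundle) == \
            pytest.approx(brute_force_negloglik(params, spec, h, bundle),
                          abs=1e-6)

    def test_all_missing_site_contributes_factor_one(self, empty_bundle):
        # compare a 2-site history where site b is all-missing-but-one
        b2 = empty_bundle(["a", "b"])
        spec = OccupancySpec()
        h_pair = DetectionHistory(["a", "b"], [[1.0, 0.0], [np.nan, 1.0]])
        h_b = DetectionHistory(["b"], [[np.nan, 1.0]])
        b1 = empty_bundle(["a"])
        h_a = DetectionHistory(["a"], [[1.0, 0.0]])
        params = [0.3, -0.2]
        assert occupancy_negloglik(params, spec, h_pair, b2) == pytest.approx(
            occupancy_negloglik(params, spec, h_a, b1)
            + occupancy_negloglik(params, spec, h_b, b1))

    def test_site_permutation_leaves_loglik_unchanged(self, small_history,
                                                      small_bundle):
        spec = OccupancySpec((), ("temp",))
        params = [0.2, 0.5, -0.3]
        base = occupancy_negloglik(params, spec, small_history, small_bundle)
        perm = np.array([3, 1, 5, 0, 2, 4])
        h2 = DetectionHistory([small_history.site_ids[i] for i in perm],
                              small_history.y[perm])
        b2 = CovariateBundle(small_bundle.site_table.iloc[perm],
                             {k: v.iloc[perm] for k, v in
                              small_bundle.obs_tables.items()})
        assert occupancy_negloglik(params, spec, h2, b2) == pytest.approx(base)


class TestFit:
    def test_parameter_recovery_intercept_only(self):
        rng = np.random.default_rng(77)
        n, J = 1000, 5
        z = rng.random(n) < 0.6
        y = ((rng.random((n, J)) < 0.7) & z[:, None]).astype(float)
        ids = [f"s{i}" for i in range(n)]
        h = DetectionHistory(ids, y)
        b = CovariateBundle(pd.DataFrame(index=pd.Index(ids, name="site")))
        fit = fit_occupancy(OccupancySpec(), h, b)
        assert fit.converged
        assert expit(fit.beta[0]) == pytest.approx(0.6, abs=0.05)
        assert expit(fit.alpha[0]) == pytest.approx(0.7, abs=0.04)

    def test_loglik_matches_grid_search(self):
        rng = np.random.default_rng(3)
        n, J = 20, 3
        z = rng.random(n) < 0.5
        y = ((rng.random((n, J)) < 0.6) & z[:, None]).astype(float)
        ids = [f"s{i}" for i in range(n)]
        h = DetectionHistory(ids, y)
        b = CovariateBundle(pd.DataFrame(index=pd.Index(ids, name="site")))
        fit = fit_occupancy(OccupancySpec(), h, b)
        grid = np.linspace(-5, 5, 201)
        best = min(occupancy_negloglik([a, c], OccupancySpec(), h, b)
                   for a in grid for c in grid)
        assert -fit.loglik == pytest.approx(best, abs=1e-3)

    def test_all_detected_hits_boundary_and_is_flagged(self):
        ids = ["a", "b", "c"]
        h = DetectionHistory(ids, np.ones((3, 3)))
        b = CovariateBundle(pd.DataFrame(index=pd.Index(ids, name="site")))
        fit = fit_occupancy(OccupancySpec(), h, b)
        assert fit.boundary
        assert expit(fit.beta[0]) > 0.99 and expit(fit.alpha[0]) > 0.99

    def test_psi_fixed_single_occasion_mle_is_raw_frequency(self):
        ids = [f"s{i}" for i in range(10)]
        y = np.array([[1.0]] * 7 + [[0.0]] * 3)
        h = DetectionHistory(ids, y)
        b = CovariateBundle(pd.DataFrame(index=pd.Index(ids, name="site")))
        fit = fit_occupancy(OccupancySpec(fix_psi_to_one=True), h, b)
        assert expit(fit.alpha[0]) == pytest.approx(0.7, abs=1e-5)


class TestPredict:
    def _fit(self):
        ves, _, _, bundle, _ = simulate_study(
            replace(default_study_preset(), n_sites=150, seed=2))
        return fit_occupancy(OccupancySpec((), ("temp",)), ves, bundle)

    def test_intercept_zero_gives_half(self):
        fit = self._fit()
        fit.beta = np.array([0.0])
        est, _ = predict_occupancy(fit, z=0.0)
        assert est == pytest.approx(0.5)

    def test_interval_endpoints_inside_unit_interval(self):
        fit = self._fit()
        est, (lo, hi) = predict_occupancy(fit, z=5.0)
        assert 0.0 < lo <= est <= hi < 1.0

    def test_z_zero_collapses_interval(self):
        fit = self._fit()
        est, (lo, hi) = predict_occupancy(fit, z=0.0)
        assert lo == pytest.approx(est) and hi == pytest.approx(est)

    @pytest.mark.parametrize("slope, direction", [(0.8, 1), (-0.8, -1), (0.0, 0)])
    def test_detection_curve_monotone_with_slope_sign(self, slope, direction):
        fit = self._fit()
        fit.alpha = np.array([0.2, slope])
        grid = {"temp": np.linspace(-2, 2, 9)}
        p, lo, hi = predict_detection(fit, grid)
        diffs = np.diff(p)
        if direction > 0:
            assert (diffs > 0).all()
        elif direction < 0:
            assert (diffs < 0).all()
        else:
            np.testing.assert_allclose(p, expit(0.2))
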