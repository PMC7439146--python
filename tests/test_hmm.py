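"""Emission densities, likelihood, fitting, decoding and diagnostics."""

import numpy as np
import pytest
from scipy import stats

from sleephmm.model import (
    HMMParameters,
    count_free_parameters,
    emission_log_density,
    fit_hmm,
    forward_log_likelihood,
    information_criteria,
    pseudo_residuals,
    select_model,
    viterbi_decode,
)
from sleephmm.synthetic import simulate_observations, simulate_states

from conftest import random_parameters, random_observations
from oracles import brute_force_loglik, brute_force_viterbi, oracle_emission_logpdf


class TestFreeParameters:
    @pytest.mark.parametrize(
        "scheme, df",
        [("M1", 13), ("M2", 11), ("HR_ONLY", 7), ("ACT_ONLY", 7)],
    )
    def test_counts(self, scheme, df):
        assert count_free_parameters(scheme) == df

    def test_unknown_scheme(self):
        with pytest.raises(ValueError, match="unknown scheme"):
            count_free_parameters("M3")


class TestInformationCriteria:
    def test_zero_case(self):
        assert information_criteria(0.0, 0, 10) == (0.0, 0.0)

    def test_definitions(self):
        aic, bic = information_criteria(-100.0, 4, 1000)
        assert aic == pytest.approx(208.0)
        assert bic == pytest.approx(200.0 + 4 * np.log(1000))

    def test_invalid_t(self):
        with pytest.raises(ValueError):
            information_criteria(-1.0, 2, 0)


class TestEmissionDensity:
    def test_matches_scipy_oracle(self, rng):
        for _ in range(20):
            params = random_parameters(rng)
            x_hr, x_act = rng.uniform(40, 140), rng.uniform(0, 4)
            for scheme in ("M1", "M2", "HR_ONLY", "ACT_ONLY"):
                for i in (0, 1):
                    got = emission_log_density(params, scheme, x_hr, x_act, i)
                    want = oracle_emission_logpdf(params, scheme, x_hr, x_act, i)
                    assert got == pytest.approx(want, abs=1e-10)

    def test_m1_with_zero_rho_equals_m2(self, rng):
        params = random_parameters(rng)
        params.rho[:] = 0.0
        for _ in range(10):
            x_hr, x_act = rng.uniform(40, 140), rng.uniform(0, 4)
            for i in (0, 1):
                assert emission_log_density(params, "M1", x_hr, x_act, i) == \
                    pytest.approx(emission_log_density(params, "M2", x_hr, x_act, i),
                                  abs=1e-12)

    def test_both_missing_gives_log_one(self, rng):
        params = random_parameters(rng)
        for i in (0, 1):
            assert emission_log_density(params, "M1", np.nan, np.nan, i) == 0.0

    def test_one_missing_gives_marginal(self, rng):
        params = random_parameters(rng)
        got = emission_log_density(params, "M1", 80.0, np.nan, 0)
        want = stats.norm.logpdf(80.0, params.mu_hr[0], np.sqrt(params.sigma2_hr[0]))
        assert got == pytest.approx(want, abs=1e-12)

    def test_mode_of_standard_bivariate(self):
        params = HMMParameters(
            pi=[0.5, 0.5], transmat=[[0.5, 0.5], [0.5, 0.5]],
            mu_hr=[0.0, 0.0], sigma2_hr=[1.0, 1.0],
            mu_act=[0.0, 0.0], sigma2_act=[1.0, 1.0], rho=[0.0, 0.0],
        )
        assert emission_log_density(params, "M1", 0.0, 0.0, 0) == \
            pytest.approx(np.log(1.0 / (2.0 * np.pi)))

    def test_infinite_observation_rejected(self, rng):
        params = random_parameters(rng)
        with pytest.raises(ValueError, match="finite"):
            emission_log_density(params, "M1", np.inf, 1.0, 0)


class TestForwardLikelihood:
    def test_t1_is_mixture_density(self, rng):
        params = random_parameters(rng)
        hr, act = np.array([77.0]), np.array([1.3])
        want = np.log(sum(
            params.pi[i] * np.exp(oracle_emission_logpdf(params, "M1", 77.0, 1.3, i))
            for i in (0, 1)))
        assert forward_log_likelihood(params, "M1", (hr, act)) == \
            pytest.approx(want, abs=1e-10)

    def test_all_missing_gives_zero(self, rng):
        params = random_parameters(rng)
        hr, act = random_observations(rng, 3, missing="all")
        assert forward_log_likelihood(params, "M1", (hr, act)) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("missing", ["none", "some"])
    def test_matches_brute_force_enumeration(self, rng, missing):
        for _ in range(25):
            params = random_parameters(rng)
            T = int(rng.integers(1, 9))
            hr, act = random_observations(rng, T, missing)
            for scheme in ("M1", "M2"):
                got = forward_log_likelihood(params, scheme, (hr, act))
                want = brute_force_loglik(params, scheme, hr, act)
                assert abs(got - want) < 1e-10

    def test_m1_rho_zero_equals_m2_likelihood(self, rng):
        params = random_parameters(rng)
        params.rho[:] = 0.0
        hr, act = random_observations(rng, 500, missing="some")
        l1 = forward_log_likelihood(params, "M1", (hr, act))
        l2 = forward_log_likelihood(params, "M2", (hr, act))
        assert abs(l1 - l2) < 1e-9

    def test_stable_at_long_series(self, separated_params, rng):
        z = simulate_states(separated_params, 100_000, seed=1)
        hr, act = simulate_observations(separated_params, z, seed=2)
        ll = forward_log_likelihood(separated_params, "M1", (hr, act))
        assert np.isfinite(ll)


class TestViterbi:
    def test_matches_exhaustive_argmax(self, rng):
        for _ in range(25):
            params = random_parameters(rng)
            T = int(rng.integers(1, 9))
            hr, act = random_observations(rng, T)
            path = viterbi_decode(params, "M1", (hr, act))
            want_path, want_lp = brute_force_viterbi(params, "M1", hr, act)
            assert path.log_joint == pytest.approx(want_lp, abs=1e-10)
            np.testing.assert_array_equal(path.states, want_path)

    def test_all_missing_follows_markov_prior(self, rng):
        params = random_parameters(rng)
        hr, act = random_observations(rng, 6, missing="all")
        path = viterbi_decode(params, "M1", (hr, act))
        want_path, want_lp = brute_force_viterbi(params, "M1", hr, act)
        assert path.log_joint == pytest.approx(want_lp, abs=1e-10)

    def test_strong_separation_matches_pointwise_argmax(self, separated_params, rng):
        # near-deterministic emissions dominate the transition penalty
        p = separated_params
        p = HMMParameters(p.pi, p.transmat, p.mu_hr, [1.0, 1.0],
                          p.mu_act, [0.01, 0.01], p.rho)
        z = simulate_states(p, 2000, seed=3)
        hr, act = simulate_observations(p, z, seed=4)
        path = viterbi_decode(p, "M1", (hr, act))
        assert np.mean(path.states == z) > 0.999


class TestFitting:
    def test_loglik_nondecreasing(self, separated_params):
        z = simulate_states(separated_params, 3000, seed=5)
        hr, act = simulate_observations(separated_params, z, seed=6)
        hr[100:130] = np.nan  # exercise the missing-data M-step
        fit = fit_hmm((hr, act), scheme="M1", n_restarts=2, seed=7)
        diffs = np.diff(fit.loglik_history)
        assert (diffs > -1e-8 * np.abs(fit.loglik_history[:-1])).all()

    def test_states_canonical_by_heart_rate(self, separated_params):
        z = simulate_states(separated_params, 3000, seed=8)
        hr, act = simulate_observations(separated_params, z, seed=9)
        fit = fit_hmm((hr, act), scheme="M1", n_restarts=3, seed=10)
        assert fit.parameters.mu_hr[0] < fit.parameters.mu_hr[1]

    def test_parameter_recovery_well_separated(self, separated_params):
        z = simulate_states(separated_params, 20_000, seed=11)
        hr, act = simulate_observations(separated_params, z, seed=12,
                                        truncate_act=False)
        fit = fit_hmm((hr, act), scheme="M1", n_restarts=3, seed=13)
        p = fit.parameters
        assert p.mu_hr == pytest.approx(separated_params.mu_hr, abs=0.5)
        assert p.mu_act == pytest.approx(separated_params.mu_act, abs=0.1)
        assert p.transmat == pytest.approx(separated_params.transmat, abs=0.005)
        assert p.rho[1] == pytest.approx(0.5, abs=0.05)

    def test_perfect_separation_recovers_occupancy(self):
        params = HMMParameters(
            pi=[0.5, 0.5], transmat=[[0.98, 0.02], [0.02, 0.98]],
            mu_hr=[60.0, 120.0], sigma2_hr=[1.0, 1.0],
            mu_act=[0.0, 3.0], sigma2_act=[0.5, 0.5], rho=[0.0, 0.0],
        )
        z = simulate_states(params, 10_000, seed=14)
        hr, act = simulate_observations(params, z, seed=15)
        fit = fit_hmm((hr, act), scheme="M1", n_restarts=2, seed=16)
        path = viterbi_decode(fit.parameters, "M1", (hr, act))
        assert np.mean(path.states == z) > 0.999

    def test_refit_from_truth_barely_moves(self, separated_params):
        z = simulate_states(separated_params, 100_000, seed=17)
        hr, act = simulate_observations(separated_params, z, seed=18,
                                        truncate_act=False)
        ll0 = forward_log_likelihood(separated_params, "M1", (hr, act))
        fit = fit_hmm((hr, act), scheme="M1", n_restarts=1,
                      init_params=separated_params, max_iter=2, seed=0)
        improvement = fit.loglik_history[-1] - ll0
        assert 0 <= improvement < 0.001 * abs(ll0)

    def test_univariate_schemes_fit(self, separated_params):
        z = simulate_states(separated_params, 3000, seed=19)
        hr, act = simulate_observations(separated_params, z, seed=20)
        for scheme in ("HR_ONLY", "ACT_ONLY"):
            fit = fit_hmm((hr, act), scheme=scheme, n_restarts=2, seed=21)
            assert fit.df == 7
            assert np.isfinite(fit.log_likelihood)

    def test_requires_enough_data(self, rng):
        hr, act = random_observations(rng, 50)
        with pytest.raises(ValueError, match="100"):
            fit_hmm((hr, act), scheme="M1", seed=0)

    def test_agrees_with_hmmlearn_on_complete_data(self, separated_params):
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        z = simulate_states(separated_params, 5000, seed=22)
        hr, act = simulate_observations(separated_params, z, seed=23,
                                        truncate_act=False)
        X = np.column_stack([hr, act])
        # likelihood of fixed parameters must agree with the reference
        ref = hmmlearn.GaussianHMM(n_components=2, covariance_type="full",
                                   init_params="")
        p = separated_params
        ref.startprob_ = p.pi
        ref.transmat_ = p.transmat
        ref.means_ = np.column_stack([p.mu_hr, p.mu_act])
        covs = []
        for i in range(2):
            c = p.rho[i] * np.sqrt(p.sigma2_hr[i] * p.sigma2_act[i])
            covs.append([[p.sigma2_hr[i], c], [c, p.sigma2_act[i]]])
        ref.covars_ = np.array(covs)
        want = ref.score(X)
        got = forward_log_likelihood(p, "M1", (hr, act))
        assert got == pytest.approx(want, rel=1e-10)
        # and our EM must reach at least the reference fit's likelihood
        ref_fit = hmmlearn.GaussianHMM(n_components=2, covariance_type="full",
                                       n_iter=200, tol=1e-6, random_state=0)
        ref_fit.fit(X)
        ours = fit_hmm((hr, act), scheme="M1", n_restarts=3, seed=24)
        assert ours.log_likelihood >= ref_fit.score(X) - 1.0


class TestModelSelection:
    def _fit(self, scheme, ll, df, t=1000):
        aic, bic = information_criteria(ll, df, t)
        from sleephmm.model import FitResult
        params = HMMParameters(
            pi=[0.5, 0.5], transmat=[[0.9, 0.1], [0.1, 0.9]],
            mu_hr=[60, 90], sigma2_hr=[50, 50],
            mu_act=[0, 2], sigma2_act=[0.5, 0.5], rho=[0, 0])
        return FitResult(params, scheme, ll, df, aic, bic, t, 10, True)

    def test_prefers_lower_aic(self):
        best = self._fit("M1", -419428.3, 13, 86_400)
        other = self._fit("M2", -424798.5, 11, 86_400)
        assert select_model([other, best]) is best

    def test_tie_goes_to_fewer_parameters(self):
        a = self._fit("M1", -100.0, 13)
        b = self._fit("M2", -102.0, 11)  # identical AIC: -2*102+22 == -2*100+26
        assert select_model([a, b]) is b

    def test_single_fit_passthrough(self):
        a = self._fit("M1", -100.0, 13)
        assert select_model([a]) is a

    def test_disagreement_warns_and_respects_preference(self):
        # small ll gap: AIC picks the bigger model, BIC the smaller
        a = self._fit("M1", -98.0, 13, t=100_000)
        b = self._fit("M2", -100.5, 11, t=100_000)
        with pytest.warns(UserWarning, match="BIC"):
            assert select_model([a, b]) is a
        with pytest.warns(UserWarning, match="BIC"):
            assert select_model([a, b], prefer="bic") is b

    def test_mismatched_lengths_rejected(self):
        a = self._fit("M1", -100.0, 13, t=1000)
        b = self._fit("M2", -100.0, 11, t=2000)
        with pytest.raises(ValueError, match="length"):
            select_model([a, b])


class TestPseudoResiduals:
    def test_identity_under_degenerate_standard_normal(self, rng):
        params = HMMParameters(
            pi=[0.5, 0.5], transmat=[[0.5, 0.5], [0.5, 0.5]],
            mu_hr=[0.0, 0.0], sigma2_hr=[1.0, 1.0],
            mu_act=[0.0, 0.0], sigma2_act=[1.0, 1.0], rho=[0.0, 0.0],
        )
        x = rng.standard_normal(200)
        res = pseudo_residuals(params, "M2", (x, x.copy()))
        np.testing.assert_allclose(res.u_hr, x, atol=1e-7)

    def test_standard_normal_when_model_true(self, separated_params):
        # KS distance below the 1% critical value in at least 9 of 10 seeds
        ok = 0
        for seed in range(10):
            z = simulate_states(separated_params, 3000, seed=100 + seed)
            hr, act = simulate_observations(separated_params, z,
                                            seed=200 + seed, truncate_act=False)
            fit = fit_hmm((hr, act), scheme="M1", n_restarts=2, seed=seed)
            res = pseudo_residuals(fit.parameters, "M1", (hr, act))
            if res.ks_hr[1] > 0.01 and res.ks_act[1] > 0.01:
                ok += 1
        assert ok >= 9

    def test_detects_heavy_tails(self, separated_params, rng):
        z = simulate_states(separated_params, 3000, seed=30)
        hr, act = simulate_observations(separated_params, z, seed=31,
                                        truncate_act=False)
        contaminated = hr.copy()
        outliers = rng.random(len(hr)) < 0.05
        contaminated[outliers] += rng.standard_t(1, outliers.sum()) * 30
        fit = fit_hmm((hr, act), scheme="M1", n_restarts=2, seed=32)
        clean = pseudo_residuals(fit.parameters, "M1", (hr, act))
        dirty = pseudo_residuals(fit.parameters, "M1", (contaminated, act))
        assert dirty.ks_hr[0] > clean.ks_hr[0]

    def test_defined_only_at_observed_minutes(self, separated_params):
        z = simulate_states(separated_params, 500, seed=33)
        hr, act = simulate_observations(separated_params, z, seed=34)
        hr[10:20] = np.nan
        res = pseudo_residuals(separated_params, "M1", (hr, act))
        assert np.isnan(res.u_hr[10:20]).all()
        assert np.isfinite(res.u_hr[np.isfinite(hr)]).all()
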