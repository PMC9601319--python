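"""Estimators of active information, variances, tests and LD rates."""

import numpy as np
import pytest
from scipy.special import logit

from actinfo import (
    EstimationResult,
    FiniteDistribution,
    FTTestConfig,
    SampleData,
    SpecificityModel,
    TiltedFamily,
    bias_bound,
    empirical_actinfo,
    estimate_nonparametric,
    ft_test,
    iid_sampler,
    ld_rate_np,
    ld_rate_np_legendre,
    ld_rate_param,
    machine_null,
    mle_tilting,
    nonparametric_target_estimate,
    parametric_target_estimate,
    target_probability,
    theta_for_target_prob,
    tilt,
    two_sample_estimate,
    variance_np,
    variance_param,
    variance_param_nuisance,
)
from actinfo.estimation import mle_nuisance, nuisance_variance_v2
from actinfo.models import machine_specificity
from actinfo.tilting import binary_states


class TestNonparametric:
    def test_hit_fraction(self):
        spec = SpecificityModel.indicator(["hit"])
        sample = SampleData(["hit"] * 3 + ["miss"] * 7)
        assert nonparametric_target_estimate(sample, spec) == pytest.approx(0.3)

    def test_all_hits(self):
        spec = SpecificityModel.indicator(["hit"])
        assert nonparametric_target_estimate(SampleData(["hit"] * 5), spec) == 1.0

    def test_consistent_for_tilted_target(self, machine5):
        fam, spec = machine5["family"], machine5["spec"]
        theta = 1.5
        p = tilt(fam, theta)
        sample = iid_sampler(p, 20000, seed=42)
        q_hat = nonparametric_target_estimate(sample, spec)
        q_true = target_probability(p, spec)
        se = np.sqrt(q_true * (1 - q_true) / sample.n)
        assert abs(q_hat - q_true) < 4 * se

    @pytest.mark.parametrize("q_hat, p0, expected", [
        (0.3, 0.1, np.log(3)),
        (0.1, 0.1, 0.0),
        (1.0, np.exp(-3.47), 3.47),
    ])
    def test_empirical_actinfo(self, q_hat, p0, expected):
        assert empirical_actinfo(q_hat, p0) == pytest.approx(expected, abs=1e-12)

    def test_variance_np(self):
        assert variance_np(0.5) == pytest.approx(1.0)
        assert variance_np(0.999) == pytest.approx(1e-3 / 0.999)
        with pytest.raises(ValueError):
            variance_np(1.0)


class TestTiltingMLE:
    def test_boundary_at_base_mean(self, two_point_family):
        # sample mean equal to E_P0[f] = 0.5 -> theta_hat = 0
        sample = SampleData([0, 1] * 50)
        assert mle_tilting(sample, two_point_family) == 0.0

    def test_two_point_closed_form(self, two_point_family):
        # hit fraction h: theta_hat = logit(h) - logit(P0(1))
        sample = SampleData([1] * 70 + [0] * 30)
        expected = logit(0.7) - logit(0.5)
        assert mle_tilting(sample, two_point_family) == pytest.approx(
            expected, abs=1e-9)

    def test_divergence_at_fmax(self, two_point_family):
        with pytest.warns(UserWarning, match="diverges"):
            assert mle_tilting(SampleData([1, 1, 1]), two_point_family) == np.inf

    def test_parameter_recovery(self, machine5):
        fam = machine5["family"]
        theta = 1.0
        q = tilt(fam, theta)
        sample = iid_sampler(q, 10**4, seed=7)
        theta_hat = mle_tilting(sample, fam)
        u = fam.var_f(theta) / fam.var_f(theta) ** 2  # U with Q = P_theta
        assert abs(theta_hat - theta) < 3 * np.sqrt(u / sample.n)

    def test_constant_f_rejected(self):
        base = FiniteDistribution.uniform((0, 1))
        fam = TiltedFamily(base, SpecificityModel(f=lambda x: 1.0, f0=1.0))
        with pytest.raises(ValueError, match="constant"):
            mle_tilting(SampleData([0, 1]), fam)


class TestParametricEstimate:
    def test_theta0_gives_null_prob(self, machine5):
        fam, spec = machine5["family"], machine5["spec"]
        assert parametric_target_estimate(fam, 0.0) == pytest.approx(
            target_probability(fam.base, spec))

    def test_binary_f_agrees_with_nonparametric_plugin(self):
        # with indicator specificity the tilting MLE reproduces the hit
        # fraction exactly, so both estimates of Q(A) coincide
        states = binary_states(3)
        base = FiniteDistribution.uniform(states)
        ones = tuple([1] * 3)
        spec = SpecificityModel(
            f={s: (1.0 if s == ones else 0.0) for s in states}, f0=1.0)
        fam = TiltedFamily(base, spec)
        draws = [ones] * 30 + [states[0]] * 70
        sample = SampleData(draws)
        theta_hat = mle_tilting(sample, fam)
        q_param = parametric_target_estimate(fam, theta_hat)
        q_np = nonparametric_target_estimate(sample, spec)
        assert q_param == pytest.approx(q_np, abs=1e-9)


class TestVarianceParam:
    def test_binary_f_matches_nonparametric(self, machine5):
        states = machine5["null"].states
        ones = tuple([1] * 5)
        spec = SpecificityModel(
            f={s: (1.0 if s == ones else 0.0) for s in states}, f0=1.0)
        fam = TiltedFamily(machine5["null"], spec)
        theta_star = 2.0
        q_a = target_probability(tilt(fam, theta_star), spec)
        assert variance_param(fam, theta_star) == pytest.approx(
            variance_np(q_a), abs=1e-9)

    def test_constant_f_rejected(self):
        base = FiniteDistribution.uniform((0, 1))
        fam = TiltedFamily(base, SpecificityModel(f=lambda x: 2.0, f0=2.0))
        with pytest.raises(ValueError):
            variance_param(fam, 1.0)

    def test_matches_simulated_sampling_variance(self, machine5):
        # Monte-Carlo oracle of the CLT: empirical Var[sqrt(n) Ihat+] ~ V
        fam, spec = machine5["family"], machine5["spec"]
        theta = 1.0
        q = tilt(fam, theta)
        v_formula = variance_param(fam, theta)
        n, reps = 4000, 2000
        rng = np.random.default_rng(5)
        fv = fam.f_values
        counts = rng.multinomial(n, q.probs, size=reps)
        i_true = np.log(target_probability(q, spec)
                        / target_probability(fam.base, spec))
        from actinfo.estimation import mle_tilting_from_mean
        i_hats = np.empty(reps)
        for r in range(reps):
            th = mle_tilting_from_mean(float(counts[r] @ fv / n), fam)
            i_hats[r] = np.log(parametric_target_estimate(fam, th)
                               / target_probability(fam.base, spec))
        v_emp = n * np.var(i_hats - i_true, ddof=1)
        assert v_emp == pytest.approx(v_formula, rel=0.10)


class TestLDRates:
    def test_closed_form_value(self):
        expected = 0.3 * np.log(3) + 0.7 * np.log(7 / 9)
        assert ld_rate_np(0.1, 0.3) == pytest.approx(expected, abs=1e-14)

    def test_equal_probs_zero(self):
        with pytest.warns(UserWarning):
            assert ld_rate_np(0.3, 0.3) == 0.0

    def test_legendre_agrees_with_closed_form(self):
        for p0 in (0.05, 0.2, 0.5, 0.8):
            for pmin in (p0 + 0.05, min(0.99, 2 * p0), 1.0):
                if pmin <= p0:
                    continue
                assert ld_rate_np_legendre(p0, pmin) == pytest.approx(
                    ld_rate_np(p0, pmin), abs=1e-10)

    def test_param_rate_matches_grid_search(self, machine5):
        fam, spec = machine5["family"], machine5["spec"]
        p0_a = target_probability(fam.base, spec)
        p_min = p0_a * np.exp(2.0)  # Imin = 2
        C, phi_star, theta_min = ld_rate_param(fam, p_min, return_maximizer=True)
        # brute-force grid oracle over phi
        from actinfo.tilting import log_normalizer
        mu_min = fam.mean_f(theta_min)
        phis = np.linspace(0, 50, 200001)
        grid = phis * mu_min - np.array([log_normalizer(fam, p) for p in phis])
        assert C >= grid.max() - 1e-8
        assert C == pytest.approx(grid.max(), abs=1e-6)
        # the maximizer is theta_min (stationarity of the concave objective)
        assert phi_star == pytest.approx(theta_min, abs=1e-6)

    def test_param_rate_vanishes_at_null(self, machine5):
        fam, spec = machine5["family"], machine5["spec"]
        p0_a = target_probability(fam.base, spec)
        assert ld_rate_param(fam, p0_a * 1.001) < 1e-4

    def test_binary_f_param_equals_np(self, machine5):
        # indicator specificity: parametric and nonparametric rates coincide
        states = machine5["null"].states
        ones = tuple([1] * 5)
        spec = SpecificityModel(
            f={s: (1.0 if s == ones else 0.0) for s in states}, f0=1.0)
        fam = TiltedFamily(machine5["null"], spec)
        p0_a = target_probability(fam.base, spec)
        p_min = p0_a * np.exp(1.5)
        assert ld_rate_param(fam, p_min) == pytest.approx(
            ld_rate_np(p0_a, p_min), abs=1e-9)


class TestFTTest:
    def test_threshold_is_inclusive(self):
        res = EstimationResult(i_hat=2.0, q_hat_A=0.5, variance=1.0, n=100)
        assert ft_test(res, FTTestConfig(2.0)).reject is True

    def test_zero_actinfo_accepts(self):
        res = EstimationResult(i_hat=0.0, q_hat_A=0.1, variance=9.0, n=100)
        assert ft_test(res, FTTestConfig(1.0)).reject is False

    def test_level_bound_reported(self):
        res = EstimationResult(i_hat=1.0, q_hat_A=0.4, variance=1.5, n=200,
                               ld_rate=0.1)
        assert res.asymptotic_level_bound() == pytest.approx(np.exp(-20.0))

    def test_type1_error_bounded_and_decreasing(self):
        # empirical rejection rate under H0 decreases with n and sits near
        # the exact binomial tail
        from scipy.stats import binom
        p0, i_min = 0.2, np.log(1.5)
        p_min = p0 * np.exp(i_min)
        rng = np.random.default_rng(17)
        levels = []
        for n in (100, 200, 400):
            k = int(np.ceil(n * p_min - 1e-12))
            hits = rng.binomial(n, p0, size=20000)
            emp = np.mean(hits >= k)
            exact = binom.sf(k - 1, n, p0)
            levels.append(emp)
            assert emp == pytest.approx(exact, abs=4 * np.sqrt(exact / 20000) + 1e-4)
        assert levels[0] > levels[-1]


class TestBiasBound:
    def test_zero_at_maximizer(self):
        assert bias_bound(0.1, 0.1) == 0.0

    def test_log_ratio(self):
        assert bias_bound(0.05, 0.1) == pytest.approx(-np.log(2))

    def test_contradiction_rejected(self):
        with pytest.raises(ValueError):
            bias_bound(0.2, 0.1)

    def test_conservative_rate_is_larger(self):
        # shifting pmin by e^{-B} with B < 0 enlarges the LD rate
        p0, p_min, B = 0.1, 0.3, -0.5
        assert ld_rate_np(p0, p_min * np.exp(-B)) > ld_rate_np(p0, p_min)


class TestTwoSample:
    def test_null_data_estimates_near_zero(self, machine5):
        spec = machine5["spec"]
        null_builder = lambda b: machine_null(5, b)
        p_true = machine_null(5, 1.0)
        draws = iid_sampler(p_true, 4000, seed=1).draws
        null_draws = iid_sampler(p_true, 4000, seed=2).draws
        res = two_sample_estimate(SampleData(draws, null_draws), null_builder,
                                  spec, bracket=(0.2, 5.0))
        se = np.sqrt(res.variance / res.n)
        assert abs(res.i_hat) < 4 * se

    def test_nuisance_mle_recovers_b(self):
        null_builder = lambda b: machine_null(5, b)
        p_true = machine_null(5, 0.7)
        draws = iid_sampler(p_true, 20000, seed=3).draws
        b_hat = mle_nuisance(draws, null_builder, (0.2, 5.0))
        assert b_hat == pytest.approx(0.7, abs=0.05)

    def test_recovers_positive_actinfo(self, machine5):
        fam, spec = machine5["family"], machine5["spec"]
        theta, b_true = 1.0, 1.0
        q = tilt(fam, theta)
        i_true = np.log(target_probability(q, spec)
                        / target_probability(fam.base, spec))
        draws = iid_sampler(q, 5000, seed=11).draws
        null_draws = iid_sampler(fam.base, 5000, seed=12).draws
        res = two_sample_estimate(SampleData(draws, null_draws),
                                  lambda b: machine_null(5, b), spec,
                                  bracket=(0.2, 5.0))
        assert res.xi_star == pytest.approx(b_true, abs=0.2)
        assert abs(res.i_hat - i_true) < 3 * np.sqrt(res.variance / res.n)

    def test_v2_positive_and_finite(self, machine5):
        v2 = nuisance_variance_v2(lambda b: machine_null(5, b), 1.0,
                                  machine5["spec"])
        assert 0 < v2 < np.inf


class TestVarianceParamNuisance:
    # a = -0.2 keeps f nonlinear in |x| (f(1..1) = 1 != a d), so the tilting
    # and mutation-bias scores are not collinear and (theta, b) is jointly
    # identifiable
    def _builder(self):
        spec = machine_specificity(5, -0.2)
        def builder(theta, b):
            fam = TiltedFamily(machine_null(5, b), spec)
            return tilt(fam, theta)
        return builder, spec

    def test_reduces_to_fixed_nuisance_variance(self, machine5):
        # a builder that ignores xi has zero xi-score: the sandwich then
        # equals the single-parameter tilting variance
        fam, spec = machine5["family"], machine5["spec"]
        theta_star = 1.2
        def builder(theta, _xi):
            return tilt(fam, theta)
        v2d = variance_param_nuisance(builder, theta_star, 1.0, spec)
        v1d = variance_param(fam, theta_star)
        assert v2d == pytest.approx(v1d, rel=1e-4)

    def test_nonnegative_with_free_nuisance(self):
        builder, spec = self._builder()
        v = variance_param_nuisance(builder, 1.0, 1.0, spec)
        assert 0 <= v < np.inf

    def test_collinear_scores_rejected(self, machine5):
        # at a = 0.2, d = 5 the specificity is exactly linear in |x|, so the
        # tilting and mutation-bias directions coincide: singular Hessian
        spec = machine5["spec"]
        def builder(theta, b):
            return tilt(TiltedFamily(machine_null(5, b), spec), theta)
        with pytest.raises(ValueError, match="singular"):
            variance_param_nuisance(builder, 1.0, 1.0, spec)

    def test_matches_simulated_joint_mle_variance(self):
        # simulation oracle: empirical variance of Ihat+ from joint
        # (theta, b) MLE over replicates matches the sandwich within 15%
        theta_star, b_star = 1.0, 1.0
        builder, spec = self._builder()
        q = builder(theta_star, b_star)
        v_formula = variance_param_nuisance(builder, theta_star, b_star, spec)
        rng = np.random.default_rng(23)
        n, reps = 3000, 400
        from scipy.optimize import minimize
        i_hats = []
        p0max_cache = {}
        for _ in range(reps):
            counts = rng.multinomial(n, q.probs)
            def negll(par):
                th, b = par
                if th < 0 or not 0.2 < b < 5:
                    return 1e9
                lp = builder(th, b).log_probs
                return -float(counts @ lp)
            res = minimize(negll, x0=[theta_star, b_star], method="Nelder-Mead",
                           options={"xatol": 1e-6, "fatol": 1e-9})
            th, b = res.x
            p_a = target_probability(builder(th, b), spec)
            i_hats.append(np.log(p_a))  # common denominator drops out of Var
        v_emp = n * np.var(np.array(i_hats), ddof=1)
        assert v_emp == pytest.approx(v_formula, rel=0.15)
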