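"""Quantal model suite: likelihood, monotonicity, BMD inversion, MAP fits."""

import math

import numpy as np
import pytest
from scipy import stats

from pefkit.bmd_models import (
    MODEL_NAMES,
    MODELS,
    BenchmarkNotAttained,
    BenchmarkSpec,
    FitConfig,
    compute_bmd,
    fit_map,
    get_model,
    log_likelihood,
    predict,
    to_natural,
)
from pefkit.types import Compound, DoseResponseDataset

# representative in-support parameter vectors per family
REFERENCE_THETA = {
    "quantal_linear": [0.05, 1.0],
    "logistic": [-2.0, 0.8],
    "probit": [-1.5, 0.5],
    "log_logistic": [0.02, -2.0, 1.2],
    "log_probit": [0.02, -1.5, 1.1],
    "gamma": [0.02, 1.5, 0.4],
    "weibull": [0.05, 2.0, 0.3],
    "dichotomous_hill": [0.02, 0.6, -1.0, 1.3],
    "multistage_2": [0.02, 0.3, 0.1],
}


def _random_theta(model, rng):
    z = np.array([
        np.clip(rng.normal(p.prior_mean, p.prior_sd), p.lo, p.hi)
        for p in model.params])
    return to_natural(z, model.params)


class TestPredict:
    def test_quantal_linear_background_cases(self):
        assert predict("quantal_linear", [0.0, 1.0], 0.0) == 0.0
        # zero slope: flat curve at background (slope ~ 0 within support)
        assert predict("quantal_linear", [0.1, 1e-300], 5.0) == \
            pytest.approx(0.1)

    def test_background_at_dose_zero(self):
        for name in ("quantal_linear", "log_logistic", "log_probit", "gamma",
                     "weibull", "dichotomous_hill", "multistage_2"):
            theta = REFERENCE_THETA[name]
            assert predict(name, theta, 0.0) == pytest.approx(theta[0])

    def test_hill_plateau_limit(self):
        g, v = 0.02, 0.6
        plateau = predict("dichotomous_hill", [g, v, -1.0, 1.3], 1e12)
        assert plateau == pytest.approx(g + (1 - g) * v, rel=1e-6)

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            predict("quantal_linear", [0.0, 1.0], -1.0)

    @pytest.mark.parametrize("name", MODEL_NAMES)
    def test_monotone_nondecreasing_in_dose(self, name, rng):
        """Every family is non-decreasing in dose over its prior support."""
        model = get_model(name)
        grid = np.concatenate([[0.0], np.geomspace(1e-6, 1e4, 60)])
        for _ in range(40):
            p = model.prob(_random_theta(model, rng), grid)
            assert np.all(np.diff(p) >= -1e-12)
            assert np.all((p >= 0) & (p <= 1))


class TestLogLikelihood:
    def test_closed_form_single_group(self, bap):
        dataset = DoseResponseDataset(compound=bap, doses=[1.0], n=[10],
                                      incidence=[5])
        # force P(1) = 0.5 with a flat logistic curve
        value = log_likelihood(dataset, "logistic", [0.0, 1e-300])
        assert value == pytest.approx(math.log(math.comb(10, 5) * 0.5 ** 10))

    def test_saturated_fit_is_an_upper_bound(self, simple_dataset, rng):
        saturated = sum(
            stats.binom.logpmf(y, n, y / n)
            for y, n in zip(simple_dataset.incidence, simple_dataset.n))
        for name in MODEL_NAMES:
            model = get_model(name)
            for _ in range(20):
                value = log_likelihood(simple_dataset, name,
                                       _random_theta(model, rng))
                assert value <= saturated + 1e-9

    def test_agrees_with_binomial_pmf_oracle(self, bap, rng):
        """Dual route: our gammaln likelihood vs scipy.stats.binom pmf."""
        for _ in range(30):
            k = rng.integers(2, 6)
            doses = np.sort(rng.uniform(0.1, 20, size=k))
            n = rng.integers(5, 60, size=k)
            name = rng.choice(MODEL_NAMES)
            model = get_model(name)
            theta = _random_theta(model, rng)
            p = np.clip(model.prob(theta, doses), 1e-12, 1 - 1e-12)
            y = rng.binomial(n, p)
            dataset = DoseResponseDataset(
                compound=bap, doses=list(doses), n=list(map(int, n)),
                incidence=list(map(int, y)))
            oracle = float(np.sum(stats.binom.logpmf(y, n, p)))
            assert log_likelihood(dataset, name, theta) == \
                pytest.approx(oracle, abs=1e-10)


class TestComputeBMD:
    def test_quantal_linear_closed_form(self):
        bmd = compute_bmd("quantal_linear", [0.0, 1.0])
        assert bmd == pytest.approx(-math.log(0.9), rel=1e-12)

    def test_extra_risk_removes_background(self):
        for g in (0.0, 0.1, 0.4):
            assert compute_bmd("quantal_linear", [g, 1.0]) == \
                pytest.approx(-math.log(0.9), rel=1e-12)

    def test_weibull_root_matches_algebraic_inversion(self):
        g, alpha, b = 0.05, 2.0, 0.3
        algebraic = (-math.log(0.9) / b) ** (1 / alpha)
        assert compute_bmd("weibull", [g, alpha, b], method="root") == \
            pytest.approx(algebraic, rel=1e-8)

    @pytest.mark.parametrize("name", MODEL_NAMES)
    def test_root_finder_matches_closed_forms(self, name):
        theta = REFERENCE_THETA[name]
        closed = compute_bmd(name, theta, method="closed")
        root = compute_bmd(name, theta, method="root")
        assert root == pytest.approx(closed, rel=1e-6)

    @pytest.mark.parametrize("name", MODEL_NAMES)
    def test_extra_risk_identity_holds(self, name, rng):
        model = get_model(name)
        benchmark = BenchmarkSpec(bmr=0.1)
        checked = 0
        for _ in range(40):
            theta = _random_theta(model, rng)
            try:
                bmd = compute_bmd(name, theta, benchmark)
            except BenchmarkNotAttained:
                continue
            if bmd > 1e12:  # numerically degenerate flat draws
                continue
            assert float(model.extra_risk(theta, bmd)) == \
                pytest.approx(0.1, rel=1e-6)
            checked += 1
        assert checked >= 10

    def test_bmd_anti_monotone_in_slope(self):
        for name in ("quantal_linear", "weibull", "gamma"):
            theta = list(REFERENCE_THETA[name])
            bmds = []
            for scale in (0.5, 1.0, 2.0, 4.0):
                t = list(theta)
                t[-1] = theta[-1] * scale
                bmds.append(compute_bmd(name, t))
            assert all(b2 < b1 for b1, b2 in zip(bmds, bmds[1:]))

    def test_benchmark_not_attained_is_explicit(self):
        # Hill plateau at v=0.05 < bmr=0.1
        with pytest.raises(BenchmarkNotAttained):
            compute_bmd("dichotomous_hill", [0.02, 0.05, -1.0, 1.3])


class TestFitMap:
    def test_recovers_simulated_slope(self, bap):
        """Quantal-linear truth (g=0.01, b=0.5) recovered within 3 SD."""
        true_g, true_b = 0.01, 0.5
        doses = [0.0, 0.5, 1.0, 2.0, 4.0]
        rng = np.random.default_rng(2024)
        p = get_model("quantal_linear").prob([true_g, true_b], np.array(doses))
        dataset = DoseResponseDataset(
            compound=bap, doses=doses, n=[50] * 5,
            incidence=list(map(int, rng.binomial(50, p))))
        fit = fit_map(dataset, "quantal_linear", FitConfig(seed=0))
        assert fit.converged
        cov = np.linalg.inv(fit.hessian)
        sd_log_b = math.sqrt(cov[1, 1])
        assert abs(math.log(fit.theta["b"]) - math.log(true_b)) < 3 * sd_log_b

    def test_refit_same_seed_is_identical(self, simple_dataset):
        config = FitConfig(seed=42, n_starts=6)
        a = fit_map(simple_dataset, "weibull", config)
        b = fit_map(simple_dataset, "weibull", config)
        assert np.array_equal(a.theta_map, b.theta_map)
        assert a.log_posterior_at_map == b.log_posterior_at_map

    def test_all_zero_incidence_is_prior_driven(self, bap, fast_fit_config):
        dataset = DoseResponseDataset(
            compound=bap, doses=[0.0, 1.0, 3.0], n=[20] * 3,
            incidence=[0, 0, 0])
        fit = fit_map(dataset, "quantal_linear", fast_fit_config)
        assert fit.converged
        assert fit.theta["g"] < 0.1          # background pulled near zero
        assert math.isfinite(fit.bmd10) and fit.bmd10 > 0

    def test_requires_two_dose_levels(self, bap, fast_fit_config):
        dataset = DoseResponseDataset(compound=bap, doses=[1.0], n=[10],
                                      incidence=[3])
        with pytest.raises(ValueError, match="dose levels"):
            fit_map(dataset, "quantal_linear", fast_fit_config)

    @pytest.mark.parametrize("family", ["quantal_linear", "weibull",
                                        "log_logistic"])
    def test_bmd_recovery_across_simulations(self, family, bap):
        """Median relative BMD10 error below 15% at n=50/group, 5 doses."""
        model = get_model(family)
        theta = {"quantal_linear": [0.02, 0.11],
                 "weibull": [0.02, 1.5, 0.08],
                 "log_logistic": [0.02, -2.197, 2.0]}[family]
        true_bmd = compute_bmd(family, theta)
        doses = [0.0, 0.5, 1.0, 2.0, 4.0]
        config = FitConfig(seed=0, n_starts=4)
        errors, covered = [], []
        rng = np.random.default_rng(99)
        p = model.prob(theta, np.array(doses))
        for _ in range(200):
            dataset = DoseResponseDataset(
                compound=bap, doses=doses, n=[50] * 5,
                incidence=list(map(int, rng.binomial(50, p))))
            fit = fit_map(dataset, family, config)
            if fit.converged and math.isfinite(fit.bmd10):
                errors.append(abs(fit.bmd10 - true_bmd) / true_bmd)
                if family == "quantal_linear":
                    # log BMD = log(-log 0.9) - z_b: delta-method interval
                    sd = math.sqrt(np.linalg.inv(fit.hessian)[1, 1])
                    covered.append(
                        abs(math.log(fit.bmd10) - math.log(true_bmd))
                        < 1.645 * sd)
        assert len(errors) >= 190
        assert float(np.median(errors)) < 0.15
        if covered:
            # Gaussian-approximation 90% interval: sane, not exact
            assert 0.75 <= float(np.mean(covered)) <= 0.99
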