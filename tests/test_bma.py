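"""Model averaging: Laplace marginals, weights, mixtures, high-dose drops."""

import math

import numpy as np
import pytest

from pefkit.bma import (
    AveragingError,
    DropPolicy,
    drop_high_dose,
    marginal_likelihood_laplace,
    model_average,
)
from pefkit.bmd_models import (
    FitConfig,
    QuantalModelFit,
    fit_all,
    fit_map,
    get_model,
    log_likelihood,
    log_prior,
    to_natural,
)
from pefkit.types import Compound, DoseResponseDataset


def _stub_fit(name: str, log_marginal: float, bmd10: float = 1.0):
    """A converged fit with prescribed marginal, for weight arithmetic."""
    model = get_model(name)
    z = np.zeros(model.k)
    return QuantalModelFit(
        model=model, theta_map=to_natural(z, model.params), z_map=z,
        log_posterior_at_map=log_marginal,
        log_marginal_likelihood=log_marginal, bmd10=bmd10, converged=True,
        hessian=np.eye(model.k) * (2 * math.pi),  # Laplace correction = 0
        hessian_conditioning=1.0, params=model.params)


class TestLaplace:
    def test_gaussian_posterior_is_exact(self):
        """For an exactly Gaussian log-posterior the Laplace identity
        log Z = log p(MAP) + (k/2) log 2pi - 0.5 log det H is the integral."""
        fit = _stub_fit("quantal_linear", 0.0)
        fit.log_posterior_at_map = -1.25
        k = 2
        expected = -1.25 + 0.5 * k * math.log(2 * math.pi) \
            - 0.5 * math.log(np.linalg.det(fit.hessian))
        assert marginal_likelihood_laplace(fit) == pytest.approx(expected)
        assert expected == pytest.approx(-1.25)  # H = 2*pi*I cancels exactly

    def test_non_converged_fit_rejected(self):
        fit = _stub_fit("quantal_linear", 0.0)
        fit.converged = False
        with pytest.raises(ValueError, match="converge"):
            marginal_likelihood_laplace(fit)

    def test_matches_grid_quadrature_on_random_datasets(self, bap, rng):
        """Laplace log-marginals within 5% of brute-force 2-D quadrature
        across >= 50 random two-parameter datasets."""
        model = get_model("quantal_linear")
        params = model.params
        config = FitConfig(seed=0, n_starts=4)
        checked = 0
        while checked < 50:
            k = rng.integers(3, 6)
            doses = np.concatenate([[0.0], np.sort(rng.uniform(0.2, 10, k - 1))])
            n = int(rng.integers(10, 40))
            truth = [rng.uniform(0.0, 0.1), rng.uniform(0.05, 1.0)]
            y = rng.binomial(n, model.prob(truth, doses))
            dataset = DoseResponseDataset(
                compound=bap, doses=list(doses), n=[n] * k,
                incidence=list(map(int, y)))
            fit = fit_map(dataset, model, config)
            if not fit.converged:
                continue
            laplace = marginal_likelihood_laplace(fit)
            # vectorized trapezoid quadrature on the transformed scale
            z1 = np.linspace(fit.z_map[0] - 7, fit.z_map[0] + 7, 161)
            z2 = np.linspace(fit.z_map[1] - 7, fit.z_map[1] + 7, 161)
            zz1, zz2 = np.meshgrid(z1, z2, indexing="ij")
            g = 1 / (1 + np.exp(-zz1))[..., None]
            b = np.exp(zz2)[..., None]
            p = np.clip(g + (1 - g) * (1 - np.exp(-b * doses)), 1e-12, 1 - 1e-12)
            from scipy.special import gammaln
            loglik = (gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1)
                      + y * np.log(p) + (n - y) * np.log1p(-p)).sum(axis=-1)
            logprior = sum(
                -0.5 * ((zz - prm.prior_mean) / prm.prior_sd) ** 2
                - math.log(prm.prior_sd) - 0.5 * math.log(2 * math.pi)
                for zz, prm in zip((zz1, zz2), params))
            vals = loglik + logprior
            m = vals.max()
            quad = m + math.log(np.trapezoid(
                np.trapezoid(np.exp(vals - m), z2, axis=1), z1))
            assert laplace == pytest.approx(quad, abs=abs(quad) * 0.05)
            checked += 1


class TestModelAverage:
    def test_equal_marginals_split_evenly(self):
        fits = [_stub_fit("quantal_linear", -5.0), _stub_fit("weibull", -5.0)]
        result = model_average(fits, seed=0)
        assert result.weights["quantal_linear"] == pytest.approx(0.5)
        assert result.weights["weibull"] == pytest.approx(0.5)

    def test_log_three_gap_gives_three_to_one(self):
        fits = [_stub_fit("quantal_linear", -5.0 + math.log(3)),
                _stub_fit("weibull", -5.0)]
        result = model_average(fits, seed=0)
        assert result.weights["quantal_linear"] == pytest.approx(0.75)
        assert result.weights["weibull"] == pytest.approx(0.25)

    def test_weights_always_normalized(self, simple_dataset, fast_fit_config):
        fits = fit_all(simple_dataset, fast_fit_config)
        result = model_average(fits, seed=0)
        assert sum(result.weights.values()) == pytest.approx(1.0, abs=1e-12)
        assert all(w >= 0 for w in result.weights.values())

    def test_single_fit_degenerate_mixture(self, simple_dataset, fast_fit_config):
        fit = fit_map(simple_dataset, "quantal_linear", fast_fit_config)
        result = model_average([fit], seed=0)
        assert result.weights == {"quantal_linear": pytest.approx(1.0)}
        # mixture collapses to that model's own BMD distribution
        assert result.bmd10_point == pytest.approx(fit.bmd10, rel=0.25)

    def test_label_permutation_changes_nothing(self, simple_dataset,
                                               fast_fit_config):
        fits = fit_all(simple_dataset, fast_fit_config)
        forward = model_average(fits, seed=3)
        backward = model_average(fits[::-1], seed=3)
        assert forward.weights == backward.weights
        assert forward.bmd10_geometric == pytest.approx(
            backward.bmd10_geometric)

    def test_negligible_model_does_not_move_the_point(self, simple_dataset,
                                                      fast_fit_config):
        fits = fit_all(simple_dataset, fast_fit_config,
                       models=["quantal_linear", "weibull"])
        base = model_average(fits, seed=5)
        ghost = _stub_fit("logistic", min(
            f.log_marginal_likelihood for f in fits) - 60.0, bmd10=1e6)
        with_ghost = model_average(fits + [ghost], seed=5)
        assert with_ghost.bmd10_point == pytest.approx(
            base.bmd10_point, rel=1e-3)

    def test_no_converged_fit_is_a_hard_failure(self):
        fit = _stub_fit("quantal_linear", 0.0)
        fit.converged = False
        with pytest.raises(AveragingError):
            model_average([fit])

    def test_dose_rescaling_with_prior_shift_preserves_weights(
            self, bap, fast_fit_config):
        """Multiplying doses by 1000 while shifting the log-slope prior
        means by -log(1000) leaves the posterior model weights unchanged."""
        dataset = DoseResponseDataset(
            compound=bap, doses=[0.0, 1.0, 3.0, 10.0], n=[20] * 4,
            incidence=[1, 5, 12, 19])
        scaled = dataset.model_copy(update={
            "doses": [d * 1000 for d in dataset.doses]})
        # families where dose scaling maps exactly to a slope-prior shift
        # (b -> b/c; multistage: b1 -> b1/c, b2 -> b2/c^2); log-dose and
        # power families shear the parameter space instead, so a diagonal
        # prior cannot be matched exactly there
        models = ["quantal_linear", "logistic", "probit", "multistage_2"]
        shift = -math.log(1000.0)
        overrides = {}
        for name in models:
            for p in get_model(name).params:
                if p.kind == "log_slope":
                    factor = 2.0 if p.name == "b2" else 1.0
                    overrides[f"{name}.{p.name}"] = (
                        p.prior_mean + factor * shift, p.prior_sd)
        base = model_average(
            fit_all(dataset, fast_fit_config, models=models), seed=1)
        scaled_cfg = FitConfig(seed=0, n_starts=4, prior_overrides=overrides)
        other = model_average(
            fit_all(scaled, scaled_cfg, models=models), seed=1)
        for name in models:
            assert other.weights[name] == pytest.approx(
                base.weights[name], abs=0.02)


class TestDropHighDose:
    def _dataset(self, incidence, doses=None, n=30):
        return DoseResponseDataset(
            compound=Compound(name="X", short_form="X"),
            doses=doses or [0.0, 1.0, 2.0, 4.0][:len(incidence)],
            n=[n] * len(incidence), incidence=incidence)

    def test_plateau_detected_and_logged(self, fast_fit_config):
        cfg = FitConfig(seed=0, n_starts=4, models=("quantal_linear",))
        dataset = self._dataset([3, 18, 27, 27], doses=[1.0, 2.0, 4.0, 8.0])
        from pefkit.bma import _plateau
        assert _plateau(dataset)

    def test_strictly_increasing_keeps_all_doses(self):
        cfg = FitConfig(seed=0, n_starts=4, models=("quantal_linear",))
        dataset = self._dataset([0, 3, 9, 18])
        reduced, removed = drop_high_dose(dataset, "auto", cfg)
        assert removed == [] and reduced.doses == dataset.doses

    def test_auto_drop_improves_heuristic_on_saturating_data(self, rng):
        """Hill-generated saturating incidence fit with quantal-linear:
        dropping the plateau dose must improve the goodness heuristic."""
        from pefkit.bma import _mean_log_marginal, _without_top
        hill = get_model("dichotomous_hill")
        doses = [0.0, 0.5, 1.0, 2.0, 4.0, 8.0]
        p = hill.prob([0.01, 0.55, 1.0, 2.0], np.array(doses))
        dataset = self._dataset(list(map(int, rng.binomial(50, p))),
                                doses=doses, n=50)
        cfg = FitConfig(seed=0, n_starts=4, models=("quantal_linear",))
        full = _mean_log_marginal(dataset, cfg)
        reduced = _mean_log_marginal(_without_top(dataset), cfg)
        assert reduced > full
        trimmed, removed = drop_high_dose(dataset, "auto", cfg)
        assert removed and removed[0] == 8.0

    def test_never_drops_below_two_nonzero_doses(self):
        dataset = self._dataset([0, 3, 9])  # two non-zero doses only
        cfg = FitConfig(seed=0, n_starts=4, models=("quantal_linear",))
        reduced, removed = drop_high_dose(dataset, "auto", cfg)
        assert removed == []
        with pytest.raises(ValueError, match="two non-zero"):
            drop_high_dose(dataset, DropPolicy(
                mode="manual", doses_to_drop=(2.0,)), cfg)

    def test_manual_drop_removes_listed_doses(self):
        dataset = self._dataset([0, 3, 9, 18])
        reduced, removed = drop_high_dose(
            dataset, DropPolicy(mode="manual", doses_to_drop=(4.0,)))
        assert removed == [4.0] and 4.0 not in reduced.doses
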