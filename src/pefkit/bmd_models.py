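"""Dichotomous dose-response models with binomial likelihood and BMD inversion.

The suite is the standard quantal family set used for cancer bioassay
benchmark-dose work: quantal-linear, logistic, log-logistic, probit,
log-probit, gamma, Weibull, dichotomous Hill, and a degree-2 multistage.
Background-additive ("extra-risk") parameterizations are used for the
log-dose families:

    P(d) = g + (1 - g) * F(d; theta),      P(0) = g,

while logistic and probit act directly on the dose scale. Power and slope
parameters are left *unrestricted* (no hard lower bound at 1) and are
regularized instead by soft priors on a log scale, the consensus approach
for Bayesian model averaging of quantal models.

Fitting is penalized maximum likelihood (MAP) on an unconstrained
transformed scale (logit for probabilities, log for positive parameters)
with seeded multi-start L-BFGS-B. The benchmark dose BMD solves the
extra-risk identity

    [P(BMD) - P(0)] / [1 - P(0)] = BMR      (BMR = 0.1 by default)

by closed form for every family in the suite; a bracketed root-finder is
also provided and used as an internal cross-check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy import optimize, special

from pefkit.types import DoseResponseDataset

_P_EPS = 1e-12  # probability clipping bound for the likelihood


class BenchmarkNotAttained(ValueError):
    """The fitted curve plateaus below the benchmark response."""


@dataclass(frozen=True)
class BenchmarkSpec:
    """Benchmark response definition: extra risk at level ``bmr``."""

    bmr: float = 0.1
    risk_type: str = "extra_risk"

    def __post_init__(self) -> None:
        if not 0 < self.bmr < 1:
            raise ValueError("bmr must be in (0, 1)")
        if self.risk_type != "extra_risk":
            raise ValueError("only extra_risk is supported")


# ---------------------------------------------------------------------------
# parameter transforms and soft-constraint priors


@dataclass(frozen=True)
class Param:
    """One model parameter: natural name, transform kind, prior on the
    transformed scale, and box bounds on the transformed scale."""

    name: str
    kind: str                     # 'logit' | 'log_slope' | 'log_power' | 'linear'
    prior_mean: float = 0.0
    prior_sd: float = 2.0
    lo: float = -18.0
    hi: float = 18.0


def _logit_param(name: str) -> Param:
    return Param(name, "logit", 0.0, 2.0, -18.0, 18.0)


def _slope_param(name: str) -> Param:
    return Param(name, "log_slope", 0.0, 2.0, -18.0, 18.0)


def _power_param(name: str) -> Param:
    # powers soft-constrained near 1 on the log scale, hard-capped below 40
    return Param(name, "log_power", 0.0, 1.0, -7.0, math.log(40.0))


def _linear_param(name: str) -> Param:
    return Param(name, "linear", 0.0, 4.0, -40.0, 40.0)


def to_natural(z: np.ndarray, params: Sequence[Param]) -> np.ndarray:
    out = np.empty_like(np.asarray(z, dtype=float))
    for i, p in enumerate(params):
        if p.kind == "logit":
            out[i] = special.expit(z[i])
        elif p.kind in ("log_slope", "log_power"):
            out[i] = np.exp(z[i])
        else:
            out[i] = z[i]
    return out


def to_transformed(theta: np.ndarray, params: Sequence[Param]) -> np.ndarray:
    out = np.empty(len(params))
    for i, p in enumerate(params):
        if p.kind == "logit":
            out[i] = special.logit(theta[i])
        elif p.kind in ("log_slope", "log_power"):
            out[i] = math.log(theta[i])
        else:
            out[i] = theta[i]
    return out


def log_prior(z: np.ndarray, params: Sequence[Param]) -> float:
    total = 0.0
    for zi, p in zip(z, params):
        total += -0.5 * ((zi - p.prior_mean) / p.prior_sd) ** 2 \
            - math.log(p.prior_sd) - 0.5 * math.log(2 * math.pi)
    return total


# ---------------------------------------------------------------------------
# model families


@dataclass(frozen=True)
class ModelFamily:
    """One quantal family: probability function and closed-form BMD."""

    name: str
    params: tuple[Param, ...]
    _prob: Callable[[np.ndarray, np.ndarray], np.ndarray]
    _bmd: Callable[[np.ndarray, float], np.ndarray]
    #: optional numerically-stable extra-risk override (complementary form)
    _extra: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None

    @property
    def k(self) -> int:
        return len(self.params)

    def prob(self, theta: Sequence[float], dose) -> np.ndarray:
        dose = np.asarray(dose, dtype=float)
        if np.any(dose < 0):
            raise ValueError("dose must be non-negative")
        theta = np.asarray(theta, dtype=float)
        return np.clip(self._prob(theta, dose), 0.0, 1.0)

    def extra_risk(self, theta: Sequence[float], dose) -> np.ndarray:
        theta = np.asarray(theta, dtype=float)
        if self._extra is not None:
            return self._extra(theta, np.asarray(dose, dtype=float))
        p0 = self.prob(theta, 0.0)
        return (self.prob(theta, dose) - p0) / (1.0 - p0)

    def bmd_closed(self, theta: Sequence[float], bmr: float) -> float:
        """Closed-form extra-risk BMD; nan when the benchmark is not attained."""
        return float(self._bmd(np.asarray(theta, dtype=float), bmr))

    def bmd_closed_vec(self, thetas: np.ndarray, bmr: float) -> np.ndarray:
        """Vectorized closed form over an (m, k) array of parameter vectors."""
        return self._bmd(thetas.T, bmr)

    def theta_dict(self, theta: Sequence[float]) -> dict[str, float]:
        return {p.name: float(v) for p, v in zip(self.params, theta)}


def _ql_prob(t, d):
    g, b = t
    return g + (1 - g) * (-np.expm1(-b * d))


def _ql_bmd(t, r):
    g, b = t
    return -np.log1p(-r) / b


def _logistic_prob(t, d):
    a, b = t
    return special.expit(a + b * d)


def _logistic_bmd(t, r):
    # survival form: expit(-(a + b d)) = (1 - r) expit(-a), stable for a >> 0
    a, b = t
    return (-a - special.logit((1 - r) * special.expit(-a))) / b


def _logistic_extra(t, d):
    a, b = t
    return 1.0 - special.expit(-(a + b * d)) / special.expit(-a)


def _probit_prob(t, d):
    a, b = t
    return special.ndtr(a + b * d)


def _probit_bmd(t, r):
    # survival form: ndtr(-(a + b d)) = (1 - r) ndtr(-a), stable for a >> 0
    a, b = t
    return (-special.ndtri((1 - r) * special.ndtr(-a)) - a) / b


def _probit_extra(t, d):
    a, b = t
    return 1.0 - special.ndtr(-(a + b * d)) / special.ndtr(-a)


def _loglogistic_prob(t, d):
    g, a, b = t
    with np.errstate(divide="ignore"):
        f = special.expit(a + b * np.log(d))
    return g + (1 - g) * np.where(np.asarray(d) > 0, f, 0.0)


def _loglogistic_bmd(t, r):
    g, a, b = t
    return np.exp((special.logit(r) - a) / b)


def _logprobit_prob(t, d):
    g, a, b = t
    with np.errstate(divide="ignore"):
        f = special.ndtr(a + b * np.log(d))
    return g + (1 - g) * np.where(np.asarray(d) > 0, f, 0.0)


def _logprobit_bmd(t, r):
    g, a, b = t
    return np.exp((special.ndtri(r) - a) / b)


def _gamma_prob(t, d):
    g, alpha, b = t
    return g + (1 - g) * special.gammainc(alpha, b * d)


def _gamma_bmd(t, r):
    g, alpha, b = t
    return special.gammaincinv(alpha, r) / b


def _weibull_prob(t, d):
    g, alpha, b = t
    return g + (1 - g) * (-np.expm1(-b * np.asarray(d, dtype=float) ** alpha))


def _weibull_bmd(t, r):
    g, alpha, b = t
    return (-np.log1p(-r) / b) ** (1.0 / alpha)


def _hill_prob(t, d):
    g, v, a, b = t
    with np.errstate(divide="ignore"):
        f = special.expit(a + b * np.log(d))
    return g + (1 - g) * v * np.where(np.asarray(d) > 0, f, 0.0)


def _hill_bmd(t, r):
    g, v, a, b = t
    # extra risk plateaus at v: benchmark attained only when r < v
    ratio = np.divide(r, v, out=np.full_like(np.asarray(v, dtype=float), np.inf),
                      where=np.asarray(v) > 0)
    with np.errstate(invalid="ignore"):
        return np.where(ratio < 1.0, np.exp((special.logit(ratio) - a) / b), np.nan)


def _ms2_prob(t, d):
    g, b1, b2 = t
    d = np.asarray(d, dtype=float)
    return g + (1 - g) * (-np.expm1(-(b1 * d + b2 * d * d)))


def _ms2_bmd(t, r):
    g, b1, b2 = t
    c = -np.log1p(-r)
    with np.errstate(invalid="ignore", divide="ignore"):
        disc = np.sqrt(b1 * b1 + 4.0 * b2 * c)
        quad = (disc - b1) / (2.0 * b2)
        lin = c / b1
    return np.where(np.asarray(b2) > 1e-12, quad, lin)


MODELS: dict[str, ModelFamily] = {
    m.name: m for m in [
        ModelFamily("quantal_linear",
                    (_logit_param("g"), _slope_param("b")),
                    _ql_prob, _ql_bmd),
        ModelFamily("logistic",
                    (_linear_param("a"), _slope_param("b")),
                    _logistic_prob, _logistic_bmd, _logistic_extra),
        ModelFamily("probit",
                    (_linear_param("a"), _slope_param("b")),
                    _probit_prob, _probit_bmd, _probit_extra),
        ModelFamily("log_logistic",
                    (_logit_param("g"), _linear_param("a"), _power_param("b")),
                    _loglogistic_prob, _loglogistic_bmd),
        ModelFamily("log_probit",
                    (_logit_param("g"), _linear_param("a"), _power_param("b")),
                    _logprobit_prob, _logprobit_bmd),
        ModelFamily("gamma",
                    (_logit_param("g"), _power_param("alpha"), _slope_param("b")),
                    _gamma_prob, _gamma_bmd),
        ModelFamily("weibull",
                    (_logit_param("g"), _power_param("alpha"), _slope_param("b")),
                    _weibull_prob, _weibull_bmd),
        ModelFamily("dichotomous_hill",
                    (_logit_param("g"), _logit_param("v"),
                     _linear_param("a"), _power_param("b")),
                    _hill_prob, _hill_bmd),
        ModelFamily("multistage_2",
                    (_logit_param("g"), _slope_param("b1"), _slope_param("b2")),
                    _ms2_prob, _ms2_bmd),
    ]
}

MODEL_NAMES: tuple[str, ...] = tuple(MODELS)


def get_model(name) -> ModelFamily:
    if isinstance(name, ModelFamily):
        return name
    try:
        return MODELS[name]
    except KeyError:
        raise KeyError(f"unknown model family: {name!r}") from None


def predict(spec, theta: Sequence[float], dose) -> np.ndarray | float:
    """P(dose; theta) for a model family; scalar in, scalar out."""
    model = get_model(spec)
    result = model.prob(theta, dose)
    return float(result) if np.isscalar(dose) or np.ndim(dose) == 0 else result


# ---------------------------------------------------------------------------
# likelihood


def log_likelihood(dataset: DoseResponseDataset, spec, theta: Sequence[float]) -> float:
    """Binomial log-likelihood of the incidence table under P(d; theta).

    Probabilities are clipped to [1e-12, 1 - 1e-12] so boundary parameter
    values yield a finite (heavily penalized) value rather than -inf.
    """
    model = get_model(spec)
    d = np.asarray(dataset.doses, dtype=float)
    n = np.asarray(dataset.n, dtype=float)
    y = np.asarray(dataset.incidence, dtype=float)
    p = np.clip(model.prob(theta, d), _P_EPS, 1.0 - _P_EPS)
    coef = special.gammaln(n + 1) - special.gammaln(y + 1) - special.gammaln(n - y + 1)
    return float(np.sum(coef + y * np.log(p) + (n - y) * np.log1p(-p)))


# ---------------------------------------------------------------------------
# BMD inversion


def compute_bmd(spec, theta: Sequence[float],
                benchmark: BenchmarkSpec | None = None,
                method: str = "closed") -> float:
    """Extra-risk benchmark dose for a fitted curve.

    ``method='closed'`` uses the family's algebraic inversion;
    ``method='root'`` brackets and solves the defining equation numerically
    (relative tolerance 1e-8). Raises :class:`BenchmarkNotAttained` when the
    curve plateaus below the benchmark response.
    """
    benchmark = benchmark or BenchmarkSpec()
    model = get_model(spec)
    theta = np.asarray(theta, dtype=float)
    if method == "closed":
        bmd = model.bmd_closed(theta, benchmark.bmr)
        if not math.isfinite(bmd) or bmd <= 0:
            raise BenchmarkNotAttained(
                f"{model.name}: benchmark response {benchmark.bmr} not attained")
        return bmd
    if method != "root":
        raise ValueError(f"unknown method: {method}")

    def deficit(d: float) -> float:
        return float(model.extra_risk(theta, d)) - benchmark.bmr

    hi = 1.0
    for _ in range(200):
        if deficit(hi) > 0:
            break
        hi *= 2.0
    else:
        raise BenchmarkNotAttained(
            f"{model.name}: extra risk stays below {benchmark.bmr} up to dose {hi}")
    lo = hi / 2.0 if hi > 1.0 else 0.0
    while lo > 0 and deficit(lo) > 0:
        lo /= 2.0
    return float(optimize.brentq(deficit, lo, hi, rtol=1e-10, maxiter=200))


# ---------------------------------------------------------------------------
# MAP fitting


@dataclass(frozen=True)
class FitConfig:
    """Optimizer and prior settings for MAP fitting.

    ``prior_overrides`` maps "model.param" to (prior_mean, prior_sd) pairs
    on the transformed scale, centralizing every soft-constraint
    hyper-value in one block.
    """

    n_starts: int = 10
    seed: int = 0
    maxiter: int = 500
    gtol: float = 1e-8
    prior_overrides: dict = field(default_factory=dict)
    models: tuple[str, ...] | None = None   # None = full suite

    def params_for(self, model: ModelFamily) -> tuple[Param, ...]:
        out = []
        for p in model.params:
            override = self.prior_overrides.get(f"{model.name}.{p.name}")
            out.append(replace(p, prior_mean=override[0], prior_sd=override[1])
                       if override else p)
        return tuple(out)


@dataclass
class QuantalModelFit:
    """One fitted family: MAP estimate, curvature, marginal likelihood, BMD."""

    model: ModelFamily
    theta_map: np.ndarray            # natural scale
    z_map: np.ndarray                # transformed scale
    log_posterior_at_map: float
    log_marginal_likelihood: float   # Laplace approximation
    bmd10: float                     # nan when benchmark not attained
    converged: bool
    hessian: np.ndarray              # curvature of -log posterior at MAP (z scale)
    hessian_conditioning: float
    params: tuple[Param, ...]
    message: str = ""

    @property
    def name(self) -> str:
        return self.model.name

    @property
    def theta(self) -> dict[str, float]:
        return self.model.theta_dict(self.theta_map)


def _fd_hessian(f: Callable[[np.ndarray], float], z: np.ndarray,
                rel_step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian with per-coordinate steps."""
    k = len(z)
    h = rel_step * np.maximum(1.0, np.abs(z))
    hess = np.empty((k, k))
    f0 = f(z)
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = h[i]
        hess[i, i] = (f(z + ei) - 2 * f0 + f(z - ei)) / h[i] ** 2
        for j in range(i + 1, k):
            ej = np.zeros(k)
            ej[j] = h[j]
            fij = f(z + ei + ej) - f(z + ei - ej) - f(z - ei + ej) + f(z - ei - ej)
            hess[i, j] = hess[j, i] = fij / (4 * h[i] * h[j])
    return hess


def _laplace_log_marginal(log_post: float, hessian: np.ndarray) -> float:
    """log Z ~= log p(D, theta_map) + (k/2) log 2pi - 1/2 log det H."""
    k = hessian.shape[0]
    sign, logdet = np.linalg.slogdet(hessian)
    if sign <= 0:
        return float("nan")
    return log_post + 0.5 * k * math.log(2 * math.pi) - 0.5 * logdet


def fit_map(dataset: DoseResponseDataset, spec,
            config: FitConfig | None = None,
            benchmark: BenchmarkSpec | None = None) -> QuantalModelFit:
    """Penalized-likelihood (MAP) fit of one family by seeded multi-start.

    Starts are the prior mean plus prior-scaled Gaussian perturbations; the
    best converged optimum is kept. Refitting with the same seed is
    deterministic. Non-convergence across all starts is flagged rather than
    raised, so model averaging can exclude the fit with a logged reason.
    """
    config = config or FitConfig()
    benchmark = benchmark or BenchmarkSpec()
    model = get_model(spec)
    nonzero = sum(d > 0 for d in dataset.doses)
    if len(set(dataset.doses)) < 2 or nonzero < 1:
        raise ValueError("dataset needs >=2 distinct dose levels with >=1 non-zero")
    params = config.params_for(model)
    bounds = [(p.lo, p.hi) for p in params]

    def neg_log_post(z: np.ndarray) -> float:
        theta = to_natural(z, params)
        return -(log_likelihood(dataset, model, theta) + log_prior(z, params))

    # deterministic per-(seed, model) start points
    rng = np.random.default_rng(
        [config.seed, MODEL_NAMES.index(model.name) + 1])
    means = np.array([p.prior_mean for p in params])
    sds = np.array([p.prior_sd for p in params])
    starts = [means] + [
        np.clip(means + sds * rng.standard_normal(len(params)),
                [b[0] for b in bounds], [b[1] for b in bounds])
        for _ in range(max(0, config.n_starts - 1))
    ]

    best = None
    for z0 in starts:
        res = optimize.minimize(
            neg_log_post, z0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": config.maxiter, "gtol": config.gtol,
                     "ftol": 1e-12})
        if not np.isfinite(res.fun):
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        return QuantalModelFit(
            model=model, theta_map=to_natural(means, params), z_map=means,
            log_posterior_at_map=float("nan"),
            log_marginal_likelihood=float("nan"), bmd10=float("nan"),
            converged=False, hessian=np.eye(len(params)),
            hessian_conditioning=float("inf"), params=params,
            message="no start produced a finite posterior")

    z_map = np.asarray(best.x)
    fun = float(best.fun)
    success = bool(best.success)
    if not success:
        # line-search breakdowns can stop L-BFGS-B at the optimum anyway;
        # polish derivative-free and judge convergence by the gradient
        polish = optimize.minimize(
            neg_log_post, z_map, method="Nelder-Mead",
            options={"maxiter": 2000, "xatol": 1e-9, "fatol": 1e-12})
        if np.isfinite(polish.fun) and polish.fun <= fun:
            z_map = np.clip(np.asarray(polish.x),
                            [b[0] for b in bounds], [b[1] for b in bounds])
            fun = float(neg_log_post(z_map))
        grad = optimize.approx_fprime(z_map, neg_log_post, 1e-6)
        # ignore gradient components pinned at an active bound
        for i, (lo, hi) in enumerate(bounds):
            if (z_map[i] <= lo + 1e-9 and grad[i] > 0) or \
               (z_map[i] >= hi - 1e-9 and grad[i] < 0):
                grad[i] = 0.0
        success = bool(np.linalg.norm(grad, ord=np.inf) < 1e-3 * max(1.0, abs(fun)))
    theta_map = to_natural(z_map, params)
    log_post = -fun
    hessian = _fd_hessian(neg_log_post, z_map)
    try:
        conditioning = float(np.linalg.cond(hessian))
    except np.linalg.LinAlgError:  # pragma: no cover
        conditioning = float("inf")
    log_marginal = _laplace_log_marginal(log_post, hessian)
    converged = success and math.isfinite(log_post)
    try:
        bmd10 = compute_bmd(model, theta_map, benchmark)
    except BenchmarkNotAttained:
        bmd10 = float("nan")
    return QuantalModelFit(
        model=model, theta_map=theta_map, z_map=z_map,
        log_posterior_at_map=log_post, log_marginal_likelihood=log_marginal,
        bmd10=bmd10, converged=converged, hessian=hessian,
        hessian_conditioning=conditioning, params=params,
        message=str(best.message))


def fit_all(dataset: DoseResponseDataset,
            config: FitConfig | None = None,
            benchmark: BenchmarkSpec | None = None,
            models: Sequence[str] | None = None) -> list[QuantalModelFit]:
    """Fit every family in the suite (or a named subset) to one dataset."""
    if models is None and config is not None and config.models is not None:
        models = config.models
    names = list(models) if models is not None else list(MODEL_NAMES)
    return [fit_map(dataset, name, config, benchmark) for name in names]
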