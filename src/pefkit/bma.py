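"""Bayesian model averaging of quantal fits and the high-dose drop rule.

Model weights are posterior model probabilities from Laplace-approximated
marginal likelihoods with (by default) equal prior model probabilities:

    w_m  propto  p(M_m) * exp(log Z_m),
    log Z_m = log p(D | theta_MAP, M_m) p(theta_MAP | M_m)
              + (k_m/2) log 2*pi - 1/2 log det H_m.

The averaged BMD10 distribution is the weight-mixture of per-model BMD
samples, each obtained by pushing Gaussian (MAP, curvature) parameter draws
through the extra-risk inversion. The reported point estimate is the
mixture median; a weighted geometric combination of per-model BMDs is
reported alongside for comparison. The 5th percentile (a BMDL10 analogue)
is computed but deliberately unused downstream: potency ratios are formed
from central BMD estimates, not lower confidence bounds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import special

from pefkit.bmd_models import (
    BenchmarkSpec,
    FitConfig,
    QuantalModelFit,
    _laplace_log_marginal,
    fit_all,
    to_natural,
)
from pefkit.types import DoseResponseDataset


class AveragingError(RuntimeError):
    """No converged fit was available to average."""


def marginal_likelihood_laplace(fit: QuantalModelFit) -> float:
    """Laplace log marginal likelihood of one converged fit.

    Requires positive-definite curvature at the MAP; otherwise raises so
    the caller can exclude the fit with a diagnostic.
    """
    if not fit.converged:
        raise ValueError(f"{fit.name}: fit did not converge")
    value = _laplace_log_marginal(fit.log_posterior_at_map, fit.hessian)
    if not math.isfinite(value):
        raise ValueError(f"{fit.name}: curvature at MAP is not positive definite")
    return value


@dataclass
class BMAResult:
    """Posterior model weights and the model-averaged BMD10."""

    weights: dict[str, float]
    bmd10_point: float                  # median of the weighted mixture
    bmd10_geometric: float              # weighted geometric mean of per-model BMDs
    bmd10_samples: np.ndarray
    bmdl10: float                       # 5th percentile; reported, unused downstream
    dropped_doses: list[float] = field(default_factory=list)
    diagnostics: dict[str, str] = field(default_factory=dict)


def _usable(fit: QuantalModelFit) -> tuple[bool, str]:
    if not fit.converged:
        return False, "did not converge"
    if not math.isfinite(fit.log_marginal_likelihood):
        return False, "non-positive-definite curvature at MAP"
    if not math.isfinite(fit.bmd10) or fit.bmd10 <= 0:
        return False, "benchmark response not attained at MAP"
    return True, "ok"


def model_average(
    fits: Sequence[QuantalModelFit],
    prior_model_probs: Sequence[float] | None = None,
    benchmark: BenchmarkSpec | None = None,
    n_samples: int = 4000,
    seed: int = 0,
) -> BMAResult:
    """Average converged fits into a single BMD10 distribution.

    Per-model BMD uncertainty comes from the Gaussian approximation at the
    MAP (on the transformed parameter scale) pushed through the closed-form
    extra-risk inversion; draws where the benchmark is not attained are
    discarded and noted in the diagnostics.
    """
    benchmark = benchmark or BenchmarkSpec()
    fits = list(fits)
    if prior_model_probs is None:
        priors = np.full(len(fits), 1.0 / max(len(fits), 1))
    else:
        priors = np.asarray(prior_model_probs, dtype=float)
        if len(priors) != len(fits):
            raise ValueError("prior_model_probs length mismatch")

    diagnostics: dict[str, str] = {}
    usable_idx = []
    for i, fit in enumerate(fits):
        ok, why = _usable(fit)
        diagnostics[fit.name] = why
        if ok:
            usable_idx.append(i)
    if not usable_idx:
        raise AveragingError("no converged fit to average")

    log_w = np.array([
        math.log(priors[i]) + fits[i].log_marginal_likelihood for i in usable_idx
    ])
    log_w -= special.logsumexp(log_w)
    weights_used = np.exp(log_w)
    weights = {fit.name: 0.0 for fit in fits}
    for w, i in zip(weights_used, usable_idx):
        weights[fits[i].name] = float(w)

    rng = np.random.default_rng([seed, 7919])
    pooled: list[np.ndarray] = []
    for w, i in zip(weights_used, usable_idx):
        fit = fits[i]
        m = int(round(w * n_samples))
        if m == 0:
            continue
        try:
            cov = np.linalg.inv(fit.hessian)
            chol = np.linalg.cholesky(cov + 1e-12 * np.eye(len(fit.z_map)))
        except np.linalg.LinAlgError:
            diagnostics[fit.name] = "curvature not invertible; point mass used"
            pooled.append(np.full(m, fit.bmd10))
            continue
        draws = fit.z_map + rng.standard_normal((m, len(fit.z_map))) @ chol.T
        draws = np.clip(draws, [p.lo for p in fit.params],
                        [p.hi for p in fit.params])
        thetas = np.stack([to_natural(z, fit.params) for z in draws])
        with np.errstate(invalid="ignore", divide="ignore", over="ignore"):
            bmds = np.asarray(fit.model.bmd_closed_vec(thetas, benchmark.bmr),
                              dtype=float)
        good = np.isfinite(bmds) & (bmds > 0)
        if not np.all(good):
            diagnostics[fit.name] = (
                f"ok; {int((~good).sum())}/{m} draws below benchmark discarded")
        pooled.append(bmds[good])
    samples = np.concatenate(pooled) if pooled else np.array([])
    if samples.size == 0:
        # degenerate: every sampled draw failed; fall back to MAP point masses
        samples = np.array([fits[i].bmd10 for i in usable_idx])

    geometric = float(np.exp(np.sum(
        weights_used * np.log([fits[i].bmd10 for i in usable_idx]))))
    return BMAResult(
        weights=weights,
        bmd10_point=float(np.median(samples)),
        bmd10_geometric=geometric,
        bmd10_samples=samples,
        bmdl10=float(np.percentile(samples, 5)),
        diagnostics=diagnostics,
    )


@dataclass(frozen=True)
class DropPolicy:
    """High-dose elimination policy.

    auto: drop the top dose while the dose-response has plateaued (top-dose
    response within one pooled binomial standard error of the next-lower
    dose) and the mixture-weighted mean log marginal improves; never drops
    below two non-zero doses. manual: drop the explicitly listed doses.
    """

    mode: str = "none"                    # 'none' | 'auto' | 'manual'
    doses_to_drop: tuple[float, ...] = ()
    min_nonzero_doses: int = 2


def _plateau(dataset: DoseResponseDataset) -> bool:
    idx = [i for i, d in enumerate(dataset.doses) if d > 0]
    if len(idx) < 2:
        return False
    i_top, i_next = idx[-1], idx[-2]
    p_top = dataset.incidence[i_top] / dataset.n[i_top]
    p_next = dataset.incidence[i_next] / dataset.n[i_next]
    pooled = ((dataset.incidence[i_top] + dataset.incidence[i_next])
              / (dataset.n[i_top] + dataset.n[i_next]))
    se = math.sqrt(max(pooled * (1 - pooled), 1e-12)
                   * (1 / dataset.n[i_top] + 1 / dataset.n[i_next]))
    return p_top <= p_next + se


def _without_top(dataset: DoseResponseDataset) -> DoseResponseDataset:
    idx = max(range(len(dataset.doses)), key=lambda i: dataset.doses[i])
    keep = [i for i in range(len(dataset.doses)) if i != idx]
    return dataset.model_copy(update={
        "doses": [dataset.doses[i] for i in keep],
        "n": [dataset.n[i] for i in keep],
        "incidence": [dataset.incidence[i] for i in keep],
    })


def _saturated_loglik(dataset: DoseResponseDataset) -> float:
    """Maximal attainable binomial log-likelihood (P = observed response)."""
    total = 0.0
    for n, y in zip(dataset.n, dataset.incidence):
        p = min(max(y / n, 1e-12), 1 - 1e-12)
        total += (special.gammaln(n + 1) - special.gammaln(y + 1)
                  - special.gammaln(n - y + 1)
                  + y * math.log(p) + (n - y) * math.log1p(-p))
    return total


def _mean_log_marginal(dataset: DoseResponseDataset,
                       config: FitConfig | None) -> float:
    """Drop heuristic: mixture-weighted mean log marginal, saturated-
    corrected and normalized per dose group.

    Subtracting the saturated log-likelihood and dividing by the number of
    groups makes fits on tables of different length comparable: a plateau
    group the suite cannot capture contributes a large misfit that dropping
    removes, while dropping a well-fit group only spreads the complexity
    penalty over fewer groups and worsens the score.
    """
    fits = fit_all(dataset, config)
    finite = [f for f in fits if _usable(f)[0]]
    if not finite:
        return -math.inf
    log_m = np.array([f.log_marginal_likelihood for f in finite])
    w = np.exp(log_m - special.logsumexp(log_m))
    return (float(np.sum(w * log_m)) - _saturated_loglik(dataset)) \
        / len(dataset.doses)


def drop_high_dose(
    dataset: DoseResponseDataset,
    policy: DropPolicy | str = "none",
    fit_config: FitConfig | None = None,
) -> tuple[DoseResponseDataset, list[float]]:
    """Sequentially eliminate top doses to improve fit where the response
    has plateaued. Returns the (possibly reduced) dataset and the removed
    doses, in removal order."""
    if isinstance(policy, str):
        policy = DropPolicy(mode=policy)
    removed: list[float] = []
    if policy.mode == "none":
        return dataset, removed

    def nonzero(ds: DoseResponseDataset) -> int:
        return sum(d > 0 for d in ds.doses)

    if policy.mode == "manual":
        current = dataset
        for dose in policy.doses_to_drop:
            if dose not in current.doses:
                raise ValueError(f"dose {dose} not present")
            if nonzero(current) - (dose > 0) < policy.min_nonzero_doses:
                raise ValueError("cannot drop below two non-zero doses")
            keep = [i for i, d in enumerate(current.doses) if d != dose]
            current = current.model_copy(update={
                "doses": [current.doses[i] for i in keep],
                "n": [current.n[i] for i in keep],
                "incidence": [current.incidence[i] for i in keep],
            })
            removed.append(dose)
        return current, removed

    if policy.mode != "auto":
        raise ValueError(f"unknown drop policy: {policy.mode}")
    if nonzero(dataset) < 3:
        return dataset, removed

    current = dataset
    score = _mean_log_marginal(current, fit_config)
    while nonzero(current) > policy.min_nonzero_doses and _plateau(current):
        candidate = _without_top(current)
        candidate_score = _mean_log_marginal(candidate, fit_config)
        if candidate_score <= score:
            break
        removed.append(max(current.doses))
        current, score = candidate, candidate_score
    return current, removed
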