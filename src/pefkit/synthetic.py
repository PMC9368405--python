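"""Synthetic bioassay generators with known ground truth.

Emulates the historical skin-painting designs the screen catalogues:
single- or multi-dose arms (with or without a solvent control), binomial
tumor incidence from a known quantal dose-response curve, and paired
target/comparator arms with a prescribed true potency ratio. The default
comparator curve is a log-logistic with 2% background and a BMD10 of 1.0
dose unit, so that historical dose ranges (0.1-100 units) straddle the
benchmark region.

Scenario collections deliberately construct records whose screening
disposition is known by construction, for engine tests:

- ``passing``: monotone sub-50% low-dose responses in both arms.
- ``single_dose_high_response``: one dose with >50% response (enforced).
- ``non_monotonic_noise``: peak response at a middle dose (enforced).
- ``minimal_response``: at most one tumor-bearing animal (enforced).
- ``plateau_top_dose``: true response equal at the top two doses.

Where binomial noise could overturn the intended disposition, the drawn
incidence is minimally adjusted to guarantee it; the adjustment is part of
the scenario's definition, not an afterthought of any particular draw.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import special

from pefkit.bmd_models import get_model
from pefkit.types import (
    Compound,
    DoseGroup,
    DoseResponseDataset,
    DoseUnit,
    ExperimentRecord,
    StudyType,
)

SCENARIOS = (
    "passing",
    "single_dose_high_response",
    "non_monotonic_noise",
    "minimal_response",
    "plateau_top_dose",
)

#: Default comparator (BaP) truth: log-logistic, background 2%, BMD10 = 1.
DEFAULT_MODEL = "log_logistic"
DEFAULT_SLOPE = 1.2


def _log_family_theta(model_name: str, bmd10: float, g: float,
                      slope: float, bmr: float = 0.1) -> list[float]:
    """Intercept placement so the curve's extra-risk BMD equals ``bmd10``."""
    if model_name == "log_logistic":
        a = special.logit(bmr) - slope * math.log(bmd10)
        return [g, a, slope]
    if model_name == "log_probit":
        a = special.ndtri(bmr) - slope * math.log(bmd10)
        return [g, a, slope]
    if model_name == "quantal_linear":
        return [g, -math.log1p(-bmr) / bmd10]
    if model_name == "weibull":
        return [g, slope, -math.log1p(-bmr) / bmd10 ** slope]
    raise ValueError(f"no truth constructor for family {model_name!r}")


@dataclass(frozen=True)
class GeneratorConfig:
    """Ground-truth configuration for one generated arm or arm pair."""

    true_model: str = DEFAULT_MODEL
    true_theta: tuple[float, ...] = ()
    bmd10: float = 1.0
    background: float = 0.02
    slope: float = DEFAULT_SLOPE
    dose_design: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0, 4.0, 8.0)
    n_per_group: int = 30
    seed: int = 0
    scenario: str = "passing"
    potency_ratio: float | None = None
    compound: str = "SYN"
    bmr: float = 0.1

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if any(d < 0 for d in self.dose_design):
            raise ValueError("doses must be non-negative")
        if not 0 <= self.background < 1:
            raise ValueError("background must be in [0, 1)")

    def theta(self) -> list[float]:
        if self.true_theta:
            theta = list(self.true_theta)
            model = get_model(self.true_model)
            from pefkit.bmd_models import to_transformed

            z = to_transformed(np.asarray(theta, dtype=float), model.params)
            if not np.all(np.isfinite(z)):
                raise ValueError(
                    f"theta {theta} outside the support of {model.name}")
            return theta
        return _log_family_theta(self.true_model, self.bmd10,
                                 self.background, self.slope, self.bmr)


def true_probabilities(config: GeneratorConfig,
                       doses: Sequence[float] | None = None) -> np.ndarray:
    model = get_model(config.true_model)
    doses = np.asarray(config.dose_design if doses is None else doses, float)
    return model.prob(config.theta(), doses)


def _scenario_doses(config: GeneratorConfig) -> tuple[float, ...]:
    if config.scenario == "single_dose_high_response":
        # one dose placed far above the BMD so the true response is high
        return (config.bmd10 * 50.0,)
    if config.scenario == "plateau_top_dose":
        base = [d for d in config.dose_design if d > 0]
        # duplicate the top of the curve: two doses deep in the plateau
        return tuple(sorted(set(base[:-1]))) + (config.bmd10 * 60.0,
                                                config.bmd10 * 100.0)
    return tuple(config.dose_design)


def _scenario_theta(config: GeneratorConfig) -> list[float]:
    if config.scenario == "minimal_response":
        # essentially flat curve: tiny slope contribution over the design
        return _log_family_theta(config.true_model, config.bmd10 * 1e4,
                                 0.0, config.slope, config.bmr)
    return config.theta()


def generate_dataset(config: GeneratorConfig,
                     seed_offset: int = 0) -> DoseResponseDataset:
    """One arm: incidence ~ Binomial(n, P(dose; true theta)), seeded."""
    doses = sorted(_scenario_doses(config))
    theta = _scenario_theta(config)
    model = get_model(config.true_model)
    probabilities = model.prob(theta, np.asarray(doses, float))
    rng = np.random.default_rng([config.seed, seed_offset, 104729])
    incidence = rng.binomial(config.n_per_group, probabilities).astype(int)

    n = config.n_per_group
    nonzero = [i for i, d in enumerate(doses) if d > 0]
    controls = [i for i, d in enumerate(doses) if d == 0]
    if config.scenario == "single_dose_high_response" and nonzero:
        i = nonzero[-1]
        incidence[i] = max(incidence[i], n // 2 + 1)
    elif config.scenario == "minimal_response":
        # one tumor-bearing animal, at the lowest non-zero dose
        for i in nonzero:
            incidence[i] = 0
        incidence[nonzero[0]] = 1
    elif config.scenario == "non_monotonic_noise" and len(nonzero) >= 3:
        mid, top = nonzero[len(nonzero) // 2], nonzero[-1]
        peak = max(incidence[i] for i in nonzero)
        incidence[mid] = min(n, max(incidence[mid], peak + 1, n // 3 + 1))
        if incidence[top] >= incidence[mid]:
            incidence[top] = incidence[mid] - 1
    elif config.scenario in ("passing", "plateau_top_dose"):
        # the intended disposition is modelable: make the noise realization
        # monotone, keep the lowest dose at or below 50%, keep at least one
        # responder, and keep the control at or below the 5% flag level
        ordered = sorted(incidence[i] for i in nonzero)
        for i, v in zip(nonzero, ordered):
            incidence[i] = v
        incidence[nonzero[0]] = min(incidence[nonzero[0]], n // 2)
        incidence[nonzero[-1]] = max(incidence[nonzero[-1]], 1)
        for i in controls:
            incidence[i] = min(incidence[i], int(0.05 * n))

    return DoseResponseDataset(
        compound=Compound(name=config.compound, short_form=config.compound),
        doses=list(map(float, doses)),
        n=[n] * len(doses),
        incidence=list(map(int, incidence)),
        publication_id=f"synthetic-seed{config.seed}",
        arm="target",
    )


def _dataset_to_groups(dataset: DoseResponseDataset) -> list[DoseGroup]:
    return [
        DoseGroup(dose=d, dose_unit=DoseUnit.MG, n=n, incidence=y)
        for d, n, y in zip(dataset.doses, dataset.n, dataset.incidence)
    ]


def generate_paired_experiment(config: GeneratorConfig,
                               seed_offset: int = 0) -> ExperimentRecord:
    """Concurrent target + comparator arms with a known true potency ratio.

    The comparator arm follows the reference curve with BMD10 =
    ``config.bmd10``; the target arm uses the same family and slope with
    its intercept shifted so that BMD10(BaP) / BMD10(target) equals
    ``potency_ratio`` exactly at the truth level.
    """
    if config.potency_ratio is None or config.potency_ratio <= 0:
        raise ValueError("potency_ratio must be a positive number")
    target_bmd = config.bmd10 / config.potency_ratio
    comparator_cfg = replace(config, compound="BaP", potency_ratio=None)
    target_cfg = replace(config, compound=config.compound, bmd10=target_bmd,
                         true_theta=(), potency_ratio=None)
    comparator = generate_dataset(comparator_cfg, seed_offset=2 * seed_offset)
    target = generate_dataset(target_cfg, seed_offset=2 * seed_offset + 1)
    return ExperimentRecord(
        publication_id=f"synthetic-seed{config.seed}",
        target_pah=config.compound,
        comparator="BaP",
        study_type=StudyType.INITIATION_PROMOTION,
        target_groups=_dataset_to_groups(target),
        comparator_groups=_dataset_to_groups(comparator),
        quality_notes=(f"synthetic pair, true potency ratio "
                       f"{config.potency_ratio}"),
        experiment_key=f"synthetic-seed{config.seed}-{seed_offset}",
    )


@dataclass(frozen=True)
class CollectionConfig:
    """Scenario mix for a synthetic screening collection."""

    scenario_counts: tuple[tuple[str, int], ...] = (
        ("passing", 10), ("single_dose_high_response", 20),
        ("non_monotonic_noise", 5), ("minimal_response", 5),
    )
    base: GeneratorConfig = field(default_factory=GeneratorConfig)
    seed: int = 0


#: screening stage each scenario is expected to reach
EXPECTED_STAGE = {
    "passing": "modelable",
    "plateau_top_dose": "modelable",
    "single_dose_high_response": "a_priori",
    "non_monotonic_noise": "dose_response",
    "minimal_response": "dose_response",
}


def generate_screening_collection(
    config: CollectionConfig,
) -> list[tuple[ExperimentRecord, str]]:
    """A mixed collection of paired records with known expected dispositions.

    Returns (record, expected_stage) pairs where the stage is the deepest
    screen stage the record is expected to pass: "a_priori",
    "dose_response", or "modelable". Per-record seeds derive
    deterministically from the record index.
    """
    out: list[tuple[ExperimentRecord, str]] = []
    index = 0
    for scenario, count in config.scenario_counts:
        for _ in range(count):
            cfg = replace(config.base, scenario=scenario,
                          seed=config.seed, potency_ratio=1.0,
                          compound=f"SYN{index:03d}")
            record = generate_paired_experiment(cfg, seed_offset=index)
            out.append((record, EXPECTED_STAGE[scenario]))
            index += 1
    return out
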