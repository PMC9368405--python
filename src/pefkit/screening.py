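"""Staged inclusion screen for PAH/BaP bioassay experiments.

Three stages, each a pure function of (record, config):

1. *A priori* criteria — tumor-incidence endpoint, physiological exposure
   route (oral, dermal, inhalation), and a concurrent BaP comparator arm
   from the same publication.
2. Dose-response criteria — the response at the single (or lowest non-zero)
   dose must be <= 50% in *both* arms, so the study carries information in
   the low-dose region; additional failures for non-positive results,
   excess mortality, and missing incidence counts (the latter two carried
   as transcription annotations, since the underlying survival data are not
   printed in the sources).
3. Modeling suitability — flags minimal tumor response, non-monotonic
   dose-response (peak response below the top dose), and high control
   response; a dataset is modelable iff no flag is raised.

A recorded adjudication (force_pass/force_fail) can override stage 2; the
strictly computed codes are retained alongside an ADJUDICATED marker so the
override is auditable.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from pefkit.types import (
    Adjudication,
    DoseGroup,
    EndpointType,
    ExperimentRecord,
    ExposureRoute,
    ReasonCode,
    ScreeningDisposition,
)

#: Annotation codes that, when transcribed onto a record, fail stage 2.
ANNOTATION_FAIL_CODES = frozenset({
    ReasonCode.NOT_INCIDENCE,
    ReasonCode.EXCESS_MORTALITY,
    ReasonCode.NON_POSITIVE,
})


@dataclass(frozen=True)
class ScreeningConfig:
    """Tunable thresholds of the screen.

    response_threshold: maximum acceptable response fraction at the single
        or lowest non-zero dose (the "<= 50%" rule).
    minimal_response_max_tumor_animals / _max_fraction: a target arm whose
        best group has no more tumor-bearing animals than the former, or no
        higher response fraction than the latter, is too weak to model.
    control_response_max: control (dose 0) response above this flags the
        experiment.
    """

    response_threshold: float = 0.50
    physiological_routes: frozenset[ExposureRoute] = frozenset({
        ExposureRoute.ORAL, ExposureRoute.DERMAL, ExposureRoute.INHALATION,
    })
    minimal_response_max_tumor_animals: int = 1
    minimal_response_max_fraction: float = 0.05
    control_response_max: float = 0.05
    honor_adjudications: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.response_threshold < 1:
            raise ValueError("response_threshold must be in (0, 1)")


def _nonzero_groups(groups: Sequence[DoseGroup]) -> list[DoseGroup]:
    return sorted((g for g in groups if g.dose > 0), key=lambda g: g.dose)


def apply_a_priori(record: ExperimentRecord,
                   config: ScreeningConfig | None = None) -> ScreeningDisposition:
    """Stage 1: endpoint, route and concurrent-comparator checks."""
    config = config or ScreeningConfig()
    codes: list[ReasonCode] = []
    if record.endpoint_type is not EndpointType.INCIDENCE:
        codes.append(ReasonCode.NOT_INCIDENCE)
    if record.exposure_route not in config.physiological_routes:
        codes.append(ReasonCode.NON_PHYSIOLOGICAL_ROUTE)
    if not record.comparator_groups:
        codes.append(ReasonCode.NO_CONCURRENT_COMPARATOR)
    return ScreeningDisposition(a_priori_pass=not codes, reason_codes=codes,
                                stage="a_priori")


def _threshold_codes(record: ExperimentRecord,
                     config: ScreeningConfig) -> list[ReasonCode]:
    """The <=50%-at-single/lowest-dose rule, applied per arm.

    Mixed designs (multi-dose target, single-dose BaP) apply the single-dose
    rule to the single-dose arm and the lowest-dose rule to the other.
    Groups with unreported incidence are skipped (an annotation covers them).
    """
    codes = []
    code_map = {
        ("target", True): ReasonCode.SINGLE_DOSE_GT50_TARGET,
        ("comparator", True): ReasonCode.SINGLE_DOSE_GT50_COMPARATOR,
        ("target", False): ReasonCode.LOWEST_DOSE_GT50_TARGET,
        ("comparator", False): ReasonCode.LOWEST_DOSE_GT50_COMPARATOR,
    }
    for arm in ("target", "comparator"):
        groups = _nonzero_groups(record.arm(arm))
        if not groups:
            raise ValueError(f"{record.key}: {arm} arm has no non-zero dose groups")
        single = len(groups) == 1
        response = groups[0].response
        if response is not None and response > config.response_threshold:
            codes.append(code_map[(arm, single)])
    return codes


def _non_positive(record: ExperimentRecord) -> bool:
    """True if either arm shows zero tumor-bearing animals at every dose."""
    for arm in ("target", "comparator"):
        groups = _nonzero_groups(record.arm(arm))
        responses = [g.incidence for g in groups if g.incidence is not None]
        if responses and all(y == 0 for y in responses):
            return True
    return False


def apply_dose_response_criteria(
    record: ExperimentRecord, config: ScreeningConfig | None = None
) -> ScreeningDisposition:
    """Stages 1+2: a priori then dose-response criteria with adjudication."""
    config = config or ScreeningConfig()
    stage1 = apply_a_priori(record, config)
    if not stage1.a_priori_pass:
        return stage1

    codes = _threshold_codes(record, config)
    if _non_positive(record):
        codes.append(ReasonCode.NON_POSITIVE)
    for annotation in record.annotations:
        if annotation in ANNOTATION_FAIL_CODES and annotation not in codes:
            codes.append(annotation)

    passes = not codes
    if config.honor_adjudications and record.adjudication is not None:
        passes = record.adjudication is Adjudication.FORCE_PASS
        codes = codes + [ReasonCode.ADJUDICATED]
    return ScreeningDisposition(
        a_priori_pass=True, dose_response_pass=passes, reason_codes=codes,
        stage="dose_response")


def assess_modelability(
    record: ExperimentRecord, config: ScreeningConfig | None = None
) -> ScreeningDisposition:
    """All three stages; modelable iff stage 2 passed and no flag is raised."""
    config = config or ScreeningConfig()
    stage2 = apply_dose_response_criteria(record, config)
    if not stage2.dose_response_pass:
        return stage2

    flags: list[ReasonCode] = []
    groups = _nonzero_groups(record.target_groups)
    counts = [g.incidence for g in groups if g.incidence is not None]
    responses = [g.response for g in groups if g.response is not None]
    if counts and responses:
        if (max(counts) <= config.minimal_response_max_tumor_animals
                or max(responses) <= config.minimal_response_max_fraction):
            flags.append(ReasonCode.MINIMAL_RESPONSE)
    if responses and max(responses) > responses[-1]:
        # peak response strictly above the top-dose response
        flags.append(ReasonCode.NON_MONOTONIC)
    controls = [g for arm in ("target", "comparator") for g in record.arm(arm)
                if g.dose == 0 and g.response is not None]
    if any(g.response > config.control_response_max for g in controls):
        flags.append(ReasonCode.HIGH_CONTROL_RESPONSE)

    return ScreeningDisposition(
        a_priori_pass=True,
        dose_response_pass=True,
        modelable=not flags,
        reason_codes=stage2.reason_codes + flags,
        stage="modelability",
    )


# the full screen is the stage-3 assessment run from scratch
screen_record = assess_modelability


def screen_collection(
    records: Iterable[ExperimentRecord], config: ScreeningConfig | None = None
) -> list[tuple[ExperimentRecord, ScreeningDisposition]]:
    config = config or ScreeningConfig()
    return [(record, screen_record(record, config)) for record in records]


def summarize_screening(
    results: Sequence[tuple[ExperimentRecord, ScreeningDisposition]]
) -> dict:
    """Tabulate screen outcomes by stage, reason code and dose design."""
    reason_counts: Counter[str] = Counter()
    design_counts: Counter[str] = Counter()
    publications = set()
    totals = {"n_experiments": 0, "a_priori_pass": 0,
              "dose_response_pass": 0, "modelable": 0}
    for record, disposition in results:
        totals["n_experiments"] += 1
        publications.add(record.publication_id)
        totals["a_priori_pass"] += disposition.a_priori_pass
        totals["dose_response_pass"] += disposition.dose_response_pass
        totals["modelable"] += disposition.modelable
        for code in disposition.reason_codes:
            reason_counts[code.value] += 1
        n_target = sum(g.dose > 0 for g in record.target_groups)
        n_comparator = sum(g.dose > 0 for g in record.comparator_groups)
        if n_target <= 1 and n_comparator <= 1:
            design = "single_dose_both"
        elif n_target > 1 and n_comparator > 1:
            design = "multi_dose_both"
        else:
            design = "mixed_design"
        design_counts[design] += 1
    return {
        **totals,
        "n_publications": len(publications),
        "by_reason_code": dict(sorted(reason_counts.items())),
        "by_dose_design": dict(sorted(design_counts.items())),
    }
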