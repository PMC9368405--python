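"""Potency equivalence factors from paired BMD10 values, plus orchestration.

With potency expressed as the slope BMR / BMD10, the ratio of target to
comparator potency reduces to

    PEF = (0.1 / BMD10_target) / (0.1 / BMD10_BaP)
        = BMD10_BaP / BMD10_target,

a dimensionless, scale-invariant ratio. Both BMDs must come from the same
publication (concurrent testing); the comparator BMD is reused across
multiple target PAHs tested in the same publication.

Display rounding is half-up to two decimals (PEFs below 0.01 fall back to
two significant figures); chemical aggregates report both the arithmetic
mean of the displayed values and the mean of the unrounded ratios.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

from pefkit.bma import DropPolicy, drop_high_dose, model_average
from pefkit.bmd_models import BenchmarkSpec, FitConfig, fit_all
from pefkit.screening import ScreeningConfig, screen_collection, summarize_screening
from pefkit.types import DoseResponseDataset, ExperimentRecord

log = logging.getLogger(__name__)


def round_display(value: float, decimals: int = 2) -> float:
    """Half-up decimal rounding for display (0.125 -> 0.13, not 0.12)."""
    if value <= 0 or not math.isfinite(value):
        raise ValueError(f"cannot display-round {value}")
    if value < 10 ** -decimals:
        # below the decimal grid: two significant figures
        exponent = math.floor(math.log10(value))
        decimals = -exponent + 1
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def round_headline(value: float) -> float:
    """One-significant-figure headline value (0.24 -> 0.2)."""
    if value <= 0 or not math.isfinite(value):
        raise ValueError(f"cannot headline-round {value}")
    exponent = math.floor(math.log10(value))
    quantum = Decimal(1).scaleb(exponent)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class PEFResult:
    """One target-PAH/BaP potency ratio with its provenance."""

    target_pah: str
    publication_id: str
    bmd10_bap: float
    bmd10_target: float
    pef: float
    pef_rounded: float
    pef_headline: float
    study_type: str = ""
    adjudicated: bool = False


def compute_pef(
    bmd10_bap: float,
    bmd10_target: float,
    target_pah: str = "",
    publication_id: str = "",
    study_type: str = "",
    adjudicated: bool = False,
) -> PEFResult:
    """PEF = BMD10(BaP) / BMD10(target), with display roundings.

    Both BMDs must be positive, finite, and on the same mass-basis dose
    scale; the ratio itself is unit-free.
    """
    for label, value in (("bmd10_bap", bmd10_bap), ("bmd10_target", bmd10_target)):
        if not (isinstance(value, (int, float)) and math.isfinite(value) and value > 0):
            raise ValueError(f"{label} must be a positive finite dose, got {value!r}")
    pef = bmd10_bap / bmd10_target
    return PEFResult(
        target_pah=target_pah,
        publication_id=publication_id,
        bmd10_bap=float(bmd10_bap),
        bmd10_target=float(bmd10_target),
        pef=pef,
        pef_rounded=round_display(pef),
        pef_headline=round_headline(pef),
        study_type=study_type,
        adjudicated=adjudicated,
    )


@dataclass(frozen=True)
class ChemicalPEFSummary:
    """Per-chemical aggregate over the datasets that yielded a PEF."""

    target_pah: str
    pefs: tuple[float, ...]               # displayed-precision per-dataset PEFs
    mean_pef: float                       # mean of displayed values, re-displayed
    mean_pef_unrounded: float             # mean of exact ratios
    n_datasets: int
    single_dataset: bool
    any_adjudicated: bool


def aggregate_pefs(results: Sequence[PEFResult]) -> ChemicalPEFSummary:
    """Arithmetic-mean aggregate of one chemical's per-dataset PEFs.

    The headline mean averages the displayed (2-decimal) per-dataset
    values; the mean of the unrounded ratios is reported alongside since
    the two can differ in the final displayed digit.
    """
    results = list(results)
    if not results:
        raise ValueError("aggregate_pefs requires at least one PEFResult")
    chemicals = {r.target_pah for r in results}
    if len(chemicals) > 1:
        raise ValueError(f"results span multiple chemicals: {sorted(chemicals)}")
    rounded = tuple(r.pef_rounded for r in results)
    return ChemicalPEFSummary(
        target_pah=results[0].target_pah,
        pefs=rounded,
        mean_pef=round_display(sum(rounded) / len(rounded)),
        mean_pef_unrounded=sum(r.pef for r in results) / len(results),
        n_datasets=len(results),
        single_dataset=len(results) == 1,
        any_adjudicated=any(r.adjudicated for r in results),
    )


@dataclass
class PipelineReport:
    """Every stage's artifacts from one end-to-end run."""

    screening: list = field(default_factory=list)          # (record, disposition)
    screening_summary: dict = field(default_factory=dict)
    bma_results: dict = field(default_factory=dict)        # key -> {arm: BMAResult}
    pef_results: list[PEFResult] = field(default_factory=list)
    summaries: dict[str, ChemicalPEFSummary] = field(default_factory=dict)
    skipped: list[str] = field(default_factory=list)


def _arm_dataset(record: ExperimentRecord, arm: str) -> DoseResponseDataset:
    from pefkit.types import Compound

    groups = sorted(record.arm(arm), key=lambda g: g.dose)
    name = record.target_pah if arm == "target" else record.comparator
    return DoseResponseDataset(
        compound=Compound(name=name, short_form=name),
        doses=[g.dose for g in groups],
        n=[g.n for g in groups],
        incidence=[g.incidence for g in groups],
        publication_id=record.publication_id,
        arm=arm,
    )


def run_pipeline(
    experiments: Sequence[ExperimentRecord],
    incidence_tables: Mapping[str, Mapping[str, DoseResponseDataset]] | None = None,
    screening_config: ScreeningConfig | None = None,
    fit_config: FitConfig | None = None,
    benchmark: BenchmarkSpec | None = None,
    drop_policy: DropPolicy | str = "none",
    use_record_arms: bool = False,
    seed: int = 0,
) -> PipelineReport:
    """Screen -> fit + average both arms of each modelable dataset -> PEFs.

    ``incidence_tables`` maps an experiment key to per-arm
    ("target"/"comparator") dose-response tables supplied by the user, for
    records whose fixture transcription carries only screening-level
    summaries. When ``use_record_arms`` is true (synthetic collections with
    fully quantitative arms) the record's own dose groups are modeled
    directly. Modelable records with neither source of incidence data are
    skipped with an explicit log entry — never fabricated.
    """
    report = PipelineReport()
    report.screening = screen_collection(experiments, screening_config)
    report.screening_summary = summarize_screening(report.screening)
    benchmark = benchmark or BenchmarkSpec()

    # a publication's BaP arm is modeled once and reused across the
    # target PAHs tested concurrently in that publication
    comparator_cache: dict[tuple, object] = {}
    per_chemical: dict[str, list[PEFResult]] = {}
    for record, disposition in report.screening:
        if not disposition.modelable:
            continue
        tables = (incidence_tables or {}).get(record.key)
        if tables is None and use_record_arms:
            if all(g.incidence is not None for arm in ("target", "comparator")
                   for g in record.arm(arm)):
                tables = {arm: _arm_dataset(record, arm)
                          for arm in ("target", "comparator")}
        if tables is None:
            message = (f"{record.key}: modelable but no incidence table "
                       "supplied; skipped")
            log.info(message)
            report.skipped.append(message)
            continue

        arm_bmds: dict[str, float] = {}
        arm_results = {}
        for arm in ("target", "comparator"):
            table = tables[arm]
            cache_key = (record.publication_id, tuple(table.doses),
                         tuple(table.n), tuple(table.incidence))
            if arm == "comparator" and cache_key in comparator_cache:
                result = comparator_cache[cache_key]
            else:
                dataset, removed = drop_high_dose(table, drop_policy, fit_config)
                fits = fit_all(dataset, fit_config, benchmark)
                result = model_average(fits, benchmark=benchmark, seed=seed)
                result.dropped_doses = removed
                if arm == "comparator":
                    comparator_cache[cache_key] = result
            arm_results[arm] = result
            arm_bmds[arm] = result.bmd10_point
        report.bma_results[record.key] = arm_results

        pef = compute_pef(
            bmd10_bap=arm_bmds["comparator"],
            bmd10_target=arm_bmds["target"],
            target_pah=record.target_pah,
            publication_id=record.publication_id,
            study_type=record.study_type.value,
            adjudicated=record.adjudication is not None,
        )
        report.pef_results.append(pef)
        per_chemical.setdefault(record.target_pah, []).append(pef)

    report.summaries = {
        chem: aggregate_pefs(results) for chem, results in per_chemical.items()
    }
    return report
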