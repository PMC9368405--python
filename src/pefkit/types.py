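"""Domain types for PAH bioassay screening and potency modeling.

All downstream modeling works on mass-basis doses; molar doses recorded in
source publications are converted at load time (see :mod:`pefkit.units`).
"""

from __future__ import annotations

import enum
from typing import Optional

from pydantic import BaseModel, Field, model_validator


class DoseUnit(str, enum.Enum):
    """Dose units encountered in the historical bioassay literature.

    Skin-painting studies report amount per application (nmol, ug, mg);
    oral studies report amount per body mass (mg/kg, mmol/kg).
    """

    NMOL = "nmol"
    UG = "ug"
    MG = "mg"
    MG_PER_KG = "mg/kg"
    MMOL_PER_KG = "mmol/kg"

    @property
    def is_molar(self) -> bool:
        return self in (DoseUnit.NMOL, DoseUnit.MMOL_PER_KG)

    @property
    def is_per_body_mass(self) -> bool:
        return self in (DoseUnit.MG_PER_KG, DoseUnit.MMOL_PER_KG)


class IARCClass(str, enum.Enum):
    GROUP_1 = "1"
    GROUP_2A = "2A"
    GROUP_2B = "2B"
    GROUP_3 = "3"
    UNCLASSIFIED = "unclassified"


class StudyType(str, enum.Enum):
    COMPLETE = "complete"
    INITIATION_PROMOTION = "initiation_promotion"


class ExposureRoute(str, enum.Enum):
    DERMAL = "dermal"
    ORAL = "oral"
    INHALATION = "inhalation"
    INTRAPERITONEAL = "intraperitoneal"
    SUBCUTANEOUS = "subcutaneous"
    IMPLANTATION = "implantation"
    OTHER = "other"


class EndpointType(str, enum.Enum):
    INCIDENCE = "incidence"
    MULTIPLICITY = "multiplicity"
    UNSPECIFIED = "unspecified"


class Adjudication(str, enum.Enum):
    FORCE_PASS = "force_pass"
    FORCE_FAIL = "force_fail"


class ReasonCode(str, enum.Enum):
    """Auditable codes attached to a screening disposition."""

    NOT_INCIDENCE = "NOT_INCIDENCE"
    NON_PHYSIOLOGICAL_ROUTE = "NON_PHYSIOLOGICAL_ROUTE"
    NO_CONCURRENT_COMPARATOR = "NO_CONCURRENT_COMPARATOR"
    SINGLE_DOSE_GT50_TARGET = "SINGLE_DOSE_GT50_TARGET"
    SINGLE_DOSE_GT50_COMPARATOR = "SINGLE_DOSE_GT50_COMPARATOR"
    LOWEST_DOSE_GT50_TARGET = "LOWEST_DOSE_GT50_TARGET"
    LOWEST_DOSE_GT50_COMPARATOR = "LOWEST_DOSE_GT50_COMPARATOR"
    NON_POSITIVE = "NON_POSITIVE"
    EXCESS_MORTALITY = "EXCESS_MORTALITY"
    MINIMAL_RESPONSE = "MINIMAL_RESPONSE"
    NON_MONOTONIC = "NON_MONOTONIC"
    HIGH_CONTROL_RESPONSE = "HIGH_CONTROL_RESPONSE"
    ADJUDICATED = "ADJUDICATED"


class Compound(BaseModel):
    """A PAH (or the comparator BaP) with registry metadata.

    ``molecular_weight`` may be supplied directly or derived from
    ``formula`` via :func:`pefkit.units.formula_mass`.
    """

    name: str
    short_form: str
    cas_number: str = ""
    formula: Optional[str] = None
    molecular_weight: Optional[float] = Field(default=None, gt=0)
    iarc_class: IARCClass = IARCClass.UNCLASSIFIED
    published_pefs: list[tuple[str, float]] = Field(default_factory=list)

    @model_validator(mode="after")
    def _derive_weight(self) -> "Compound":
        if self.molecular_weight is None and self.formula:
            from pefkit.units import formula_mass

            object.__setattr__(self, "molecular_weight", formula_mass(self.formula))
        return self


class DoseGroup(BaseModel):
    """One dose group of one arm: dose, group size, tumor-bearing count.

    ``incidence`` is None when the source publication did not report animal
    counts with tumors (the record then carries a NOT_INCIDENCE annotation).
    """

    dose: float = Field(ge=0)
    dose_unit: DoseUnit = DoseUnit.MG
    n: int = Field(gt=0)
    incidence: Optional[int] = Field(default=None, ge=0)

    @model_validator(mode="after")
    def _check_incidence(self) -> "DoseGroup":
        if self.incidence is not None and self.incidence > self.n:
            raise ValueError(
                f"incidence {self.incidence} exceeds group size {self.n}"
            )
        return self

    @property
    def response(self) -> Optional[float]:
        """Fraction of tumor-bearing animals, in [0, 1]; None if unreported."""
        if self.incidence is None:
            return None
        return self.incidence / self.n


class ExperimentRecord(BaseModel):
    """One bioassay experiment: a target-PAH arm tested concurrently with BaP.

    Annotations are structured quality flags transcribed from the source
    (excess mortality, author-declared non-positive results, missing
    incidence counts); they drive screening codes that cannot be computed
    from the printed numbers alone.
    """

    publication_id: str
    target_pah: str
    comparator: str = "BaP"
    study_type: StudyType = StudyType.COMPLETE
    exposure_route: ExposureRoute = ExposureRoute.DERMAL
    endpoint_type: EndpointType = EndpointType.INCIDENCE
    target_groups: list[DoseGroup] = Field(default_factory=list)
    comparator_groups: list[DoseGroup] = Field(default_factory=list)
    quality_notes: str = ""
    annotations: list[ReasonCode] = Field(default_factory=list)
    adjudication: Optional[Adjudication] = None
    adjudication_reason: str = ""
    experiment_key: str = ""

    @property
    def key(self) -> str:
        return self.experiment_key or f"{self.publication_id}|{self.target_pah}"

    def arm(self, which: str) -> list[DoseGroup]:
        if which == "target":
            return self.target_groups
        if which == "comparator":
            return self.comparator_groups
        raise KeyError(which)


class ScreeningDisposition(BaseModel):
    """Outcome of the staged screen with auditable reason codes.

    Invariants: ``dose_response_pass`` implies ``a_priori_pass``;
    ``modelable`` implies ``dose_response_pass``; a failing disposition
    carries at least one reason code.
    """

    a_priori_pass: bool
    dose_response_pass: bool = False
    modelable: bool = False
    reason_codes: list[ReasonCode] = Field(default_factory=list)
    #: deepest stage actually evaluated (partial dispositions stop early)
    stage: str = "modelability"

    @model_validator(mode="after")
    def _check_stages(self) -> "ScreeningDisposition":
        if self.stage not in ("a_priori", "dose_response", "modelability"):
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.dose_response_pass and not self.a_priori_pass:
            raise ValueError("dose_response_pass requires a_priori_pass")
        if self.modelable and not self.dose_response_pass:
            raise ValueError("modelable requires dose_response_pass")
        failed_at_stage = (
            not self.a_priori_pass
            or (self.stage != "a_priori" and not self.dose_response_pass)
            or (self.stage == "modelability" and not self.modelable)
        )
        if failed_at_stage and not self.reason_codes:
            raise ValueError("failing disposition must carry a reason code")
        return self


class DoseResponseDataset(BaseModel):
    """Numeric dose/n/incidence table ready for quantal modeling.

    Doses are mass-basis (mg per application, or mg/kg for oral designs),
    strictly increasing; the first dose may be 0 (control).
    """

    compound: Compound
    doses: list[float]
    n: list[int]
    incidence: list[int]
    publication_id: str = ""
    arm: str = ""

    @model_validator(mode="after")
    def _check(self) -> "DoseResponseDataset":
        if not (len(self.doses) == len(self.n) == len(self.incidence)):
            raise ValueError("doses, n and incidence must have equal length")
        if any(b <= a for a, b in zip(self.doses, self.doses[1:])):
            raise ValueError("doses must be strictly increasing")
        if self.doses and self.doses[0] < 0:
            raise ValueError("doses must be non-negative")
        for i, (ni, yi) in enumerate(zip(self.n, self.incidence)):
            if ni <= 0:
                raise ValueError(f"group {i}: n must be positive")
            if not 0 <= yi <= ni:
                raise ValueError(f"group {i}: incidence {yi} outside [0, {ni}]")
        return self

    @property
    def responses(self) -> list[float]:
        return [y / m for y, m in zip(self.incidence, self.n)]
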