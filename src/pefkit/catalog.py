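"""Packaged transcription of the printed evidence tables.

The catalog carries the 48 screened experiments (with their printed
dispositions and reason codes), the per-publication study counts of the
selection table, and the four modeled BMD/PEF rows used for regression
tests. Per-dose-group incidence tables for the four modeled datasets are
not part of the printed evidence and are deliberately not fabricated here:
full modeling runs require user-supplied incidence tables.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources

from pefkit.types import Compound, ExperimentRecord, ReasonCode, ScreeningDisposition


class FixtureIntegrityError(RuntimeError):
    """Packaged resource does not match its recorded checksum."""


@dataclass(frozen=True)
class Table7Row:
    """One printed BMD/PEF row of the modeling-summary table."""

    target_pah: str
    publication_id: str
    bmd10_bap: float
    bmd10_target: float
    pef_printed: float
    study_type: str
    note: str = ""


@dataclass
class FixtureBundle:
    records: list[ExperimentRecord]
    expected_dispositions: dict[str, ScreeningDisposition]
    table4_counts: dict[str, int]
    table7: list[Table7Row]
    table7_cpp_mean: float
    compounds: dict[str, Compound]
    entries: dict[str, dict]
    publications: dict[str, str]
    description: str


def _read_resource(name: str, checksums: dict[str, str] | None = None) -> bytes:
    data = resources.files("pefkit.fixtures").joinpath(name).read_bytes()
    if checksums is not None:
        digest = hashlib.sha256(data).hexdigest()
        if digest != checksums[name]:
            raise FixtureIntegrityError(
                f"{name}: sha256 {digest} != recorded {checksums[name]}")
    return data


def load_fixture(verify: bool = True) -> FixtureBundle:
    """Load the packaged catalog, verifying resource checksums."""
    checksums = None
    if verify:
        checksums = json.loads(_read_resource("checksums.json"))
    catalog = json.loads(_read_resource("bioassay_catalog.json", checksums))
    compound_list = json.loads(_read_resource("compounds.json", checksums))

    records = [ExperimentRecord.model_validate(r) for r in catalog["records"]]
    expected = {
        key: ScreeningDisposition(
            a_priori_pass=e["a_priori_pass"],
            dose_response_pass=e["dose_response_pass"],
            modelable=e["modelable"],
            reason_codes=[ReasonCode(c) for c in e["reason_codes"]],
        )
        for key, e in catalog["expected_dispositions"].items()
    }
    compounds = {c["short_form"]: Compound.model_validate(c)
                 for c in compound_list}
    table7 = [Table7Row(**row) for row in catalog["table7"]]
    return FixtureBundle(
        records=records,
        expected_dispositions=expected,
        table4_counts=catalog["table4_counts"],
        table7=table7,
        table7_cpp_mean=catalog["table7_cpp_mean"],
        compounds=compounds,
        entries=catalog["entries"],
        publications=catalog["publications"],
        description=catalog["description"],
    )
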