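"""Readers and writers for experiment collections, registries and reports.

CSV interchange is UTF-8, comma-separated, "." decimal, one row per dose
group; rows sharing an ``experiment_key`` form one experiment record. JSON
interchange nests dose groups inside records. Reports are emitted as a
machine-readable JSON summary plus human-readable TSV tables (dispositions
with reason codes; BMDs and PEFs).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml
from pydantic import ValidationError

from pefkit.types import (
    Compound,
    DoseGroup,
    ExperimentRecord,
    ReasonCode,
    ScreeningDisposition,
)

CSV_COLUMNS = [
    "experiment_key",
    "publication_id",
    "target_pah",
    "comparator",
    "study_type",
    "exposure_route",
    "endpoint_type",
    "arm",
    "dose",
    "dose_unit",
    "n",
    "incidence",
    "quality_notes",
    "annotations",
    "adjudication",
    "adjudication_reason",
]

_RECORD_FIELDS = [
    "publication_id",
    "target_pah",
    "comparator",
    "study_type",
    "exposure_route",
    "endpoint_type",
    "quality_notes",
    "adjudication",
    "adjudication_reason",
    "experiment_key",
]


class SchemaError(ValueError):
    """Input file does not conform to the documented schema."""


def _blank(value) -> bool:
    return value is None or (isinstance(value, float) and pd.isna(value)) or value == ""


def load_experiments(path: str | Path, format: str | None = None) -> list[ExperimentRecord]:
    """Load a collection of experiment records from CSV or JSON.

    The format is inferred from the suffix when not given. Malformed rows
    are reported with their (1-based, header-exclusive) row numbers.
    """
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    if fmt == "json":
        payload = json.loads(path.read_text())
        records = []
        for i, item in enumerate(payload):
            try:
                records.append(ExperimentRecord.model_validate(item))
            except ValidationError as exc:
                raise SchemaError(f"record {i}: {exc}") from exc
        return records
    if fmt != "csv":
        raise ValueError(f"unsupported format: {fmt}")

    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CSV_COLUMNS[:12] if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing required columns: {', '.join(missing)}")
    if frame.empty:
        return []

    grouped: dict[str, dict] = {}
    order: list[str] = []
    for row_number, row in enumerate(frame.to_dict("records"), start=1):
        key = row.get("experiment_key") or f"{row['publication_id']}|{row['target_pah']}"
        if key not in grouped:
            grouped[key] = {
                "experiment_key": key,
                "publication_id": row["publication_id"],
                "target_pah": row["target_pah"],
                "comparator": row.get("comparator") or "BaP",
                "study_type": row.get("study_type") or "complete",
                "exposure_route": row.get("exposure_route") or "dermal",
                "endpoint_type": row.get("endpoint_type") or "incidence",
                "quality_notes": row.get("quality_notes") or "",
                "annotations": [
                    ReasonCode(code)
                    for code in (row.get("annotations") or "").split(";")
                    if code
                ],
                "adjudication": row.get("adjudication") or None,
                "adjudication_reason": row.get("adjudication_reason") or "",
                "target_groups": [],
                "comparator_groups": [],
            }
            order.append(key)
        arm = row.get("arm")
        if arm not in ("target", "comparator"):
            raise SchemaError(f"row {row_number}: arm must be 'target' or 'comparator'")
        try:
            group = DoseGroup(
                dose=float(row["dose"]),
                dose_unit=row.get("dose_unit") or "mg",
                n=int(row["n"]),
                incidence=None if _blank(row.get("incidence")) else int(row["incidence"]),
            )
        except (ValueError, ValidationError) as exc:
            raise SchemaError(f"row {row_number}: {exc}") from exc
        grouped[key][f"{arm}_groups"].append(group)

    records = []
    for key in order:
        try:
            records.append(ExperimentRecord.model_validate(grouped[key]))
        except ValidationError as exc:
            raise SchemaError(f"experiment {key}: {exc}") from exc
    return records


def write_experiments(records: Iterable[ExperimentRecord], path: str | Path,
                      format: str | None = None) -> Path:
    """Write records to CSV (one row per dose group) or JSON (nested)."""
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    records = list(records)
    if fmt == "json":
        path.write_text(json.dumps(
            [r.model_dump(mode="json") for r in records], indent=1))
        return path
    rows = []
    for record in records:
        base = {f: getattr(record, f) for f in _RECORD_FIELDS}
        base["experiment_key"] = record.key
        base["annotations"] = ";".join(code.value for code in record.annotations)
        for field in ("study_type", "exposure_route", "endpoint_type", "adjudication"):
            value = base[field]
            base[field] = getattr(value, "value", value) or ""
        for arm in ("target", "comparator"):
            for group in record.arm(arm):
                rows.append({
                    **base,
                    "arm": arm,
                    "dose": group.dose,
                    "dose_unit": group.dose_unit.value,
                    "n": group.n,
                    "incidence": "" if group.incidence is None else group.incidence,
                })
    pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False)
    return path


def load_compounds(path: str | Path) -> dict[str, Compound]:
    """Load a compound registry (YAML or JSON list) keyed by short form."""
    path = Path(path)
    text = path.read_text()
    payload = (json.loads(text) if path.suffix.lower() == ".json"
               else yaml.safe_load(text))
    registry: dict[str, Compound] = {}
    for item in payload:
        compound = Compound.model_validate(item)
        if compound.short_form in registry:
            raise SchemaError(f"duplicate short form: {compound.short_form}")
        registry[compound.short_form] = compound
    return registry


def write_report(
    dispositions: Sequence[tuple[ExperimentRecord, ScreeningDisposition]],
    pef_results,
    path: str | Path,
    summary: Mapping | None = None,
) -> dict[str, Path]:
    """Emit a JSON summary plus TSV tables mirroring the evidence-table layout.

    ``pef_results`` is a sequence of :class:`pefkit.pef.PEFResult`; pass an
    empty list for screening-only runs.
    """
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)

    disposition_rows = [{
        "experiment_key": record.key,
        "publication_id": record.publication_id,
        "target_pah": record.target_pah,
        "study_type": record.study_type.value,
        "dose_design": f"{sum(g.dose > 0 for g in record.target_groups)}"
                       f"/{sum(g.dose > 0 for g in record.comparator_groups)}",
        "a_priori_pass": disposition.a_priori_pass,
        "dose_response_pass": disposition.dose_response_pass,
        "modelable": disposition.modelable,
        "reason_codes": ";".join(c.value for c in disposition.reason_codes),
    } for record, disposition in dispositions]

    pef_rows = [{
        "target_pah": result.target_pah,
        "publication_id": result.publication_id,
        "bmd10_bap": result.bmd10_bap,
        "bmd10_target": result.bmd10_target,
        "pef": result.pef,
        "pef_rounded": result.pef_rounded,
        "study_type": result.study_type,
    } for result in pef_results]

    paths = {
        "dispositions_tsv": out / "dispositions.tsv",
        "pefs_tsv": out / "pefs.tsv",
        "summary_json": out / "summary.json",
    }
    pd.DataFrame(disposition_rows, columns=[
        "experiment_key", "publication_id", "target_pah", "study_type",
        "dose_design", "a_priori_pass", "dose_response_pass", "modelable",
        "reason_codes",
    ]).to_csv(paths["dispositions_tsv"], sep="\t", index=False)
    pd.DataFrame(pef_rows, columns=[
        "target_pah", "publication_id", "bmd10_bap", "bmd10_target",
        "pef", "pef_rounded", "study_type",
    ]).to_csv(paths["pefs_tsv"], sep="\t", index=False)

    payload = {
        "n_experiments": len(disposition_rows),
        "n_a_priori_pass": sum(r["a_priori_pass"] for r in disposition_rows),
        "n_dose_response_pass": sum(r["dose_response_pass"] for r in disposition_rows),
        "n_modelable": sum(r["modelable"] for r in disposition_rows),
        "pefs": pef_rows,
    }
    if summary:
        payload["screening_summary"] = dict(summary)
    paths["summary_json"].write_text(json.dumps(payload, indent=1, default=str))
    return paths
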