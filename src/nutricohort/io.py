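"""Reading and writing the tabular interfaces.

Input schemas (CSV, long format):

``clients.csv``
    client_id, age_years, sex, dx_bipolar, dx_adhd, treatment_start_day
``symptom_reports.csv``
    client_id, day, scale, item_1 ... item_16 (columns beyond a scale's
    length left empty)
``medications.csv``
    client_id, day, medication, dose

Duplicate same-day reports for one client/scale are merged at ingestion by
item-wise averaging with half-up rounding, so downstream code can assume one
report per client/scale/day.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model import (
    COHORT_SUMMARY_FIELDS,
    ITEM_COLUMNS,
    SCALES,
    SCALE_N_ITEMS,
    SEVERITY_N_ITEMS,
    ClientProfile,
    CohortSummary,
    MedicationRecord,
    SymptomReport,
    ValidationError,
)

__all__ = [
    "read_cohort",
    "write_cohort",
    "write_summary",
    "reports_to_frame",
    "frame_to_reports",
    "clients_to_frame",
    "medications_to_frame",
    "write_tables_json",
    "round_half_up",
    "round_half_away",
]

_TRUE = {"true", "1", "yes", "t"}
_FALSE = {"false", "0", "no", "f"}


def round_half_up(x):
    """Round halves upward (1.5 -> 2, 2.5 -> 3); used for merged item scores."""
    return np.floor(np.asarray(x, dtype=float) + 0.5).astype(int)


def round_half_away(x):
    """Round halves away from zero (-46.5 -> -47); used for report percents."""
    a = np.asarray(x, dtype=float)
    return (np.sign(a) * np.floor(np.abs(a) + 0.5)).astype(int)


def _parse_bool(value, path, line, column) -> bool:
    s = str(value).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise ValidationError(f"{path}:{line}:{column}: cannot parse boolean {value!r}")


def _read_csv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, dtype=str, keep_default_na=False)
    except Exception as exc:  # noqa: BLE001 - rewrap with file context
        raise ValidationError(f"{path}: cannot read CSV ({exc})") from exc


def _require_columns(df: pd.DataFrame, needed: Sequence[str], path) -> None:
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")


def _parse_int(value, path, line, column) -> int:
    try:
        return int(str(value).strip())
    except ValueError as exc:
        raise ValidationError(
            f"{path}:{line}:{column}: cannot parse integer {value!r}"
        ) from exc


def read_clients(path) -> list[ClientProfile]:
    df = _read_csv(path)
    _require_columns(
        df,
        ["client_id", "age_years", "sex", "dx_bipolar", "dx_adhd"],
        path,
    )
    clients = []
    seen = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        cid = str(row.client_id).strip()
        if cid in seen:
            raise ValidationError(f"{path}:{i}:client_id: duplicate id {cid!r}")
        seen.add(cid)
        start = getattr(row, "treatment_start_day", 0) or 0
        try:
            clients.append(
                ClientProfile(
                    client_id=cid,
                    age_years=_parse_int(row.age_years, path, i, "age_years"),
                    sex=str(row.sex).strip().lower(),
                    dx_bipolar=_parse_bool(row.dx_bipolar, path, i, "dx_bipolar"),
                    dx_adhd=_parse_bool(row.dx_adhd, path, i, "dx_adhd"),
                    treatment_start_day=_parse_int(start, path, i, "treatment_start_day"),
                )
            )
        except ValidationError:
            raise
        except ValueError as exc:
            raise ValidationError(f"{path}:{i}: {exc}") from exc
    return clients


def read_symptom_reports(path) -> list[SymptomReport]:
    df = _read_csv(path)
    _require_columns(df, ["client_id", "day", "scale"], path)
    item_cols = [c for c in ITEM_COLUMNS if c in df.columns]

    parsed: dict[tuple, list[np.ndarray]] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        cid = str(row.client_id).strip()
        day = _parse_int(row.day, path, i, "day")
        scale = str(row.scale).strip().lower()
        if scale not in SCALES:
            raise ValidationError(f"{path}:{i}:scale: unknown scale label {row.scale!r}")
        n = SCALE_N_ITEMS[scale]
        scores = []
        for k in range(n):
            col = f"item_{k + 1}"
            if col not in df.columns:
                raise ValidationError(f"{path}: missing column {col}")
            raw = str(getattr(row, col)).strip()
            if raw == "":
                raise ValidationError(f"{path}:{i}:{col}: empty score for {scale} report")
            v = _parse_int(raw, path, i, col)
            if v not in (0, 1, 2, 3):
                raise ValidationError(f"{path}:{i}:{col}: item score {v} outside 0..3")
            scores.append(v)
        # columns beyond the scale's length must be empty
        for col in item_cols[n:]:
            if str(getattr(row, col)).strip() != "":
                raise ValidationError(
                    f"{path}:{i}:{col}: unexpected score beyond {scale} scale length"
                )
        parsed.setdefault((cid, scale, day), []).append(np.array(scores, dtype=float))

    reports = []
    for (cid, scale, day), stack in parsed.items():
        merged = round_half_up(np.mean(stack, axis=0)) if len(stack) > 1 else stack[0].astype(int)
        reports.append(SymptomReport(cid, day, scale, tuple(int(v) for v in merged)))
    reports.sort(key=lambda r: (r.client_id, r.scale, r.day))
    return reports


def read_medications(path) -> list[MedicationRecord]:
    df = _read_csv(path)
    _require_columns(df, ["client_id", "day", "medication", "dose"], path)
    records = []
    seen = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        cid = str(row.client_id).strip()
        day = _parse_int(row.day, path, i, "day")
        med = str(row.medication).strip()
        try:
            dose = float(str(row.dose).strip())
        except ValueError as exc:
            raise ValidationError(f"{path}:{i}:dose: cannot parse {row.dose!r}") from exc
        if not math.isfinite(dose) or dose < 0:
            raise ValidationError(f"{path}:{i}:dose: dose must be finite and >= 0")
        key = (cid, med, day)
        if key in seen:
            raise ValidationError(
                f"{path}:{i}: duplicate medication record for {key}"
            )
        seen.add(key)
        records.append(MedicationRecord(cid, day, med, dose))
    records.sort(key=lambda r: (r.client_id, r.medication, r.day))
    return records


def read_cohort(clients_path, reports_path, medications_path):
    """Read and validate the three input files.

    Returns ``(clients, reports, medications)`` as lists of domain records;
    same-day duplicate reports are merged and severity totals recomputed.
    """
    return (
        read_clients(clients_path),
        read_symptom_reports(reports_path),
        read_medications(medications_path),
    )


# ---------------------------------------------------------------- frames

def clients_to_frame(clients: Iterable[ClientProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "client_id": c.client_id,
                "age_years": c.age_years,
                "sex": c.sex,
                "dx_bipolar": c.dx_bipolar,
                "dx_adhd": c.dx_adhd,
                "treatment_start_day": c.treatment_start_day,
            }
            for c in clients
        ]
    )


def reports_to_frame(reports: Iterable[SymptomReport]) -> pd.DataFrame:
    """Long-format frame: client_id, day, scale, item_1..item_16, severity."""
    rows = []
    for r in reports:
        row = {"client_id": r.client_id, "day": r.day, "scale": r.scale}
        for k, col in enumerate(ITEM_COLUMNS):
            row[col] = r.item_scores[k] if k < len(r.item_scores) else np.nan
        row["severity"] = r.severity
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_reports(df: pd.DataFrame) -> list[SymptomReport]:
    reports = []
    for row in df.itertuples(index=False):
        n = SCALE_N_ITEMS[row.scale]
        items = tuple(int(getattr(row, f"item_{k + 1}")) for k in range(n))
        reports.append(SymptomReport(str(row.client_id), int(row.day), row.scale, items))
    return reports


def medications_to_frame(records: Iterable[MedicationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "client_id": r.client_id,
                "day": r.day,
                "medication": r.medication,
                "dose": r.dose,
            }
            for r in records
        ]
    )


def write_cohort(outdir, clients, reports, medications) -> dict[str, Path]:
    """Write the three CSV inputs to ``outdir``; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "clients": outdir / "clients.csv",
        "symptom_reports": outdir / "symptom_reports.csv",
        "medications": outdir / "medications.csv",
    }
    clients_to_frame(clients).to_csv(paths["clients"], index=False)
    rdf = reports_to_frame(reports)
    # item columns beyond a scale's length are written empty, severity omitted
    rdf = rdf.drop(columns=["severity"])
    int_items = {c: "Int64" for c in ITEM_COLUMNS}
    rdf = rdf.astype(int_items)
    rdf.to_csv(paths["symptom_reports"], index=False)
    medications_to_frame(medications).to_csv(paths["medications"], index=False)
    return paths


# ---------------------------------------------------------------- summaries

_REPORT_PCT_FIELDS = (
    "pct_change_of_means",
    "pct_change_of_medians",
    "median_pct_change",
)
_REPORT_FRAC_FIELDS = (
    "frac_reduction_gt_30",
    "frac_reduction_gt_50",
    "frac_symptom_free",
    "frac_worsened",
)


def summaries_to_frame(summaries: Sequence[CohortSummary]) -> pd.DataFrame:
    """Tabulate summaries in the fixed field order, adding integer-rounded
    report columns next to the raw values."""
    if not summaries:
        raise ValueError("no summaries to write")
    df = pd.DataFrame([asdict(s) for s in summaries])[list(COHORT_SUMMARY_FIELDS)]
    for col in _REPORT_PCT_FIELDS:
        df[f"{col}_report"] = [
            None if pd.isna(v) else int(round_half_away(v)) for v in df[col]
        ]
    for col in _REPORT_FRAC_FIELDS:
        df[f"{col}_report_pct"] = [
            None if pd.isna(v) else int(round_half_away(100.0 * v)) for v in df[col]
        ]
    return df


def write_summary(summaries: Sequence[CohortSummary], path) -> pd.DataFrame:
    """Write one CSV row per group.

    Report columns hold percents rounded to the nearest integer (half away
    from zero); raw unrounded values are kept alongside.  An empty summary
    list is an error rather than an empty file.
    """
    df = summaries_to_frame(summaries)
    df.to_csv(path, index=False)
    return df


def write_tables_json(tables: dict, path) -> None:
    """Machine-readable mirror of all output tables (frames become records)."""

    def convert(obj):
        if isinstance(obj, pd.DataFrame):
            return json.loads(obj.to_json(orient="records"))
        if isinstance(obj, dict):
            return {k: convert(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [convert(v) for v in obj]
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, float) and math.isnan(obj):
            return None
        return obj

    Path(path).write_text(json.dumps(convert(tables), indent=2))
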