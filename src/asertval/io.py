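"""Readers and writers for the long-format CSV tables and run configuration.

CSV schemas (comma-separated, UTF-8, ISO-8601 dates, empty cells for missing
optional values):

* ``asert.csv`` — ``patient_id,date,q1..q10`` (subscores are derived, never
  stored).
* ``clinical.csv`` — ``patient_id,date,madrs_total,ymrs_total`` with optional
  item-level columns ``m1..m10`` and/or ``y1..y11``.
* ``patients.csv`` — ``patient_id,enrollment_date,exit_date``.
* ``matched.csv`` — flattened :class:`~asertval.domain.MatchedRecord` rows
  (assessment + concurrent + optional lag blocks); round-trips losslessly.

Errors are reported with the 1-based data row number (header = row 1).
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import asdict
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
import yaml

from .domain import (
    AsertResponse,
    ClinicalAssessment,
    MatchedRecord,
    Patient,
    RunConfig,
)

__all__ = [
    "read_asert_table",
    "write_asert_table",
    "read_clinical_table",
    "write_clinical_table",
    "read_patient_table",
    "write_patient_table",
    "read_matched_table",
    "write_matched_table",
    "matched_frame",
    "load_config",
    "save_config",
]

PathLike = Union[str, Path]

_Q_COLS = [f"q{k}" for k in range(1, 11)]
_M_COLS = [f"m{k}" for k in range(1, 11)]
_Y_COLS = [f"y{k}" for k in range(1, 12)]


class TableFormatError(ValueError):
    """Raised when an input table violates its schema."""


def _parse_date(value: str, row: int, column: str) -> dt.date:
    try:
        return dt.date.fromisoformat(str(value).strip())
    except ValueError as exc:
        raise TableFormatError(
            f"row {row}: unparseable date {value!r} in column {column}"
        ) from exc


def _require_columns(df: pd.DataFrame, required: Sequence[str], path: PathLike) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing column(s) {', '.join(missing)}")


def _read_csv(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, dtype=str, keep_default_na=False)


def read_asert_table(path: PathLike) -> list[AsertResponse]:
    """Load weekly self-reports, sorted by (patient_id, date).

    Raises :class:`TableFormatError` (with row numbers) on missing columns,
    out-of-range item values, unparseable dates or duplicate
    (patient_id, date) rows.
    """
    df = _read_csv(path)
    _require_columns(df, ["patient_id", "date", *_Q_COLS], path)
    records: list[AsertResponse] = []
    seen: set[tuple[str, dt.date]] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        rownum = i  # 1-based including header
        pid = str(getattr(row, "patient_id"))
        date = _parse_date(getattr(row, "date"), rownum, "date")
        items = []
        for col in _Q_COLS:
            raw = getattr(row, col)
            try:
                v = int(raw)
            except ValueError as exc:
                raise TableFormatError(
                    f"row {rownum}: non-integer value {raw!r} in {col}"
                ) from exc
            if not (0 <= v <= 4):
                raise TableFormatError(
                    f"row {rownum}: item {col}={v} outside the 0..4 response range"
                )
            items.append(v)
        key = (pid, date)
        if key in seen:
            raise TableFormatError(
                f"row {rownum}: duplicate (patient_id, date) = ({pid}, {date})"
            )
        seen.add(key)
        records.append(AsertResponse(pid, date, tuple(items)))
    records.sort(key=lambda r: (r.patient_id, r.date))
    return records


def write_asert_table(records: Sequence[AsertResponse], path: PathLike) -> None:
    rows = [
        {"patient_id": r.patient_id, "date": r.date.isoformat(),
         **{f"q{k + 1}": r.items[k] for k in range(10)}}
        for r in records
    ]
    pd.DataFrame(rows, columns=["patient_id", "date", *_Q_COLS]).to_csv(
        path, index=False
    )


def _optional_items(
    row, cols: Sequence[str], present: bool, rownum: int
) -> Optional[tuple[int, ...]]:
    if not present:
        return None
    raw = [str(getattr(row, c)).strip() for c in cols]
    if all(v == "" for v in raw):
        return None
    try:
        return tuple(int(v) for v in raw)
    except ValueError as exc:
        raise TableFormatError(
            f"row {rownum}: incomplete or non-integer item-level scores"
        ) from exc


def read_clinical_table(path: PathLike) -> list[ClinicalAssessment]:
    """Load clinician assessments; relapse flags derive from the totals."""
    df = _read_csv(path)
    _require_columns(df, ["patient_id", "date", "madrs_total", "ymrs_total"], path)
    has_m = all(c in df.columns for c in _M_COLS)
    has_y = all(c in df.columns for c in _Y_COLS)
    records: list[ClinicalAssessment] = []
    seen: set[tuple[str, dt.date]] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        pid = str(getattr(row, "patient_id"))
        date = _parse_date(getattr(row, "date"), i, "date")
        try:
            madrs = int(getattr(row, "madrs_total"))
            ymrs = int(getattr(row, "ymrs_total"))
        except ValueError as exc:
            raise TableFormatError(f"row {i}: non-integer scale total") from exc
        key = (pid, date)
        if key in seen:
            raise TableFormatError(
                f"row {i}: duplicate (patient_id, date) = ({pid}, {date})"
            )
        seen.add(key)
        try:
            records.append(
                ClinicalAssessment(
                    pid,
                    date,
                    madrs,
                    ymrs,
                    madrs_items=_optional_items(row, _M_COLS, has_m, i),
                    ymrs_items=_optional_items(row, _Y_COLS, has_y, i),
                )
            )
        except ValueError as exc:
            raise TableFormatError(f"row {i}: {exc}") from exc
    records.sort(key=lambda r: (r.patient_id, r.date))
    return records


def write_clinical_table(
    records: Sequence[ClinicalAssessment], path: PathLike
) -> None:
    has_m = any(r.madrs_items is not None for r in records)
    has_y = any(r.ymrs_items is not None for r in records)
    cols = ["patient_id", "date", "madrs_total", "ymrs_total"]
    if has_m:
        cols += _M_COLS
    if has_y:
        cols += _Y_COLS
    rows = []
    for r in records:
        d = {
            "patient_id": r.patient_id,
            "date": r.date.isoformat(),
            "madrs_total": r.madrs_total,
            "ymrs_total": r.ymrs_total,
        }
        if has_m:
            items = r.madrs_items
            d.update(
                {c: ("" if items is None else items[k]) for k, c in enumerate(_M_COLS)}
            )
        if has_y:
            items = r.ymrs_items
            d.update(
                {c: ("" if items is None else items[k]) for k, c in enumerate(_Y_COLS)}
            )
        rows.append(d)
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_patient_table(path: PathLike) -> list[Patient]:
    df = _read_csv(path)
    _require_columns(df, ["patient_id", "enrollment_date", "exit_date"], path)
    patients: list[Patient] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        pid = str(getattr(row, "patient_id"))
        if pid in seen:
            raise TableFormatError(f"row {i}: duplicate patient_id {pid}")
        seen.add(pid)
        patients.append(
            Patient(
                pid,
                _parse_date(getattr(row, "enrollment_date"), i, "enrollment_date"),
                _parse_date(getattr(row, "exit_date"), i, "exit_date"),
            )
        )
    patients.sort(key=lambda p: p.patient_id)
    return patients


def write_patient_table(patients: Sequence[Patient], path: PathLike) -> None:
    rows = [
        {
            "patient_id": p.patient_id,
            "enrollment_date": p.enrollment_date.isoformat(),
            "exit_date": p.exit_date.isoformat(),
        }
        for p in patients
    ]
    pd.DataFrame(
        rows, columns=["patient_id", "enrollment_date", "exit_date"]
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Matched-record table

_MATCHED_COLS = (
    ["patient_id", "assessment_date", "madrs_total", "ymrs_total"]
    + _M_COLS
    + _Y_COLS
    + ["asert_date"]
    + _Q_COLS
    + ["lag1_date"]
    + [f"lag1_q{k}" for k in range(1, 11)]
    + ["lag2_date"]
    + [f"lag2_q{k}" for k in range(1, 11)]
)


def write_matched_table(records: Sequence[MatchedRecord], path: PathLike) -> None:
    """Write matched records; absent lags leave their cells empty, never zero."""
    rows = []
    for r in records:
        a = r.assessment
        d: dict[str, object] = {
            "patient_id": a.patient_id,
            "assessment_date": a.date.isoformat(),
            "madrs_total": a.madrs_total,
            "ymrs_total": a.ymrs_total,
        }
        for k, c in enumerate(_M_COLS):
            d[c] = "" if a.madrs_items is None else a.madrs_items[k]
        for k, c in enumerate(_Y_COLS):
            d[c] = "" if a.ymrs_items is None else a.ymrs_items[k]
        d["asert_date"] = r.concurrent.date.isoformat()
        for k in range(10):
            d[f"q{k + 1}"] = r.concurrent.items[k]
        for name, lag in (("lag1", r.lag1), ("lag2", r.lag2)):
            d[f"{name}_date"] = "" if lag is None else lag.date.isoformat()
            for k in range(10):
                d[f"{name}_q{k + 1}"] = "" if lag is None else lag.items[k]
        rows.append(d)
    pd.DataFrame(rows, columns=_MATCHED_COLS).to_csv(path, index=False)


def read_matched_table(path: PathLike) -> list[MatchedRecord]:
    df = _read_csv(path)
    _require_columns(df, _MATCHED_COLS, path)
    records: list[MatchedRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        pid = str(getattr(row, "patient_id"))
        assessment = ClinicalAssessment(
            pid,
            _parse_date(getattr(row, "assessment_date"), i, "assessment_date"),
            int(getattr(row, "madrs_total")),
            int(getattr(row, "ymrs_total")),
            madrs_items=_optional_items(row, _M_COLS, True, i),
            ymrs_items=_optional_items(row, _Y_COLS, True, i),
        )
        concurrent = AsertResponse(
            pid,
            _parse_date(getattr(row, "asert_date"), i, "asert_date"),
            tuple(int(getattr(row, c)) for c in _Q_COLS),
        )
        lags: dict[str, Optional[AsertResponse]] = {}
        for name in ("lag1", "lag2"):
            date_raw = str(getattr(row, f"{name}_date")).strip()
            if date_raw == "":
                lags[name] = None
            else:
                lags[name] = AsertResponse(
                    pid,
                    _parse_date(date_raw, i, f"{name}_date"),
                    tuple(int(getattr(row, f"{name}_q{k}")) for k in range(1, 11)),
                )
        records.append(
            MatchedRecord(assessment, concurrent, lag1=lags["lag1"], lag2=lags["lag2"])
        )
    return records


def matched_frame(records: Sequence[MatchedRecord]) -> pd.DataFrame:
    """Flatten matched records into the analysis DataFrame.

    Columns include the scale totals, relapse labels, the concurrent items and
    subscores, the signed concurrent offset ``delta_days``, per-lag subscores
    (NaN when the lag is absent) and, when archived, item-level clinician
    scores.
    """
    rows = []
    for r in records:
        a = r.assessment
        c = r.concurrent
        d: dict[str, object] = {
            "patient_id": a.patient_id,
            "assessment_date": a.date,
            "madrs_total": a.madrs_total,
            "ymrs_total": a.ymrs_total,
            "dep_relapse": int(a.dep_relapse),
            "man_relapse": int(a.man_relapse),
            "delta_days": r.delta_days,
            "asert_date": c.date,
            "dep_sum": c.dep_sum,
            "man_sum": c.man_sum,
            "nsp_sum": c.nsp_sum,
            "depnsp_sum": c.depnsp_sum,
        }
        for k in range(10):
            d[f"q{k + 1}"] = c.items[k]
        if a.madrs_items is not None:
            for k in range(10):
                d[f"m{k + 1}"] = a.madrs_items[k]
        if a.ymrs_items is not None:
            for k in range(11):
                d[f"y{k + 1}"] = a.ymrs_items[k]
        for name, lag in (("lag1", r.lag1), ("lag2", r.lag2)):
            d[f"{name}_dep_sum"] = float("nan") if lag is None else lag.dep_sum
            d[f"{name}_man_sum"] = float("nan") if lag is None else lag.man_sum
            d[f"{name}_nsp_sum"] = float("nan") if lag is None else lag.nsp_sum
            d[f"{name}_depnsp_sum"] = (
                float("nan") if lag is None else lag.depnsp_sum
            )
        rows.append(d)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Run configuration

def load_config(path: PathLike) -> RunConfig:
    """Read a YAML or JSON run configuration; unknown keys are rejected."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise TableFormatError(f"{path}: config must be a mapping")
    valid = set(RunConfig.__dataclass_fields__)
    unknown = set(data) - valid
    if unknown:
        raise TableFormatError(
            f"{path}: unknown config key(s) {', '.join(sorted(unknown))}"
        )
    return RunConfig(**data)


def save_config(config: RunConfig, path: PathLike) -> None:
    path = Path(path)
    data = asdict(config)
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
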