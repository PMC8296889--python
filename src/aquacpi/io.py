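"""Readers and writers for monitoring data, standards and result reports.

Monitoring data travel as a long-format CSV with columns
``facility_id,date,parameter,value,unit``; values beginning with ``<`` are
parsed as left-censored measurements at the stated detection limit.
Standards live in a YAML document declaring the parameter set and one
objective table per reuse scenario.  Reports are emitted as JSON, CSV or a
Markdown pipe table with identical numeric content.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

import pandas as pd
import yaml

from .types import (
    BoundType,
    CensorFlag,
    Measurement,
    MonitoringSeries,
    ObjectiveSpec,
    ParameterDef,
    ScenarioStandards,
)

if TYPE_CHECKING:  # pragma: no cover
    from .benchmark import IndexResult

__all__ = [
    "read_monitoring_csv",
    "write_monitoring_csv",
    "read_standards_config",
    "read_parameter_defs",
    "write_report",
    "REPORT_COLUMNS",
]

_MONITORING_COLUMNS = ["facility_id", "date", "parameter", "value", "unit"]


def _parse_value(raw: object, row_no: int) -> tuple[float, CensorFlag, float | None]:
    """Parse a value cell; ``"<x"`` becomes a censored result at limit x."""
    text = str(raw).strip()
    if text.startswith("<"):
        try:
            limit = float(text[1:])
        except ValueError:
            raise ValueError(f"row {row_no}: non-numeric censored value {text!r}")
        return limit, CensorFlag.below_detection, limit
    try:
        value = float(text)
    except ValueError:
        raise ValueError(f"row {row_no}: non-numeric value {text!r}")
    if not math.isfinite(value):
        raise ValueError(f"row {row_no}: non-finite value {text!r}")
    return value, CensorFlag.none, None


def read_monitoring_csv(
    path: str | Path, parameter_set: Sequence[ParameterDef]
) -> list[MonitoringSeries]:
    """Read a long-format monitoring CSV into one series per (facility, parameter).

    Raises ``ValueError`` on an empty file, an unknown parameter code, a
    non-numeric value (with the offending row number) or a unit that
    disagrees with the parameter definition.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: no records")
    if frame.empty:
        raise ValueError(f"{path}: no records")
    missing = [c for c in _MONITORING_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")

    by_code = {p.code: p for p in parameter_set}
    records: dict[tuple[str, str], list[Measurement]] = {}
    for idx, row in enumerate(frame.itertuples(index=False), start=2):  # 1 = header
        code = str(row.parameter)
        if code not in by_code:
            raise ValueError(f"row {idx}: unknown parameter code {code!r}")
        pdef = by_code[code]
        unit = str(row.unit).strip()
        if unit != pdef.unit:
            raise ValueError(
                f"row {idx}: unit {unit!r} does not match {pdef.unit!r} for {code}"
            )
        value, censored, limit = _parse_value(row.value, idx)
        meas = Measurement(
            date=pd.Timestamp(row.date).date(),
            value=value,
            censored=censored,
            detection_limit=limit,
        )
        records.setdefault((str(row.facility_id), code), []).append(meas)

    series = []
    for (facility, code), measurements in sorted(records.items()):
        measurements.sort(key=lambda m: m.date)
        series.append(
            MonitoringSeries(
                facility_id=facility,
                parameter=by_code[code],
                measurements=measurements,
            )
        )
    return series


def write_monitoring_csv(dataset: Iterable[MonitoringSeries], path: str | Path) -> None:
    """Write series back to the long CSV format (inverse of ``read_monitoring_csv``)."""
    rows = []
    for series in dataset:
        for m in series.measurements:
            if m.censored is CensorFlag.below_detection:
                value = f"<{m.detection_limit:g}"
            else:
                value = repr(m.value)
            rows.append(
                {
                    "facility_id": series.facility_id,
                    "date": m.date.isoformat(),
                    "parameter": series.parameter.code,
                    "value": value,
                    "unit": series.parameter.unit,
                }
            )
    pd.DataFrame(rows, columns=_MONITORING_COLUMNS).to_csv(path, index=False)


def _objective_from_mapping(code: str, raw: dict) -> ObjectiveSpec:
    bound_type = BoundType(raw["bound_type"])
    low = raw.get("low")
    high = raw.get("high")
    if bound_type is not BoundType.absent and low is None and high is None:
        raise ValueError(f"parameter {code!r}: no limits but bound_type != absent")
    return ObjectiveSpec(bound_type=bound_type, low=low, high=high)


def read_parameter_defs(path: str | Path) -> list[ParameterDef]:
    """Read the ``parameters`` section of a standards YAML document."""
    doc = yaml.safe_load(Path(path).read_text())
    return [ParameterDef(**entry) for entry in doc.get("parameters", [])]


def read_standards_config(path: str | Path) -> list[ScenarioStandards]:
    """Read per-scenario objective tables from a standards YAML document."""
    doc = yaml.safe_load(Path(path).read_text())
    if not doc or "scenarios" not in doc:
        raise ValueError(f"{path}: no scenarios declared")
    standards = []
    for entry in doc["scenarios"]:
        objectives = {
            code: _objective_from_mapping(code, raw)
            for code, raw in entry["objectives"].items()
        }
        standards.append(
            ScenarioStandards(
                scenario_id=entry["scenario_id"],
                description=entry.get("description", ""),
                objectives=objectives,
            )
        )
    return standards


REPORT_COLUMNS = [
    "facility",
    "scenario",
    "GWQI",
    "CWQI_PC",
    "WQI_MB",
    "modified_CWQI",
    "F1",
    "F2",
    "F3",
    "category",
    "benchmark",
    "gap",
    "actions",
]


def _result_row(result: "IndexResult") -> dict:
    ccme = result.ccme
    factors = ccme.factors if ccme else None
    return {
        "facility": result.facility_id,
        "scenario": result.scenario_id,
        "GWQI": result.gwqi,
        "CWQI_PC": ccme.cwqi_pc if ccme else None,
        "WQI_MB": ccme.wqi_mb if ccme else None,
        "modified_CWQI": ccme.modified_cwqi if ccme else None,
        "F1": factors.f1 if factors else None,
        "F2": factors.f2 if factors else None,
        "F3": factors.f3 if factors else None,
        "category": result.category,
        "benchmark": result.benchmark,
        "gap": result.gap,
        "actions": result.actions,
    }


def _markdown_table(frame: pd.DataFrame) -> str:
    cells = frame.astype(object).where(frame.notna(), "")
    cells = cells.map(lambda v: f"{v:.2f}" if isinstance(v, float) else str(v))
    widths = [
        max(len(col), *(len(v) for v in cells[col])) for col in cells.columns
    ]
    header = "| " + " | ".join(c.ljust(w) for c, w in zip(cells.columns, widths)) + " |"
    rule = "| " + " | ".join("-" * w for w in widths) + " |"
    lines = [header, rule]
    for _, row in cells.iterrows():
        lines.append(
            "| " + " | ".join(str(v).ljust(w) for v, w in zip(row, widths)) + " |"
        )
    return "\n".join(lines) + "\n"


def write_report(
    results: Sequence["IndexResult"], path: str | Path, format: str = "json"
) -> None:
    """Write assessment results as ``json``, ``csv`` or ``markdown``."""
    if not results:
        raise ValueError("no results to report")
    rows = [_result_row(r) for r in results]
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(rows, indent=2) + "\n")
    elif format == "csv":
        frame = pd.DataFrame(rows, columns=REPORT_COLUMNS)
        frame["actions"] = frame["actions"].map(lambda a: " | ".join(a))
        frame.to_csv(path, index=False)
    elif format == "markdown":
        frame = pd.DataFrame(rows, columns=REPORT_COLUMNS)
        frame["actions"] = frame["actions"].map(lambda a: "; ".join(a))
        path.write_text(_markdown_table(frame))
    else:
        raise ValueError(f"unknown report format {format!r}")
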