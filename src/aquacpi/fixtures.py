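"""Packaged reference tables: standards, monitoring summaries, printed indices.

The published study tables ship with the package as plain-text data files
so every pipeline stage can be exercised and cross-checked without the
confidential raw monitoring series.  ``load_paper_table`` returns each
table as the typed object the corresponding module consumes.
"""

from __future__ import annotations

from importlib import resources
from io import StringIO

import pandas as pd
import yaml

from .ccme import CATEGORY_BANDS, SUBINDEX_WEIGHTS
from .compliance import NonExceedanceTable, PEntry
from .io import _objective_from_mapping
from .types import ObjectiveSpec, ParameterDef, ScenarioStandards

__all__ = [
    "default_parameter_set",
    "load_paper_table",
    "TABLE_IDS",
]

TABLE_IDS = (
    "standards",      # objective limits per scenario
    "summary",        # per-facility monitoring summary statistics
    "p_values",       # printed non-exceedance probabilities
    "weights",        # printed entropy-method importance weights
    "ccme_weights",   # sub-index weighting scheme (W1, W2)
    "categories",     # performance category bands
    "actions",        # improvement actions per scenario
)


def _read_data_text(name: str) -> str:
    return resources.files("aquacpi.data").joinpath(name).read_text()


def default_parameter_set() -> list[ParameterDef]:
    """The eleven routinely monitored effluent parameters."""
    doc = yaml.safe_load(_read_data_text("standards.yaml"))
    return [ParameterDef(**entry) for entry in doc["parameters"]]


def _load_standards() -> list[ScenarioStandards]:
    doc = yaml.safe_load(_read_data_text("standards.yaml"))
    out = []
    for entry in doc["scenarios"]:
        objectives = {
            code: _objective_from_mapping(code, raw)
            for code, raw in entry["objectives"].items()
        }
        out.append(
            ScenarioStandards(
                scenario_id=entry["scenario_id"],
                description=entry.get("description", ""),
                objectives=objectives,
            )
        )
    return out


def _load_summary() -> pd.DataFrame:
    return pd.read_csv(StringIO(_read_data_text("effluent_summary.csv")), dtype=str)


def _load_p_values() -> dict[str, NonExceedanceTable]:
    frame = pd.read_csv(StringIO(_read_data_text("nonexceedance_probabilities.csv")))
    tables: dict[str, NonExceedanceTable] = {}
    for row in frame.itertuples(index=False):
        table = tables.setdefault(
            row.scenario, NonExceedanceTable(scenario_id=row.scenario)
        )
        p = float(row.p)
        table.entries[(row.facility, row.parameter)] = PEntry(p=p, pe=100.0 - p)
    return tables


def _load_weights() -> dict[str, dict[str, float]]:
    frame = pd.read_csv(StringIO(_read_data_text("entropy_weights.csv")))
    out: dict[str, dict[str, float]] = {}
    for row in frame.itertuples(index=False):
        out.setdefault(row.scenario, {})[row.parameter] = float(row.weight)
    return out


def load_paper_table(table_id: str):
    """Return a packaged reference table as its typed in-memory form.

    ``standards``    → list[ScenarioStandards]
    ``summary``      → DataFrame (string cells; "<1" marks non-detects)
    ``p_values``     → dict scenario → NonExceedanceTable
    ``weights``      → dict scenario → {parameter: weight}
    ``ccme_weights`` → dict scenario → (W1, W2)
    ``categories``   → list of (low, high, label) bands
    ``actions``      → list[ActionRule]
    """
    if table_id == "standards":
        return _load_standards()
    if table_id == "summary":
        return _load_summary()
    if table_id == "p_values":
        return _load_p_values()
    if table_id == "weights":
        return _load_weights()
    if table_id == "ccme_weights":
        return dict(SUBINDEX_WEIGHTS)
    if table_id == "categories":
        return list(CATEGORY_BANDS)
    if table_id == "actions":
        from .benchmark import DEFAULT_ACTION_RULES

        return list(DEFAULT_ACTION_RULES)
    raise KeyError(f"unknown table id {table_id!r}; expected one of {TABLE_IDS}")
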