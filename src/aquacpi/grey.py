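"""Grey relational aggregation of non-exceedance probabilities (GWQI).

Each facility's vector of non-exceedance percentages is compared with the
perfect-compliance reference sequence (P = 100 for every parameter).
With deviations Δ_ik = |100 − P_ik|, the grey relational coefficient of
entry (i, k) is

    ξ_ik = (Δmin + ξ·Δmax) / (Δ_ik + ξ·Δmax),

where Δmin/Δmax are taken over the whole comparison set of a scenario
(all facilities × all parameters by default) and the distinguishing
coefficient ξ ∈ (0, 1] moderates the contrast (ξ = 0.5 by default).  The
grey water quality index is the weighted grade

    GWQI_i = 100 · Σ_k W_k ξ_ik  ∈ [0, 100].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Union

import pandas as pd
from pydantic import BaseModel, Field

from .compliance import NonExceedanceTable
from .entropy import WeightVector

__all__ = ["GreyConfig", "GreyResult", "grey_coefficients", "gwqi"]

#: slack allowed on the weight-sum check, so printed weight tables rounded
#: to two decimals remain usable directly (rounded rows can drift to 0.97)
_WEIGHT_SUM_TOL = 0.05


class GreyConfig(BaseModel):
    """Knobs of the grey relational computation."""

    distinguishing_coefficient: float = Field(default=0.5, gt=0.0, le=1.0)
    reference_value: float = 100.0
    scale_to_100: bool = True
    #: "global" pools Δmin/Δmax over all facilities and parameters of the
    #: scenario; "per_parameter" scopes them within each parameter column.
    comparison_scope: str = "global"


@dataclass
class GreyResult:
    scenario_id: str
    deviations: pd.DataFrame     # Δ_ik, facility × parameter
    coefficients: pd.DataFrame   # ξ_ik, facility × parameter
    gwqi: dict[str, float]       # per facility


def grey_coefficients(
    p_table: NonExceedanceTable, config: GreyConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Deviation and grey-coefficient grids for one scenario's P table."""
    config = config or GreyConfig()
    if not p_table.entries:
        raise ValueError("empty non-exceedance table")
    p = p_table.to_frame()
    delta = (config.reference_value - p).abs()
    xi = config.distinguishing_coefficient
    if config.comparison_scope == "global":
        d_min = float(delta.min().min())
        d_max = float(delta.max().max())
    elif config.comparison_scope == "per_parameter":
        d_min = delta.min(axis=0)
        d_max = delta.max(axis=0)
    else:
        raise ValueError(f"unknown comparison_scope {config.comparison_scope!r}")
    denom = delta + xi * d_max
    numer = d_min + xi * d_max
    coeff = (numer / denom).where(denom != 0, 1.0)  # Δmax = 0 ⇒ ξ_ik = 1
    return delta, coeff


def gwqi(
    p_table: NonExceedanceTable,
    weights: Union[WeightVector, Mapping[str, float]],
    config: GreyConfig | None = None,
) -> GreyResult:
    """Per-facility grey water quality index from a P table and weights.

    ``weights`` may be a computed :class:`WeightVector` or any mapping of
    parameter code to weight; the weights must cover every parameter in
    the table and sum to 1 (a slack of ±0.02 accommodates published
    weight tables rounded to two decimals).
    """
    config = config or GreyConfig()
    w = weights.as_mapping() if isinstance(weights, WeightVector) else dict(weights)
    missing = [p for p in p_table.parameters() if p not in w]
    if missing:
        raise KeyError(f"weights missing for parameters: {missing}")
    total = sum(w[p] for p in p_table.parameters())
    if abs(total - 1.0) > _WEIGHT_SUM_TOL:
        raise ValueError(f"weights over table parameters sum to {total}, not ~1")

    delta, coeff = grey_coefficients(p_table, config)
    w_series = pd.Series({p: w[p] for p in coeff.columns})
    grade = (coeff * w_series).sum(axis=1)
    if config.scale_to_100:
        grade = 100.0 * grade
    return GreyResult(
        scenario_id=p_table.scenario_id,
        deviations=delta,
        coefficients=coeff,
        gwqi={f: float(v) for f, v in grade.items()},
    )
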