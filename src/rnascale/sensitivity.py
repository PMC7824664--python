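"""One-at-a-time tornado analysis, titre scenarios, scale sweeps and
recovery recalibration."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import economics, throughput
from .scenarios import CostParams, Demand, ProcessParams, VaccineScenario

__all__ = [
    "TornadoRow",
    "RecoveryFit",
    "DEFAULT_TORNADO_RANGES",
    "tornado",
    "titre_scenarios",
    "scale_sweep",
    "recalibrate_recovery",
    "single_line_outputs",
]

#: Swept parameter ranges.  Dose, scale, titre and failure ranges are the
#: study's published uncertainty ranges; price/labour/QC ranges default to
#: 0.5x-2x of their baselines (their published ranges are graphical only).
DEFAULT_TORNADO_RANGES: Dict[str, Optional[Tuple[float, float]]] = {
    "rna_per_dose_ug": (0.1, 100.0),
    "volume_l": (1.0, 50.0),
    "titre_g_per_l": (2.0, 7.0),
    "failure_rate": (0.0, 0.15),
    "cleancap_price": None,   # None -> 0.5x-2x baseline
    "mod_utp_price": None,
    "labour_rate": None,
    "qc_fraction": None,
}

_VACCINE_FIELDS = {"rna_per_dose_ug"}
_PROCESS_FIELDS = {"volume_l", "titre_g_per_l", "failure_rate"}
_COST_FIELDS = {"cleancap_price", "mod_utp_price", "labour_rate", "qc_fraction"}


@dataclass(frozen=True)
class TornadoRow:
    """Relative effect of one parameter's bounds on annual doses and cost/dose."""

    parameter: str
    low_value: float
    high_value: float
    delta_doses_low: float    # percent vs baseline
    delta_doses_high: float
    delta_cost_low: float
    delta_cost_high: float

    @property
    def max_abs_effect(self) -> float:
        return max(abs(self.delta_doses_low), abs(self.delta_doses_high),
                   abs(self.delta_cost_low), abs(self.delta_cost_high))

    @property
    def max_abs_doses_effect(self) -> float:
        return max(abs(self.delta_doses_low), abs(self.delta_doses_high))

    @property
    def max_abs_cost_effect(self) -> float:
        return max(abs(self.delta_cost_low), abs(self.delta_cost_high))


def single_line_outputs(
    vaccine: VaccineScenario, process: ProcessParams, costs: CostParams
) -> Tuple[float, float]:
    """(annual doses, cost per dose) of one production line running at capacity."""
    recovery = throughput.process_recovery(process)
    bpy = throughput.batches_per_year(process.volume_l, process.capacity_anchors)
    annual_mass, _ = throughput.annual_output(
        process.volume_l, process.titre_g_per_l, recovery, process.capacity_anchors
    )
    doses = throughput.annual_doses(annual_mass, vaccine.rna_per_dose_ug)
    result = economics.opex_annual(vaccine, process, costs, required_batches=bpy)
    return doses, result.opex_annual / doses


def _with(vaccine, process, costs, name, value):
    if name in _VACCINE_FIELDS:
        return vaccine.model_copy(update={name: value}), process, costs
    if name in _PROCESS_FIELDS:
        return vaccine, process.model_copy(update={name: value}), costs
    if name in _COST_FIELDS:
        return vaccine, process, costs.model_copy(update={name: value})
    raise ValueError(f"unknown tornado parameter: {name}")


def _baseline_value(vaccine, process, costs, name) -> float:
    for obj in (vaccine, process, costs):
        if name in type(obj).model_fields:
            return getattr(obj, name)
    raise ValueError(f"unknown tornado parameter: {name}")


def tornado(
    vaccine: VaccineScenario,
    process: ProcessParams,
    costs: CostParams,
    ranges: Optional[Dict[str, Optional[Tuple[float, float]]]] = None,
) -> list[TornadoRow]:
    """One-at-a-time sensitivity of a single line's annual doses and cost/dose.

    Each parameter is evaluated at its range endpoints with everything else
    held at baseline; rows come back sorted by largest absolute effect.
    """
    ranges = dict(DEFAULT_TORNADO_RANGES if ranges is None else ranges)
    base_doses, base_cpd = single_line_outputs(vaccine, process, costs)
    rows = []
    for name, bounds in ranges.items():
        baseline = _baseline_value(vaccine, process, costs, name)
        if bounds is None:
            bounds = (0.5 * baseline, 2.0 * baseline)
        lo, hi = bounds
        if not lo <= baseline <= hi:
            raise ValueError(
                f"range ({lo}, {hi}) for {name} does not bracket baseline {baseline}"
            )
        deltas = []
        for endpoint in (lo, hi):
            doses, cpd = single_line_outputs(*_with(vaccine, process, costs, name, endpoint))
            deltas.append((100.0 * (doses / base_doses - 1.0),
                           100.0 * (cpd / base_cpd - 1.0)))
        rows.append(TornadoRow(
            parameter=name, low_value=lo, high_value=hi,
            delta_doses_low=deltas[0][0], delta_doses_high=deltas[1][0],
            delta_cost_low=deltas[0][1], delta_cost_high=deltas[1][1],
        ))
    rows.sort(key=lambda r: r.max_abs_effect, reverse=True)
    return rows


def titre_scenarios(
    vaccine: VaccineScenario,
    process: ProcessParams,
    costs: CostParams,
    demand: Demand,
    titres: Sequence[float] = (4.0, 5.0, 6.0),
) -> Dict[str, Tuple[throughput.CapacityResult, economics.CostResult]]:
    """Low/medium/high assessment at -20%/baseline/+20% titre.

    ``low`` is the worst (lowest-titre) case.  Returns per-case capacity and
    cost results at the process scale.
    """
    if len(titres) != 3:
        raise ValueError("exactly three titres (low, medium, high) expected")
    out = {}
    for label, titre in zip(("low", "medium", "high"), sorted(titres)):
        proc = process.model_copy(update={"titre_g_per_l": titre})
        cap = throughput.evaluate_capacity(vaccine, proc, demand)
        cost = economics.opex_annual(vaccine, proc, costs, cap.required_batches)
        out[label] = (cap, cost)
    return out


def scale_sweep(
    vaccine: VaccineScenario,
    process: ProcessParams,
    costs: CostParams,
    volumes: Sequence[float],
) -> pd.DataFrame:
    """Single-line annual doses and cost/dose across scales.

    Volumes above the 30 L scale-up feasibility limit are computed anyway
    but trigger a warning.
    """
    records = []
    for v in volumes:
        if v > 30.0:
            warnings.warn(
                f"volume {v} L exceeds the 30 L scale-up feasibility limit",
                stacklevel=2,
            )
        proc = process.model_copy(update={"volume_l": float(v)})
        doses, cpd = single_line_outputs(vaccine, proc, costs)
        records.append({"volume_l": float(v), "annual_doses": doses, "cost_per_dose": cpd})
    return pd.DataFrame.from_records(records)


@dataclass(frozen=True)
class RecoveryFit:
    recovery: float
    residuals: Tuple[float, ...]  # observed - fitted batches, per row


def recalibrate_recovery(
    table: Sequence[Tuple[float, float, float, float]],
    demand_doses: float = 8e9,
) -> RecoveryFit:
    """Least-squares effective recovery from (dose ug, titre, volume, batches) rows.

    The batch count model is ``demand mass / (volume x titre x recovery)``,
    linear in 1/recovery, so the fit is closed-form.  Contradictory rows
    yield nonzero residuals, never an exception.
    """
    if len(table) == 0:
        raise ValueError("recovery recalibration needs at least one row")
    rows = np.asarray(table, dtype=float)
    if rows.ndim != 2 or rows.shape[1] != 4:
        raise ValueError("each row must be (dose_ug, titre, volume, batches)")
    dose, titre, volume, batches = rows.T
    a = demand_doses * dose * 1e-6 / (volume * titre)  # batches x recovery
    s = float(np.dot(a, batches) / np.dot(a, a))       # s = 1/recovery
    fitted = a * s
    return RecoveryFit(recovery=1.0 / s, residuals=tuple(batches - fitted))
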