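"""CapEx/OpEx model and cost-per-dose computation.

The cost model is a calibrated surrogate, not a bottom-up simulation: unit
operations are not modelled individually.  Per-batch costs split into
materials (reagents charged on the design-basis synthesis mass), consumables
(single-use equipment, power-law in scale), labour and QC; capital cost per
line follows a power law in scale and enters OpEx via straight-line
annualisation.  Coefficient defaults are frozen calibration output (see
:func:`calibrate_costs`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares

from .scenarios import CostParams, Demand, ProcessParams, UTPType, VaccineScenario
from . import throughput

__all__ = [
    "CostResult",
    "CalibrationTarget",
    "CalibrationReport",
    "capex_per_line",
    "per_batch_costs",
    "opex_annual",
    "cost_per_dose",
    "calibrate_costs",
    "check_breakdown_ordering",
]

#: Breakdown component keys, in reporting order.
COMPONENTS = (
    "materials_cleancap",
    "materials_modutp",
    "materials_other",
    "consumables",
    "labour",
    "qc",
    "annualised_capex",
)


@dataclass(frozen=True)
class CostResult:
    """Annual cost assessment for one scenario at one scale."""

    capex_total: float
    opex_annual: float
    cost_per_dose: float
    breakdown: Dict[str, float]
    facilities: int

    @property
    def materials_total(self) -> float:
        return (self.breakdown["materials_cleancap"]
                + self.breakdown["materials_modutp"]
                + self.breakdown["materials_other"])


def capex_per_line(
    volume: float,
    capex_ref: float,
    exponent: float,
    reference_volume: float = 30.0,
) -> float:
    """Capital cost of one production line, power-law scaled from a reference."""
    if volume <= 0:
        raise ValueError(f"volume must be positive, got {volume}")
    return capex_ref * (volume / reference_volume) ** exponent


def per_batch_costs(
    vaccine: VaccineScenario, volume: float, costs: CostParams
) -> Dict[str, float]:
    """Variable cost per batch by component (no capital)."""
    design_mass = volume * costs.design_titre_g_per_l
    labour = costs.labour_hours_per_batch * costs.labour_rate
    out = {
        "materials_cleancap": design_mass * costs.cleancap_per_g_rna * costs.cleancap_price,
        "materials_modutp": (
            design_mass * costs.modutp_per_g_rna * costs.mod_utp_price
            if vaccine.utp_type == UTPType.modified else 0.0
        ),
        "materials_other": design_mass * costs.materials_other_per_g,
        "consumables": costs.consumables_per_batch_ref
        * (volume / costs.consumables_reference_volume) ** costs.consumables_scale_exponent,
        "labour": labour,
        "qc": costs.qc_fraction * labour,
    }
    return out


def opex_annual(
    vaccine: VaccineScenario,
    process: ProcessParams,
    costs: CostParams,
    required_batches: float,
    volume: Optional[float] = None,
) -> CostResult:
    """Annual operating cost (incl. annualised CapEx) to run a batch requirement.

    ``required_batches`` is the annual batch count (real-valued); facilities
    are the ceiling of batches over single-line annual capacity, each
    carrying one line's annualised capital.  Cost per dose divides the total
    by the doses those batches deliver at the effective recovery.
    """
    v = process.volume_l if volume is None else volume
    per_batch = per_batch_costs(vaccine, v, costs)
    facilities = throughput.facilities_required(required_batches, v, process.capacity_anchors)
    line_capex = capex_per_line(v, costs.capex_ref, costs.capex_exponent,
                                costs.capex_reference_volume)
    breakdown = {k: val * required_batches for k, val in per_batch.items()}
    breakdown["annualised_capex"] = facilities * line_capex / costs.depreciation_years
    total = sum(breakdown.values())
    recovery = throughput.process_recovery(process)
    doses = throughput.annual_doses(
        required_batches * v * process.titre_g_per_l * recovery,
        vaccine.rna_per_dose_ug,
    )
    return CostResult(
        capex_total=facilities * line_capex,
        opex_annual=total,
        cost_per_dose=cost_per_dose(total, doses) if doses > 0 else 0.0,
        breakdown=breakdown,
        facilities=facilities,
    )


def cost_per_dose(opex: float, doses: float) -> float:
    """Annual operating cost divided by annual doses."""
    if doses <= 0:
        raise ValueError(f"annual doses must be positive, got {doses}")
    return opex / doses


def check_breakdown_ordering(
    vaccine: VaccineScenario,
    result: CostResult,
    consumables_dominant: bool = False,
) -> list[str]:
    """Return violated qualitative ordering constraints (empty when all hold).

    Materials lead for clinical-stage vaccines, consumables lead for the
    very-low-dose next-generation vaccine, and CleanCap is the largest
    materials line item in every case.
    """
    b = result.breakdown
    materials = (b["materials_cleancap"] + b["materials_modutp"] + b["materials_other"])
    violations = []
    if consumables_dominant:
        if not b["consumables"] > materials:
            violations.append("consumables_not_dominant")
    else:
        if not materials > b["consumables"]:
            violations.append("materials_not_dominant")
    if b["materials_cleancap"] < max(b["materials_modutp"], b["materials_other"]):
        violations.append("cleancap_not_largest_material")
    return violations


@dataclass(frozen=True)
class CalibrationTarget:
    """One printed aggregate: a scenario/process pair and its annual OpEx."""

    vaccine: VaccineScenario
    process: ProcessParams
    opex: float
    demand: Demand = field(default_factory=Demand)


@dataclass(frozen=True)
class CalibrationReport:
    fitted: Dict[str, float]
    residuals: Tuple[float, ...]
    ordering_violations: Dict[str, list]
    feasible: bool


#: Free coefficients and their bounds.  Stoichiometries are bounded above by
#: 1.2 g/g: the printed OpEx anchors combined with the materials-dominance
#: constraint at 30 L are infeasible under a tighter cap.
_DEFAULT_FREE: Dict[str, Tuple[float, float]] = {
    "cleancap_per_g_rna": (0.05, 1.2),
    "modutp_per_g_rna": (0.05, 1.2),
    "materials_other_per_g": (0.0, 1e4),
    "consumables_per_batch_ref": (1.0, 1e7),
    "consumables_scale_exponent": (1e-6, 1.0),
}


def _model_opex(target: CalibrationTarget, costs: CostParams) -> float:
    recovery = throughput.process_recovery(target.process)
    req = throughput.required_batches(
        target.demand.annual_doses, target.vaccine.rna_per_dose_ug,
        target.process.volume_l, target.process.titre_g_per_l, recovery,
    )
    return opex_annual(target.vaccine, target.process, costs, req).opex_annual


def calibrate_costs(
    targets: Sequence[CalibrationTarget],
    base: Optional[CostParams] = None,
    free: Optional[Sequence[str]] = None,
    ordering_cases: Optional[Sequence[Tuple[VaccineScenario, ProcessParams, bool]]] = None,
) -> Tuple[CostParams, CalibrationReport]:
    """Fit free cost coefficients to printed OpEx aggregates.

    Minimizes squared relative error across targets with bounded
    least-squares, then audits the qualitative breakdown-ordering
    constraints on ``ordering_cases`` (vaccine, process,
    consumables_dominant flags).  Infeasible orderings are reported, not
    raised.
    """
    if not targets:
        raise ValueError("at least one calibration target is required")
    base = base or CostParams()
    names = list(free) if free is not None else list(_DEFAULT_FREE)
    for n in names:
        if n not in type(base).model_fields:
            raise ValueError(f"unknown cost coefficient: {n}")
    bounds_lo = [(_DEFAULT_FREE.get(n, (0.0, np.inf)))[0] for n in names]
    bounds_hi = [(_DEFAULT_FREE.get(n, (0.0, np.inf)))[1] for n in names]
    x0 = np.clip([getattr(base, n) for n in names], bounds_lo, bounds_hi)

    def residuals(x: np.ndarray) -> np.ndarray:
        costs = base.model_copy(update=dict(zip(names, (float(v) for v in x))))
        return np.array([
            (_model_opex(t, costs) - t.opex) / t.opex for t in targets
        ])

    fit = least_squares(residuals, x0, bounds=(bounds_lo, bounds_hi),
                        xtol=1e-14, ftol=1e-14, gtol=1e-14)
    fitted = base.model_copy(update=dict(zip(names, (float(v) for v in fit.x))))
    res = tuple(float(r) for r in residuals(fit.x))

    violations: Dict[str, list] = {}
    for vac, proc, cons_dom in (ordering_cases or ()):
        recovery = throughput.process_recovery(proc)
        req = throughput.required_batches(
            Demand().annual_doses, vac.rna_per_dose_ug,
            proc.volume_l, proc.titre_g_per_l, recovery,
        )
        result = opex_annual(vac, proc, fitted, req)
        bad = check_breakdown_ordering(vac, result, consumables_dominant=cons_dom)
        if bad:
            violations[vac.name] = bad
    return fitted, CalibrationReport(
        fitted={n: float(getattr(fitted, n)) for n in names},
        residuals=res,
        ordering_violations=violations,
        feasible=not violations,
    )
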