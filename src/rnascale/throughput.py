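"""Batch-level and annual production arithmetic.

Conventions: a year is 8760 h, a month is a twelfth of a year and a day a
365th.  Batch capacity and duration interpolate linearly between the
scheduling anchors (471 batches/year, 41 h at 1 L; 444 batches/year,
48.2 h at 30 L) and clamp at the anchor values outside the anchored range,
since no scheduling data exists above the 30 L scale-up limit.

Two recovery conventions coexist deliberately: resource sizing (batch
counts, volumes, facilities) uses the full effective recovery (nominal x
survival x residual calibration, ~0.4922) while production timelines use
the nominal recovery (0.56) alone.  The printed resource and timeline
figures are internally inconsistent on this point; both conventions are
therefore explicit arguments rather than hidden defaults.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

from .scenarios import (
    DEFAULT_ANCHORS,
    CapacityAnchor,
    Demand,
    ProcessParams,
    VaccineScenario,
)

__all__ = [
    "HOURS_PER_YEAR",
    "CapacityResult",
    "batches_per_year",
    "batch_duration",
    "effective_recovery",
    "annual_output",
    "annual_doses",
    "required_batches",
    "required_total_volume",
    "facilities_required",
    "time_to_demand",
    "demand_from_population",
    "schedule_oracle",
    "evaluate_capacity",
]

HOURS_PER_YEAR = 8760.0

Anchors = Sequence[CapacityAnchor]


def _interp(volume: float, anchors: Anchors, attr: str) -> float:
    if volume <= 0:
        raise ValueError(f"volume must be positive, got {volume}")
    pts = [(a.volume_l, getattr(a, attr)) for a in anchors]
    if volume <= pts[0][0]:
        return pts[0][1]
    if volume >= pts[-1][0]:
        return pts[-1][1]
    for (v0, y0), (v1, y1) in zip(pts, pts[1:]):
        if v0 <= volume <= v1:
            return y0 + (y1 - y0) * (volume - v0) / (v1 - v0)
    raise AssertionError("unreachable")  # pragma: no cover


def batches_per_year(volume: float, anchors: Anchors = DEFAULT_ANCHORS) -> float:
    """Maximum batches one line completes per year at the given scale."""
    return _interp(volume, anchors, "batches_per_year")


def batch_duration(volume: float, anchors: Anchors = DEFAULT_ANCHORS) -> float:
    """Batch duration in hours at the given scale."""
    return _interp(volume, anchors, "batch_duration_h")


def effective_recovery(
    nominal: float, failure_rate: float, residual_loss_factor: float = 1.0
) -> float:
    """Overall fraction of synthesized RNA ending up as usable drug substance.

    Product of the nominal downstream recovery, the batch survival fraction
    ``1 - failure_rate`` and a residual calibration factor.
    """
    for name, v in (("nominal", nominal), ("failure_rate", failure_rate),
                    ("residual_loss_factor", residual_loss_factor)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be within [0, 1], got {v}")
    return nominal * (1.0 - failure_rate) * residual_loss_factor


def process_recovery(process: ProcessParams) -> float:
    """Effective recovery implied by a :class:`ProcessParams` (sizing convention)."""
    return effective_recovery(
        process.nominal_recovery, process.failure_rate, process.residual_loss_factor
    )


def annual_output(
    volume: float,
    titre: float,
    recovery: float,
    anchors: Anchors = DEFAULT_ANCHORS,
) -> tuple[float, float]:
    """(annual mass [g/yr], per-batch mass [g]) for a single line."""
    if volume <= 0 or titre < 0 or recovery < 0:
        raise ValueError("volume must be positive; titre and recovery nonnegative")
    per_batch = volume * titre * recovery
    return per_batch * batches_per_year(volume, anchors), per_batch


def annual_doses(annual_mass_g: float, rna_per_dose_ug: float) -> float:
    """Convert an annual RNA mass [g/yr] into doses/yr at the given dose mass."""
    if rna_per_dose_ug <= 0:
        raise ValueError(f"rna_per_dose_ug must be positive, got {rna_per_dose_ug}")
    return annual_mass_g * 1e6 / rna_per_dose_ug


def demand_mass_g(demand_doses: float, rna_per_dose_ug: float) -> float:
    """RNA mass [g] needed for the given number of doses."""
    return demand_doses * rna_per_dose_ug * 1e-6


def required_batches(
    demand_doses: float,
    rna_per_dose_ug: float,
    volume: float,
    titre: float,
    recovery: float,
) -> float:
    """Batches needed to supply the demand (real-valued; round for reporting)."""
    if volume <= 0 or titre <= 0 or recovery <= 0:
        raise ValueError("volume, titre and recovery must be positive")
    return demand_mass_g(demand_doses, rna_per_dose_ug) / (volume * titre * recovery)


def required_total_volume(
    demand_doses: float,
    rna_per_dose_ug: float,
    titre: float,
    recovery: float,
    reference_volume: float,
    anchors: Anchors = DEFAULT_ANCHORS,
) -> float:
    """Total bioreactor working volume [L] across all parallel lines.

    Equals required_batches x reference_volume / batches_per_year at the
    reference scale.
    """
    bpy = batches_per_year(reference_volume, anchors)
    return demand_mass_g(demand_doses, rna_per_dose_ug) / (titre * recovery * bpy)


def facilities_required(
    required_batches_count: float,
    volume: float,
    anchors: Anchors = DEFAULT_ANCHORS,
) -> int:
    """Facilities (one line each) to run the batch requirement within a year."""
    if required_batches_count < 0:
        raise ValueError("required batches must be nonnegative")
    if required_batches_count == 0:
        return 0
    return max(1, math.ceil(required_batches_count / batches_per_year(volume, anchors)))


def time_to_demand(
    demand_doses: float,
    rna_per_dose_ug: float,
    volume: float,
    titre: float,
    recovery: float,
    anchors: Anchors = DEFAULT_ANCHORS,
) -> float:
    """Years for a single line to produce the demand; ``inf`` at zero rate."""
    mass = demand_mass_g(demand_doses, rna_per_dose_ug)
    rate, _ = annual_output(volume, titre, recovery, anchors)
    if rate == 0:
        return math.inf if mass > 0 else 0.0
    return mass / rate


def demand_from_population(population: float, doses_per_person: float) -> float:
    if population < 0 or doses_per_person < 0:
        raise ValueError("population and doses_per_person must be nonnegative")
    return population * doses_per_person


def schedule_oracle(
    volume: float,
    horizon_days: float,
    anchors: Anchors = DEFAULT_ANCHORS,
) -> int:
    """Brute-force count of batches a steadily running line completes in a window.

    Batches start at a fixed stagger of ``8760 h / batches_per_year(volume)``
    with the line already in steady state before the window opens; a batch
    counts when its completion time falls inside ``[0, horizon)``.
    """
    duration = batch_duration(volume, anchors)
    horizon_h = horizon_days * 24.0
    if horizon_h < duration:
        raise ValueError("horizon must be at least one batch duration")
    cycle = HOURS_PER_YEAR / batches_per_year(volume, anchors)
    count = 0
    k = -int(math.ceil(duration / cycle)) - 2
    while True:
        completion = k * cycle + duration
        if completion >= horizon_h:
            break
        if completion >= 0.0:
            count += 1
        k += 1
    return count


@dataclass(frozen=True)
class CapacityResult:
    """Annual production and demand-fulfilment requirements for one scenario."""

    rna_per_batch_g: float
    batches_per_year: float
    annual_mass_g: float
    annual_doses: float
    required_batches: float
    required_batches_rounded: int
    required_total_volume_l: float
    facilities: int
    time_to_demand_years: float

    @property
    def time_to_demand_months(self) -> float:
        return self.time_to_demand_years * 12.0

    @property
    def time_to_demand_days(self) -> float:
        return self.time_to_demand_years * 365.0


def evaluate_capacity(
    vaccine: VaccineScenario,
    process: ProcessParams,
    demand: Demand,
    volume: Optional[float] = None,
) -> CapacityResult:
    """Full capacity assessment of one vaccine at one line scale.

    Sizing quantities (batches, volume, facilities) use the effective
    recovery; the single-line timeline uses the nominal recovery (timeline
    reporting convention, see module docstring).
    """
    v = process.volume_l if volume is None else volume
    anchors = process.capacity_anchors
    r_eff = process_recovery(process)
    titre = process.titre_g_per_l
    annual_mass, per_batch = annual_output(v, titre, r_eff, anchors)
    doses = annual_doses(annual_mass, vaccine.rna_per_dose_ug)
    req = required_batches(demand.annual_doses, vaccine.rna_per_dose_ug, v, titre, r_eff)
    total_volume = required_total_volume(
        demand.annual_doses, vaccine.rna_per_dose_ug, titre, r_eff, v, anchors
    )
    return CapacityResult(
        rna_per_batch_g=per_batch,
        batches_per_year=batches_per_year(v, anchors),
        annual_mass_g=annual_mass,
        annual_doses=doses,
        required_batches=req,
        required_batches_rounded=round(req),
        required_total_volume_l=total_volume,
        facilities=facilities_required(req, v, anchors),
        time_to_demand_years=time_to_demand(
            demand.annual_doses, vaccine.rna_per_dose_ug, v, titre,
            process.nominal_recovery, anchors,
        ),
    )
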