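"""Batch-process model of the quinaldine-hydroquinone API flowsheet.

The plant runs a fixed recipe of reaction, filtration, crystallization and
drying steps on shared equipment (three reactors, two Nutsche filters, a
storage tank and a tray dryer).  For costing purposes the model reduces to

* a chain of step yields (the overall yield is their product),
* a bottleneck cycle time that fixes how many batches fit into the annual
  operating window, and
* per-batch material-consumption and waste-emission coefficients, calibrated
  so that the baseline year reproduces the published cost structure.

Equipment sizing, Gantt-level scheduling and unit-operation mass balances are
out of scope; the yield chain and the coefficient vector carry all the
process information the economics needs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

__all__ = [
    "ReactionStep",
    "FlowsheetSpec",
    "BatchResult",
    "chain_yield",
    "batches_per_year",
    "annual_production",
    "material_demand",
    "default_flowsheet",
    "BASELINE_ANNUAL_HOURS",
    "BASELINE_BATCHES",
    "BOTTLENECK_CYCLE_HOURS",
    "PER_BATCH_API_MASS",
]

#: Baseline annual operational availability, hours/year.
BASELINE_ANNUAL_HOURS = 7920.0
#: Baseline number of batches executed per year.
BASELINE_BATCHES = 134
#: Bottleneck recipe cycle time (h), calibrated so the baseline operating
#: window of 7,920 h yields exactly 134 batches.  The published schedule only
#: brackets the total batch duration (58.47-113.39 h); the bottleneck cycle
#: is the effective batch-to-batch interval.
BOTTLENECK_CYCLE_HOURS = BASELINE_ANNUAL_HOURS / BASELINE_BATCHES  # 59.104 h
#: API mass per batch (kg), fixed so 134 batches produce 33,000 kg/yr.
PER_BATCH_API_MASS = 33_000.0 / BASELINE_BATCHES  # 246.27 kg

#: Total batch duration bracket (h) from the published schedule.
SCHEDULE_DURATION_RANGE = (58.47, 113.39)


@dataclass(frozen=True)
class ReactionStep:
    """One procedure of the recipe with its yield and duration."""

    id: str
    yield_fraction: float
    duration: float  # hours
    equipment_id: str

    def __post_init__(self) -> None:
        if not 0.0 < self.yield_fraction <= 1.0:
            raise ValueError(
                f"step {self.id!r}: yield_fraction must be in (0, 1], "
                f"got {self.yield_fraction}"
            )
        if self.duration <= 0.0:
            raise ValueError(f"step {self.id!r}: duration must be positive")


@dataclass(frozen=True)
class FlowsheetSpec:
    """Process recipe plus the calibrated per-batch coefficient vectors."""

    steps: tuple[ReactionStep, ...]
    bottleneck_cycle_time: float = BOTTLENECK_CYCLE_HOURS
    per_batch_api_mass: float = PER_BATCH_API_MASS
    material_coefficients: Mapping[str, float] = field(default_factory=dict)
    waste_coefficients: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lo, hi = SCHEDULE_DURATION_RANGE
        if not lo <= self.bottleneck_cycle_time <= hi:
            raise ValueError(
                "bottleneck_cycle_time must lie within the schedule bracket "
                f"[{lo}, {hi}] h, got {self.bottleneck_cycle_time}"
            )
        for name, coeff in {**dict(self.material_coefficients),
                            **dict(self.waste_coefficients)}.items():
            if coeff < 0.0:
                raise ValueError(f"coefficient for {name!r} is negative")


@dataclass(frozen=True)
class BatchResult:
    """Annual throughput and material/waste flows for one operating year."""

    batches_per_year: int
    annual_production: float  # kg/yr
    annual_material_demand: Mapping[str, float]  # kg/yr per material
    annual_waste: Mapping[str, float]  # kg/yr per stream


def chain_yield(steps: Sequence[ReactionStep | float]) -> float:
    """Overall yield of a sequence of steps (product of step yields).

    Accepts either ``ReactionStep`` objects or bare fractions.
    """
    if len(steps) == 0:
        raise ValueError("no steps")
    total = 1.0
    for step in steps:
        y = step.yield_fraction if isinstance(step, ReactionStep) else float(step)
        if not 0.0 < y <= 1.0:
            raise ValueError(f"yield {y} outside (0, 1]")
        total *= y
    return total


def batches_per_year(annual_hours: float, cycle_time: float = BOTTLENECK_CYCLE_HOURS) -> int:
    """Whole batches that fit into ``annual_hours`` at the bottleneck cycle."""
    if annual_hours <= 0.0:
        raise ValueError("annual_hours must be positive")
    if cycle_time <= 0.0:
        raise ValueError("cycle_time must be positive")
    return math.floor(annual_hours / cycle_time)


def annual_production(batches: int, per_batch_api_mass: float = PER_BATCH_API_MASS) -> float:
    """Annual API output (kg/yr) from the batch count."""
    if batches < 0:
        raise ValueError("batches must be non-negative")
    if per_batch_api_mass < 0.0:
        raise ValueError("per_batch_api_mass must be non-negative")
    return batches * per_batch_api_mass


def material_demand(spec: FlowsheetSpec, batches: int) -> BatchResult:
    """Scale the per-batch coefficient vectors to an annual campaign."""
    if batches < 0:
        raise ValueError("batches must be non-negative")
    demand = {m: c * batches for m, c in spec.material_coefficients.items()}
    waste = {w: c * batches for w, c in spec.waste_coefficients.items()}
    return BatchResult(
        batches_per_year=batches,
        annual_production=annual_production(batches, spec.per_batch_api_mass),
        annual_material_demand=demand,
        annual_waste=waste,
    )


# The published recipe: procedure id, yield, duration (h), equipment.  Unit
# yields are bookkeeping steps (dissolutions, transfers, neutralizations).
_RECIPE: tuple[tuple[str, float, float, str], ...] = (
    ("P-1/R-101", 0.98, 16.35, "R-101"),   # chlorination of quinaldine
    ("P-2/R-102", 1.00, 17.63, "R-102"),   # condensation with hydroquinone
    ("P-3/NFD-101", 0.90, 4.44, "NFD-101"),  # filtration, solid recovery
    ("P-4/R-101", 1.00, 17.40, "R-101"),   # dissolution in NaOH (Product-Na)
    ("P-5/NFD-101", 0.95, 5.63, "NFD-101"),  # impurity removal
    ("P-6/R-103", 1.00, 15.31, "R-103"),   # neutralization with HCl
    ("P-7/NFD-101", 0.90, 4.00, "NFD-101"),  # API recovery
    ("P-8/R-102", 1.00, 20.17, "R-102"),   # charcoal treatment in isopropanol
    ("P-9/NFD-101", 1.00, 3.51, "NFD-101"),  # charcoal removal
    ("P-10/R-103", 0.97, 13.86, "R-103"),  # crystallization
    ("P-11/NFD-101", 0.99, 2.44, "NFD-101"),  # crystal recovery
    ("P-12/TDR-101", 1.00, 15.54, "TDR-101"),  # drying
)


def default_flowsheet(
    material_coefficients: Mapping[str, float] | None = None,
    waste_coefficients: Mapping[str, float] | None = None,
) -> FlowsheetSpec:
    """The baseline flowsheet; coefficient vectors default to empty maps
    (the economics layer injects its calibrated vectors)."""
    steps = tuple(ReactionStep(*row) for row in _RECIPE)
    return FlowsheetSpec(
        steps=steps,
        material_coefficients=dict(material_coefficients or {}),
        waste_coefficients=dict(waste_coefficients or {}),
    )
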