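"""Monte Carlo scenario generation: the stochastic stage of the assessment.

Each scenario draws the 34 uncertain inputs independently and uniformly
within their bounds (``X_i = X_min + U * (X_max - X_min)``), plus a target
internal rate of return, runs the flowsheet + economics engine, and records
35 features (34 inputs + IRR) and the two computed targets (UPC, MPSP).
The default run emulates the study conditions: 5,000 records.

The IRR column is, by default, a *sampled target rate* at which the MPSP is
solved — the rate is an input the analyst specifies, and the MPSP responds
to it.  An alternative mode computes the achieved IRR at a fixed reference
selling price instead, for studies of the IRR distribution itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .economics import (
    EconomicAssumptions,
    ScenarioInputs,
    ScenarioOutputs,
    build_cash_flow,
    compute_opex,
    compute_upc,
    irr as compute_irr,
    scenario_flows,
    solve_mpsp,
)
from .variables import VARIABLES, VARIABLE_NAMES, Variable

__all__ = [
    "SamplingBounds",
    "ScenarioDataset",
    "FEATURE_COLUMNS",
    "TARGET_COLUMNS",
    "sample_inputs",
    "run_scenario",
    "generate_dataset",
]

logger = logging.getLogger(__name__)

#: The 35 model features: 34 sampled inputs plus the target rate.
FEATURE_COLUMNS: tuple[str, ...] = VARIABLE_NAMES + ("irr",)
#: The two computed targets.
TARGET_COLUMNS: tuple[str, ...] = ("upc", "mpsp")


@dataclass(frozen=True)
class SamplingBounds:
    """Uniform sampling intervals for the inputs and the target-rate range."""

    variables: tuple[Variable, ...] = VARIABLES
    target_irr_range: tuple[float, float] = (0.01, 0.50)

    def __post_init__(self) -> None:
        lo, hi = self.target_irr_range
        if not lo < hi:
            raise ValueError("target_irr_range: low must be < high")
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise ValueError("duplicate variable names in bounds")


@dataclass(frozen=True)
class ScenarioDataset:
    """The generated table: 35 features + 2 targets per scenario."""

    frame: pd.DataFrame
    seed: int

    @property
    def n(self) -> int:
        return len(self.frame)

    def features(self) -> pd.DataFrame:
        return self.frame[list(FEATURE_COLUMNS)]

    def targets(self) -> pd.DataFrame:
        return self.frame[list(TARGET_COLUMNS)]

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, seed: int = -1) -> "ScenarioDataset":
        frame = pd.read_csv(path)
        missing = set(FEATURE_COLUMNS + TARGET_COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"dataset at {path} is missing columns {sorted(missing)}")
        return cls(frame=frame, seed=seed)


def sample_inputs(bounds: SamplingBounds, n: int, seed: int) -> list[ScenarioInputs]:
    """Draw ``n`` independent uniform scenarios within the bounds."""
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(seed)
    draws = _sample_matrix(bounds, n, rng)
    return [ScenarioInputs.from_flat(dict(zip([v.name for v in bounds.variables], row)))
            for row in draws]


def _sample_matrix(bounds: SamplingBounds, n: int, rng: np.random.Generator) -> np.ndarray:
    cols = []
    for v in bounds.variables:
        cols.append(v.lower + rng.random(n) * (v.upper - v.lower))
    return np.column_stack(cols)


def run_scenario(inputs: ScenarioInputs, target_irr: float,
                 assumptions: EconomicAssumptions | None = None,
                 reference_price: float | None = None) -> ScenarioOutputs:
    """Evaluate the economics engine for one scenario.

    With ``reference_price`` unset (the default), the MPSP is solved at the
    given target rate and that rate is recorded as the scenario IRR.  With a
    reference price, the achieved IRR at that price is computed and recorded
    instead.
    """
    assumptions = assumptions or EconomicAssumptions()
    flows = scenario_flows(inputs)
    opex = compute_opex(inputs, flows, assumptions)
    production = flows.annual_production
    upc = compute_upc(opex.total, production)
    mpsp = solve_mpsp(inputs, assumptions, opex, production, target_irr)
    if reference_price is None:
        achieved = target_irr
    else:
        sched = build_cash_flow(inputs, assumptions, opex, production,
                                reference_price)
        achieved = compute_irr(sched)
    return ScenarioOutputs(upc=upc, mpsp=mpsp, irr=achieved,
                           revenue=production * mpsp)


def generate_dataset(bounds: SamplingBounds | None = None, n: int = 5_000,
                     seed: int = 0,
                     assumptions: EconomicAssumptions | None = None) -> ScenarioDataset:
    """Generate the scenario table: ``n`` rows, 37 columns, reproducible for
    a fixed seed.

    Scenarios whose MPSP solve fails are logged and resampled so the row
    count is exact.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    bounds = bounds or SamplingBounds()
    assumptions = assumptions or EconomicAssumptions()
    rng = np.random.default_rng(seed)
    names = [v.name for v in bounds.variables]
    lo_irr, hi_irr = bounds.target_irr_range

    rows: list[dict[str, float]] = []
    while len(rows) < n:
        need = n - len(rows)
        draws = _sample_matrix(bounds, need, rng)
        irr_draws = lo_irr + rng.random(need) * (hi_irr - lo_irr)
        for row, target in zip(draws, irr_draws):
            flat = dict(zip(names, (float(x) for x in row)))
            inputs = ScenarioInputs.from_flat(flat)
            try:
                out = run_scenario(inputs, float(target), assumptions)
            except (ValueError, ZeroDivisionError) as exc:
                logger.warning("scenario skipped and resampled: %s", exc)
                continue
            flat["irr"] = float(target)
            flat["upc"] = out.upc
            flat["mpsp"] = out.mpsp
            rows.append(flat)

    frame = pd.DataFrame(rows, columns=list(FEATURE_COLUMNS + TARGET_COLUMNS))
    return ScenarioDataset(frame=frame, seed=seed)
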