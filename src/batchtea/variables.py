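"""Registry of the 34 uncertain input variables of the assessment.

Each entry carries the baseline value and the uniform sampling bounds used in
the Monte Carlo stage: ten raw-material unit prices (USD/kg), eighteen
waste-stream treatment/disposal unit costs (USD/kg), the operator labor rate
(USD/h), four financial parameters and the annual operating window (h/yr).
Rates (inflation, income tax, loan interest) are stored as fractions.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "Variable",
    "VARIABLES",
    "VARIABLE_NAMES",
    "RAW_MATERIALS",
    "WASTE_STREAMS",
    "by_name",
]


@dataclass(frozen=True)
class Variable:
    name: str
    kind: str  # "raw_material" | "waste" | "labor" | "financial" | "operational"
    units: str
    baseline: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(f"{self.name}: lower bound must be < upper bound")
        if not self.lower <= self.baseline <= self.upper:
            raise ValueError(f"{self.name}: baseline outside bounds")


def _raw(name: str, baseline: float, lo: float, hi: float) -> Variable:
    return Variable(name, "raw_material", "USD/kg", baseline, lo, hi)


def _waste(name: str, baseline: float, lo: float, hi: float) -> Variable:
    return Variable(name, "waste", "USD/kg", baseline, lo, hi)


VARIABLES: tuple[Variable, ...] = (
    # raw-material unit prices
    _raw("quinaldine_cost", 32.0, 16.0, 48.0),
    _raw("isopropanol_cost", 1.1, 0.1, 1.5),
    _raw("nitrogen_cost", 1.0, 0.05, 1.5),
    _raw("sodium_carbonate_cost", 6.5, 3.0, 13.0),
    _raw("hydroquinone_cost", 4.0, 2.0, 10.0),
    _raw("carbon_tetrachloride_cost", 0.8, 0.2, 2.0),
    _raw("chlorine_cost", 3.0, 2.0, 4.0),
    _raw("sodium_hydroxide_cost", 2.0, 0.5, 5.0),
    _raw("process_water_cost", 0.1, 0.01, 1.0),
    _raw("wash_water_cost", 0.1, 0.01, 1.0),
    # waste-stream unit treatment/disposal costs
    _waste("carbon_tetrachloride_waste_cost", 5.0, 4.0, 6.0),
    _waste("carbon_dioxide_waste_cost", 5.0, 4.0, 6.0),
    _waste("isopropanol_waste_cost", 2.0, 1.0, 3.0),
    _waste("sodium_hydroxide_waste_cost", 2.0, 1.0, 3.0),
    _waste("charcoal_waste_cost", 2.0, 1.0, 3.0),
    _waste("quinaldine_waste_cost", 2.0, 1.0, 3.0),
    _waste("chloroquinaldine_waste_cost", 2.0, 1.0, 3.0),
    _waste("product_waste_cost", 2.0, 1.0, 3.0),
    _waste("product_crystal_waste_cost", 2.0, 1.0, 3.0),
    _waste("impurity_waste_cost", 2.0, 1.0, 3.0),
    _waste("product_na_waste_cost", 2.0, 1.0, 3.0),
    _waste("chlorine_waste_cost", 2.0, 1.0, 3.0),
    _waste("hydrochloric_acid_waste_cost", 2.0, 1.0, 3.0),
    _waste("hydroquinone_na_waste_cost", 2.0, 1.0, 3.0),
    _waste("methanol_waste_cost", 2.0, 1.0, 3.0),
    _waste("sodium_carbonate_waste_cost", 2.0, 1.0, 3.0),
    _waste("hydroquinone_waste_cost", 2.0, 1.0, 3.0),
    _waste("sodium_chloride_waste_cost", 2.0, 1.0, 3.0),
    # labor
    Variable("labor_rate", "labor", "USD/h", 41.4, 5.0, 50.0),
    # financial (fractions) and operational
    Variable("inflation", "financial", "fraction/yr", 0.04, 0.01, 0.06),
    Variable("income_tax", "financial", "fraction", 0.40, 0.10, 0.50),
    Variable("loan_interest", "financial", "fraction/yr", 0.09, 0.01, 0.10),
    Variable("loan_period", "financial", "yr", 10.0, 3.0, 12.0),
    Variable("annual_operation_time", "operational", "h/yr", 7920.0, 7200.0, 8760.0),
)

VARIABLE_NAMES: tuple[str, ...] = tuple(v.name for v in VARIABLES)
RAW_MATERIALS: tuple[str, ...] = tuple(v.name for v in VARIABLES if v.kind == "raw_material")
WASTE_STREAMS: tuple[str, ...] = tuple(v.name for v in VARIABLES if v.kind == "waste")

_INDEX = {v.name: v for v in VARIABLES}


def by_name(name: str) -> Variable:
    try:
        return _INDEX[name]
    except KeyError:
        raise KeyError(f"unknown input variable {name!r}") from None
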