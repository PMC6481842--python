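"""Itemized survey-cost ledger with startup/recurring amortization.

Monitoring costs are modelled as line items (unit cost x a product of
multipliers such as trips-per-site and number of sites), classified as
startup (equipment, training) or recurring (fuel, surveyor or technician
time, lab consumables), and amortized per study, per site and per
sample.  An overhead rate applies once, to designated laboratory items
only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["CostItem", "CostLedger", "line_total", "overhead", "amortize",
           "default_ves_ledger", "default_edna_ledger"]


@dataclass(frozen=True)
class CostItem:
    label: str
    unit_cost: float                     # USD
    multipliers: tuple = ()              # ((name, count), ...)
    category: str = "recurring"          # "startup" | "recurring"
    method: str = "ves"                  # "ves" | "edna_field" | "edna_lab"
    overhead_applies: bool = False

    def __post_init__(self) -> None:
        if self.unit_cost < 0:
            raise ValueError("unit_cost must be >= 0")
        if any(count < 0 for _, count in self.multipliers):
            raise ValueError("multiplier counts must be >= 0")
        if self.category not in ("startup", "recurring"):
            raise ValueError(f"unknown category {self.category!r}")


def line_total(item: CostItem) -> float:
    """unit_cost times the product of all multiplier counts."""
    total = item.unit_cost
    for _, count in item.multipliers:
        total *= count
    return total


def overhead(lab_items, rate: float) -> float:
    """rate x sum of line totals of the designated lab items."""
    if rate < 0:
        raise ValueError("overhead rate must be >= 0")
    return rate * sum(line_total(i) for i in lab_items if i.overhead_applies)


@dataclass
class CostLedger:
    """A method's cost lines plus the study design they amortize over."""

    items: list
    n_sites: int
    samples_per_site: int
    overhead_rate: float = 0.0

    def startup_total(self) -> float:
        return sum(line_total(i) for i in self.items if i.category == "startup")

    def recurring_total(self) -> float:
        rec = sum(line_total(i) for i in self.items if i.category == "recurring")
        return rec + overhead(self.items, self.overhead_rate)

    def overhead_total(self) -> float:
        return overhead(self.items, self.overhead_rate)


def amortize(ledger: CostLedger, include_startup: bool = False) -> dict:
    """Per-study / per-site / per-sample totals.

    per_study sums recurring lines (plus overhead on designated lab
    items), plus startup lines when requested; per_site divides by the
    number of sites; per_sample further divides by samples per site.
    """
    if ledger.n_sites <= 0 or ledger.samples_per_site <= 0:
        raise ValueError("design counts must be positive")
    per_study = ledger.recurring_total()
    if include_startup:
        per_study += ledger.startup_total()
    return {
        "per_study": per_study,
        "per_site": per_study / ledger.n_sites,
        "per_sample": per_study / (ledger.n_sites * ledger.samples_per_site),
    }


def default_ves_ledger(n_sites: int = 40, surveys_per_site: int = 2) -> CostLedger:
    """Visual-encounter-survey ledger for a comparable-design study:
    2 one-km surveys at each of 40 sites, equipment and observer
    training as startup."""
    items = [
        CostItem("Equipment: waders, nets, etc.", 740.0, (), "startup", "ves"),
        CostItem("Fuel cost", 55.0,
                 (("surveys_per_site", surveys_per_site), ("sites", n_sites)),
                 "recurring", "ves"),
        CostItem("Survey cost", 220.32,
                 (("surveys_per_site", surveys_per_site), ("sites", n_sites)),
                 "recurring", "ves"),
        CostItem("Training: to develop observers", 6183.2, (), "startup", "ves"),
    ]
    return CostLedger(items, n_sites, surveys_per_site)


def default_edna_ledger(n_sites: int = 40, filters_per_site: int = 6,
                        overhead_rate: float = 0.33) -> CostLedger:
    """eDNA sampling-and-analysis ledger: one collection trip per site,
    six filters per site (4 samples + 2 field blanks), with 33% overhead
    on laboratory supplies and technician time."""
    items = [
        CostItem("Field equipment & supplies", 1983.4, (), "startup", "edna_field"),
        CostItem("Fuel cost", 55.0, (("sites", n_sites),),
                 "recurring", "edna_field"),
        CostItem("Survey cost", 73.44, (("sites", n_sites),),
                 "recurring", "edna_field"),
        CostItem("Training: to develop field techniques", 128.4, (),
                 "startup", "edna_field"),
        CostItem("Laboratory supplies", 2817.2, (), "recurring", "edna_lab",
                 overhead_applies=True),
        CostItem("Laboratory technician time", 1000.3, (), "recurring",
                 "edna_lab", overhead_applies=True),
    ]
    return CostLedger(items, n_sites, filters_per_site, overhead_rate)
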