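"""Unit costs and per-woman cost profiles (2016/17 GBP, NHS perspective).

Unit costs follow the reference-cost convention: the cost of an activity
type is the activity-weighted mean over its constituent Healthcare
Resource Groups (HRGs), and all neonatal admissions share one weighted
cost per bed day. Delivery is costed by mode but always held in a
separate field — bed-day reference costs already embed delivery, so
adding it to the maternal/infant totals would double count.

The packaged table ``unit_costs_synthetic.csv`` is a synthetic stand-in
with realistic magnitudes, not a published schedule; supply your own
CSV (columns ``item,unit,cost_gbp[,activity]``) for real analyses.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .schema import CATEGORIES, CATEGORY_UNITS, DELIVERY_MODES

__all__ = [
    "HRGEntry",
    "UnitCostTable",
    "weighted_unit_cost",
    "cost_profile",
    "CostProfile",
    "load_unit_costs",
]


@dataclass(frozen=True)
class HRGEntry:
    """One Healthcare Resource Group: label, unit cost, episode count."""

    label: str
    unit_cost: float
    activity: float

    def __post_init__(self):
        if self.unit_cost < 0:
            raise ValueError("unit cost must be nonnegative")
        if self.activity < 0:
            raise ValueError("activity must be nonnegative")


def weighted_unit_cost(entries: Sequence[HRGEntry]) -> float:
    """Activity-weighted mean cost: sum(cost*activity) / sum(activity)."""
    total_activity = sum(e.activity for e in entries)
    if total_activity <= 0:
        raise ValueError("total activity must be positive")
    return sum(e.unit_cost * e.activity for e in entries) / total_activity


@dataclass(frozen=True)
class UnitCostTable:
    """Weighted unit costs per resource category and delivery mode."""

    category_costs: Mapping[str, float]
    delivery_costs: Mapping[str, float]
    plgf_test_cost: float = 70.0
    currency_year: str = "2016/17"

    def __post_init__(self):
        missing = set(CATEGORIES) - set(self.category_costs)
        if missing:
            raise ValueError(f"missing unit cost for categories: {sorted(missing)}")
        missing_modes = set(DELIVERY_MODES) - set(self.delivery_costs)
        if missing_modes:
            raise ValueError(f"missing delivery cost for modes: {sorted(missing_modes)}")
        for name, cost in list(self.category_costs.items()) + list(
            self.delivery_costs.items()
        ):
            if cost < 0:
                raise ValueError(f"negative unit cost for {name}")
        if self.plgf_test_cost < 0:
            raise ValueError("negative PlGF test cost")

    def replace_test_cost(self, cost: float) -> "UnitCostTable":
        return UnitCostTable(
            self.category_costs, self.delivery_costs, float(cost), self.currency_year
        )


def load_unit_costs(path=None, currency_year: str = "2016/17") -> UnitCostTable:
    """Read a unit-cost CSV; ``None`` loads the packaged synthetic table.

    Rows whose item carries an ``activity`` represent HRG-level entries
    sharing the item label; they are collapsed with
    :func:`weighted_unit_cost` before lookup.
    """
    if path is None:
        ref = importlib.resources.files("plgfcea.data").joinpath(
            "unit_costs_synthetic.csv"
        )
        with ref.open("r") as fh:
            df = pd.read_csv(fh)
    else:
        df = pd.read_csv(path)
    required = {"item", "unit", "cost_gbp"}
    if not required <= set(df.columns):
        raise ValueError(f"unit-cost file needs columns {sorted(required)}")

    def collapse(sub: pd.DataFrame) -> float:
        if "activity" in sub.columns and sub["activity"].notna().any():
            entries = [
                HRGEntry(str(r["item"]), float(r["cost_gbp"]), float(r["activity"]))
                for _, r in sub.iterrows()
                if pd.notna(r.get("activity"))
            ]
            return weighted_unit_cost(entries)
        if len(sub) != 1:
            raise ValueError(
                f"multiple rows for item {sub['item'].iloc[0]!r} without activity"
            )
        return float(sub["cost_gbp"].iloc[0])

    costs = {item: collapse(sub) for item, sub in df.groupby("item", sort=False)}
    category_costs = {c: costs[c] for c in CATEGORIES if c in costs}
    delivery_costs = {
        m: costs[f"delivery_{m}"] for m in DELIVERY_MODES if f"delivery_{m}" in costs
    }
    test = float(costs.get("plgf_test", 70.0))
    return UnitCostTable(category_costs, delivery_costs, test, currency_year)


@dataclass(frozen=True)
class CostProfile:
    """Costed resource use for one woman; delivery is kept out of totals."""

    categories: Mapping[str, float]
    delivery: float
    currency_year: str

    def total(self, include_delivery: bool = False) -> float:
        t = sum(self.categories.values())
        return t + self.delivery if include_delivery else t


def cost_profile(
    resource_use: Mapping[str, float],
    table: UnitCostTable,
    delivery_mode: str | None = None,
) -> CostProfile:
    """Cost a resource-use map: quantity x weighted unit cost per category.

    The delivery cost (by mode) is computed but stored separately so it
    can never leak into the maternal/infant totals.
    """
    costs = {}
    for category, quantity in resource_use.items():
        if category not in table.category_costs:
            raise ValueError(f"no unit cost for category {category!r}")
        if quantity < 0:
            raise ValueError(f"negative quantity for {category!r}")
        costs[category] = float(quantity) * table.category_costs[category]
    delivery = 0.0
    if delivery_mode is not None:
        if delivery_mode not in table.delivery_costs:
            raise ValueError(f"no unit cost for delivery mode {delivery_mode!r}")
        delivery = table.delivery_costs[delivery_mode]
    return CostProfile(costs, delivery, table.currency_year)
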