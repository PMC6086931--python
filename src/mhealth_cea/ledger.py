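"""Ingredients-based cost ledger: itemized program expenditures by
category, phase and program year, with exact-decimal aggregation and
integer-percent share reporting.

The ledger mirrors how mHealth program cost tables are laid out: two
top-level categories (implementation support vs. technology), subcategory
rows, and one column per program year.  Capital items (useful life
> 1 year, or one-time development/start-up activities amortized over the
project lifetime) are stored already annualized; annualization of raw
outlays is done with :func:`mhealth_cea.money.annualize_capital`.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from decimal import Decimal
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence, Union

import pandas as pd

from .money import round_half_up, to_decimal

PROGRAM_YEARS = (1, 2, 3, 4, 5)

Category = Literal["implementation", "technology"]

#: Sentinel for capital items amortized over the whole project lifetime.
PROJECT_LIFETIME = "project-lifetime"


@dataclass
class CostItem:
    """One ledger row: a named expenditure with amounts per program year.

    ``useful_life_years`` is required for capital items; the string
    ``"project-lifetime"`` means the item is amortized over the project's
    5-year horizon.
    """

    name: str
    category: Category
    subcategory: str
    is_capital: bool = False
    useful_life_years: Union[int, str, None] = None
    annual_amounts: dict[int, Decimal] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.category not in ("implementation", "technology"):
            raise ValueError(f"unknown category {self.category!r}")
        bad = set(self.annual_amounts) - set(PROGRAM_YEARS)
        if bad:
            raise ValueError(f"annual_amounts keys outside program years 1-5: {bad}")
        self.annual_amounts = {y: to_decimal(v) for y, v in self.annual_amounts.items()}
        if any(v < 0 for v in self.annual_amounts.values()):
            raise ValueError(f"negative amount in item {self.name!r}")
        if self.is_capital and self.useful_life_years is None:
            raise ValueError(f"capital item {self.name!r} must carry a useful life")
        if isinstance(self.useful_life_years, int) and self.useful_life_years < 1:
            raise ValueError("useful_life_years must be a positive integer")

    def amount(self, year: int) -> Decimal:
        return self.annual_amounts.get(year, Decimal("0.00"))

    @property
    def total(self) -> Decimal:
        return sum(self.annual_amounts.values(), Decimal("0.00"))


@dataclass
class CostLedger:
    """An ordered collection of :class:`CostItem` rows with a discount rate."""

    items: list[CostItem] = field(default_factory=list)
    discount_rate: float = 0.03

    def __iter__(self):
        return iter(self.items)

    def __len__(self) -> int:
        return len(self.items)

    def total_by_year(self) -> dict[int, Decimal]:
        return {
            y: sum((it.amount(y) for it in self.items), Decimal("0.00"))
            for y in PROGRAM_YEARS
        }

    def subtotal(self, category: str, year: Optional[int] = None) -> Decimal:
        """Exact sum over the items of one category (one year or all years)."""
        rows = [it for it in self.items if it.category == category]
        if year is not None:
            return sum((it.amount(year) for it in rows), Decimal("0.00"))
        return sum((it.total for it in rows), Decimal("0.00"))

    @property
    def grand_total(self) -> Decimal:
        return sum((it.total for it in self.items), Decimal("0.00"))


def aggregate_ledger(
    ledger: CostLedger, by: Literal["year", "category", "subcategory"] = "category"
) -> pd.DataFrame:
    """Aggregate a ledger into totals and percentage-of-grand-total shares.

    Returns a DataFrame with columns ``total`` (exact Decimal sums,
    reported as float), ``share`` (unrounded fraction of the grand total)
    and ``share_pct`` (integer percent, round half-up — the convention of
    printed cost tables).  An empty ledger yields zero totals and NaN
    shares (flagged, not raised).
    """
    if by == "year":
        groups = {f"y{y}": v for y, v in ledger.total_by_year().items()}
    elif by == "category":
        groups = {
            cat: ledger.subtotal(cat) for cat in ("implementation", "technology")
        }
    elif by == "subcategory":
        groups = {}
        for it in ledger.items:
            key = (it.category, it.subcategory)
            groups[key] = groups.get(key, Decimal("0.00")) + it.total
    else:
        raise ValueError(f"unknown grouping {by!r}")

    grand = ledger.grand_total
    rows = []
    for key, total in groups.items():
        if grand > 0:
            share = float(total / grand)
            pct = int(round_half_up(100 * float(total) / float(grand)))
        else:
            share, pct = float("nan"), -1  # undefined, flagged
        rows.append({"group": key, "total": float(total), "share": share, "share_pct": pct})
    df = pd.DataFrame(rows).set_index("group")
    df.attrs["grand_total"] = float(grand)
    return df


#: Subcategory labels that make up combined personnel costs: program
#: support staff (implementation) and technology project management.
PERSONNEL_SUBCATEGORIES = (
    ("implementation", "Personnel"),
    ("technology", "Project management/personnel"),
)


def personnel_share(ledger: CostLedger) -> tuple[int, float]:
    """Combined personnel share of the grand total.

    Sums the implementation personnel and technology project-management
    subcategories and divides by the ledger grand total.  Returns
    ``(integer_percent, unrounded_fraction)``.  Raises if either personnel
    subcategory is absent, naming the missing one.
    """
    total = Decimal("0.00")
    for cat, sub in PERSONNEL_SUBCATEGORIES:
        rows = [
            it for it in ledger.items if it.category == cat and it.subcategory == sub
        ]
        if not rows:
            raise ValueError(f"ledger is missing personnel subcategory {cat}/{sub!r}")
        total += sum((it.total for it in rows), Decimal("0.00"))
    grand = ledger.grand_total
    if grand == 0:
        raise ValueError("cannot compute shares on an empty ledger")
    frac = float(total / grand)
    return int(round_half_up(100 * frac)), frac


# ---------------------------------------------------------------------------
# CSV interface: columns name, category, subcategory, is_capital,
# useful_life_years, y1..y5 (USD, base-year prices)

_CSV_FIELDS = [
    "name",
    "category",
    "subcategory",
    "is_capital",
    "useful_life_years",
    "y1",
    "y2",
    "y3",
    "y4",
    "y5",
]


def write_ledger_csv(ledger: CostLedger, path: Union[str, Path]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=_CSV_FIELDS)
        w.writeheader()
        for it in ledger.items:
            row = {
                "name": it.name,
                "category": it.category,
                "subcategory": it.subcategory,
                "is_capital": str(it.is_capital).lower(),
                "useful_life_years": "" if it.useful_life_years is None else it.useful_life_years,
            }
            for y in PROGRAM_YEARS:
                row[f"y{y}"] = str(it.amount(y))
            w.writerow(row)


def read_ledger_csv(path: Union[str, Path], discount_rate: float = 0.03) -> CostLedger:
    items = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            life: Union[int, str, None]
            raw = (row.get("useful_life_years") or "").strip()
            if not raw:
                life = None
            elif raw == PROJECT_LIFETIME:
                life = PROJECT_LIFETIME
            else:
                life = int(raw)
            items.append(
                CostItem(
                    name=row["name"],
                    category=row["category"],  # type: ignore[arg-type]
                    subcategory=row["subcategory"],
                    is_capital=row["is_capital"].strip().lower() in ("true", "1", "yes"),
                    useful_life_years=life,
                    annual_amounts={
                        y: to_decimal(row[f"y{y}"])
                        for y in PROGRAM_YEARS
                        if row.get(f"y{y}", "").strip()
                    },
                )
            )
    return CostLedger(items=items, discount_rate=discount_rate)


def format_ledger_table(ledger: CostLedger) -> str:
    """Human-readable table mirroring the printed cost-table layout."""
    lines = []
    header = f"{'Item':38s}" + "".join(f"{'Y' + str(y):>13s}" for y in PROGRAM_YEARS) + f"{'Total':>14s}"
    lines.append(header)
    lines.append("-" * len(header))
    grand = ledger.grand_total
    for cat in ("implementation", "technology"):
        lines.append(f"{cat.capitalize()}:")
        for it in ledger.items:
            if it.category != cat:
                continue
            cells = "".join(f"{float(it.amount(y)):13,.2f}" for y in PROGRAM_YEARS)
            lines.append(f"  {it.name:36s}{cells}{float(it.total):14,.2f}")
        sub = ledger.subtotal(cat)
        pct = int(round_half_up(100 * float(sub) / float(grand))) if grand else 0
        cells = "".join(
            f"{float(ledger.subtotal(cat, y)):13,.2f}" for y in PROGRAM_YEARS
        )
        lines.append(f"  {'Subtotal ' + cat + f' ({pct}%)':36s}{cells}{float(sub):14,.2f}")
    by_year = ledger.total_by_year()
    cells = "".join(f"{float(by_year[y]):13,.2f}" for y in PROGRAM_YEARS)
    lines.append(f"{'Total':38s}{cells}{float(grand):14,.2f}")
    return "\n".join(lines)
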