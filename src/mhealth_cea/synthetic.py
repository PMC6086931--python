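"""Synthetic study data with known ground truth.

The original study's raw data (cost workbooks, exit-interview records,
and the per-year PSA input appendices) are not deposited, so this module
generates everything the pipeline needs:

* the published 5-year program cost table, row for row (a fixture, not
  simulated);
* per-year PSA parameter tables seeded from the published point
  estimates and ranges;
* monthly enrollment series consistent with the published annual totals;
* individual-level utilization records drawn from a known
  :class:`ScenarioTruth`, for parameter-recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import Decimal
from typing import Optional

import numpy as np
import pandas as pd

from .effects import LivesSavedParameter
from .enrollment import EnrollmentSeries, series_from_annual_total
from .ledger import CostItem, CostLedger
from .uncertainty import ParameterSpec

# ---------------------------------------------------------------------------
# Published 5-year cost table (2015 USD), stored verbatim at item level.
# Each row: (name, subcategory, is_capital, life, [y1..y5]).
# Development and start-up are one-time activities amortized over the
# 5-year project lifetime; their rows are already annualized.

_IMPLEMENTATION_ROWS = [
    ("Development", "Development", True, "project-lifetime",
     ["37353.42", "38474.03", "39628.25", "39628.25", "42041.61"]),
    ("Start-up", "Start-up", True, "project-lifetime",
     ["17765.76", "18298.74", "18847.70", "18847.70", "19995.52"]),
    ("Training", "Training", False, None,
     ["149.73", "0", "73.86", "0", "80.51"]),
    ("Personnel", "Personnel", False, None,
     ["18375.80", "18798.00", "19630.41", "20514.67", "21398.94"]),
    ("Buildings", "Buildings", False, None,
     ["5974.80", "5644.53", "5894.48", "6160.00", "6425.52"]),
    ("Transport", "Transport", False, None,
     ["3223.16", "3044.99", "3179.83", "3323.06", "3466.30"]),
    ("Communication", "Communication", False, None,
     ["537.19", "507.50", "529.97", "553.84", "577.72"]),
]

_TECHNOLOGY_ROWS = [
    ("Start-up/development", "Start-up/development", True, "project-lifetime",
     ["129.89", "129.89", "137.03", "144.08", "158.74"]),
    ("Content maintenance", "Content maintenance", False, None,
     ["10478.75", "12876.98", "9167.21", "9442.22", "9725.49"]),
    ("Technology maintenance", "Technology maintenance", False, None,
     ["8279.94", "36864.04", "18509.92", "19333.07", "20156.87"]),
    ("Project management/personnel", "Project management/personnel", False, None,
     ["25697.90", "30970.64", "15588.69", "16625.15", "17709.78"]),
    ("Monitoring and evaluation", "Monitoring and evaluation", False, None,
     ["1842.36", "1961.43", "108.72", "111.99", "115.34"]),
    ("Building/overhead", "Building/overhead", False, None,
     ["10073.21", "13088.45", "12225.42", "12765.21", "13305.66"]),
    ("Travel", "Travel", False, None,
     ["11353.19", "8606.91", "3100.02", "3237.30", "3374.71"]),
    ("SMS text message delivery", "SMS delivery", False, None,
     ["5384.11", "9857.96", "23233.68", "75421.98", "246909.46"]),
    ("SMS text message translation", "SMS translation", False, None,
     ["1736.80", "1855.87", "1855.87", "1855.87", "1855.87"]),
    ("Printing", "Printing", False, None,
     ["4726.26", "0", "0", "0", "0"]),
]

#: Aggregate rows as printed in the source table.  The published table is
#: internally inconsistent in program year 3: the printed implementation
#: subtotal (86,081.31) falls 1,703.19 short of the sum of its printed
#: items.  The printed aggregate rows are self-consistent across years,
#: so they are kept alongside the items as the reference aggregates.
PRINTED_ANNUAL_TOTALS = {
    1: Decimal("163082.27"), 2: Decimal("200979.94"), 3: Decimal("170007.86"),
    4: Decimal("227964.40"), 5: Decimal("407298.04"),
}
PRINTED_SUBTOTALS = {
    "implementation": {
        1: Decimal("83379.87"), 2: Decimal("84767.78"), 3: Decimal("86081.31"),
        4: Decimal("89027.53"), 5: Decimal("93986.12"),
    },
    "technology": {
        1: Decimal("79702.40"), 2: Decimal("116212.16"), 3: Decimal("83926.55"),
        4: Decimal("138936.88"), 5: Decimal("313311.93"),
    },
}
PRINTED_GRAND_TOTAL = Decimal("1169332.51")
PRINTED_TECHNOLOGY_TOTAL = Decimal("732089.92")


def generate_cost_ledger(discount_rate: float = 0.03) -> CostLedger:
    """The published program cost table as a :class:`CostLedger`,
    item values verbatim."""
    items = []
    for cat, rows in (("implementation", _IMPLEMENTATION_ROWS),
                      ("technology", _TECHNOLOGY_ROWS)):
        for name, sub, capital, life, amounts in rows:
            items.append(
                CostItem(
                    name=name, category=cat, subcategory=sub,
                    is_capital=capital, useful_life_years=life,
                    annual_amounts={y + 1: Decimal(a) for y, a in enumerate(amounts)},
                )
            )
    return CostLedger(items=items, discount_rate=discount_rate)


# ---------------------------------------------------------------------------
# Published per-year scale-up quantities

#: Registered users per program year (years 1-2 observed, 3-5 forecast).
USERS_BY_YEAR = {1: 2879, 2: 8161, 3: 18419, 4: 57214, 5: 179562}

#: SMS delivery cost per program year (from the cost table).
SMS_DELIVERY_BY_YEAR = {
    1: 5384.11, 2: 9857.96, 3: 23233.68, 4: 75421.98, 5: 246909.46
}

#: Published lives-saved estimate for the year-5 reference scenario.
YEAR5_LIVES = LivesSavedParameter(
    point=182.0, low=109.0, high=199.0,
    reference_year=5, reference_users=179_562, reference_delta_cc=0.28,
)

#: Year-5 arm utilization proportions (intervention vs. comparison) and
#: the analyzed case-control sample sizes behind them.
YEAR5_UTILIZATION = {
    "p_anc4_int": 0.72, "p_anc4_comp": 0.46,
    "p_imm_int": 0.95, "p_imm_comp": 0.90,
    "p_cc_int": 0.67, "p_cc_comp": 0.39,
}
CASE_CONTROL_N = {"intervention": 87, "comparison": 90}

#: Exit-interview sample size behind the mean user visit costs.
USER_COST_INTERVIEW_N = 177
USER_COST_CV = 0.5

_UNIT_COST_POINTS = {
    "cost_registration": 0.08,
    "cost_anc_first": 1.28,
    "cost_anc_later": 1.03,
    "cost_pnc_first": 1.03,
    "cost_pnc_later": 0.51,
    "cost_user_anc": 1.66,
    "cost_user_pnc": 1.48,
}


@dataclass
class ScenarioTruth:
    """Ground-truth parameter values behind a generated dataset."""

    year: int
    seed: int
    users: float
    proportions: dict[str, float]
    unit_costs: dict[str, float]
    lives: LivesSavedParameter
    monthly_growth: float = 0.10

    def __post_init__(self) -> None:
        for arm in ("int", "comp"):
            p4 = self.proportions[f"p_anc4_{arm}"]
            pi = self.proportions[f"p_imm_{arm}"]
            pc = self.proportions[f"p_cc_{arm}"]
            if pc > min(p4, pi) + 1e-12:
                raise ValueError("comprehensive care exceeds a component coverage")
            if p4 + pi - pc > 1 + 1e-12:
                raise ValueError(
                    "marginals are not jointly attainable with cc = anc4 AND imm"
                )


def _se(p: float, n: int) -> float:
    return math.sqrt(p * (1 - p) / n)


def generate_parameter_table(
    year: int = 5, seed: int = 0
) -> tuple[list[ParameterSpec], ScenarioTruth]:
    """PSA parameter table for one program year, seeded from the
    published point estimates and ranges.

    Coverage proportions and unit costs are common to all years; the
    registered-user count follows the published enrollment trajectory,
    and the lives-saved parameter and SMS delivery cost scale with it.
    One-way ranges: printed ranges where published (registration cost,
    lives saved); +/- 1 binomial SE at the case-control sample sizes for
    proportions; +/- 1.96 sd for cost parameters (sd = 25% of the point
    for program/provider costs, the standard error of the interview mean
    for user visit costs).
    """
    if year not in USERS_BY_YEAR:
        raise ValueError(f"unknown scenario year {year}; expected 1-5")
    users = float(USERS_BY_YEAR[year])
    scale = users / YEAR5_LIVES.reference_users
    lives = LivesSavedParameter(
        point=YEAR5_LIVES.point * scale,
        low=YEAR5_LIVES.low * scale,
        high=YEAR5_LIVES.high * scale,
        reference_year=year,
        reference_users=users,
        reference_delta_cc=YEAR5_LIVES.reference_delta_cc,
    )
    sms = SMS_DELIVERY_BY_YEAR[year]
    program_other = float(PRINTED_ANNUAL_TOTALS[year]) - sms

    specs = [ParameterSpec("users", users, users, users, "fixed")]
    for name, p in YEAR5_UTILIZATION.items():
        n = CASE_CONTROL_N["intervention" if name.endswith("_int") else "comparison"]
        se = _se(p, n)
        specs.append(
            ParameterSpec(name, p, max(0.0, p - se), min(1.0, p + se), "beta",
                          effective_n=n)
        )
    specs.append(
        ParameterSpec("lives_saved", lives.point, lives.low, lives.high, "pert")
    )
    reg = _UNIT_COST_POINTS["cost_registration"]
    specs.append(
        ParameterSpec("cost_registration", reg, 0.04, 0.11, "gamma")
    )
    for name in ("cost_anc_first", "cost_anc_later", "cost_pnc_first", "cost_pnc_later"):
        point = _UNIT_COST_POINTS[name]
        sd = 0.25 * point
        specs.append(
            ParameterSpec(name, point, max(0.0, point - 1.96 * sd), point + 1.96 * sd,
                          "gamma", sd=sd)
        )
    for name in ("cost_user_anc", "cost_user_pnc"):
        point = _UNIT_COST_POINTS[name]
        sd = point * USER_COST_CV / math.sqrt(USER_COST_INTERVIEW_N)
        specs.append(
            ParameterSpec(name, point, point - 1.96 * sd, point + 1.96 * sd,
                          "gamma", sd=sd)
        )
    for name, point in (("cost_sms_delivery", sms), ("cost_program_other", program_other)):
        sd = 0.25 * point
        specs.append(
            ParameterSpec(name, point, max(0.0, point - 1.96 * sd), point + 1.96 * sd,
                          "gamma", sd=sd)
        )

    truth = ScenarioTruth(
        year=year, seed=seed, users=users,
        proportions=dict(YEAR5_UTILIZATION),
        unit_costs=dict(_UNIT_COST_POINTS),
        lives=lives,
    )
    return specs, truth


def parameter_table_frame(specs: list[ParameterSpec]) -> pd.DataFrame:
    """Parameter table as a DataFrame (the CSV interchange shape)."""
    return pd.DataFrame(
        [
            {
                "name": s.name, "point": s.point, "low": s.low, "high": s.high,
                "family": s.family, "effective_n": s.effective_n, "sd": s.sd,
            }
            for s in specs
        ]
    )


def specs_from_frame(df: pd.DataFrame) -> list[ParameterSpec]:
    specs = []
    for row in df.to_dict("records"):
        eff = row.get("effective_n")
        sd = row.get("sd")
        specs.append(
            ParameterSpec(
                str(row["name"]), float(row["point"]), float(row["low"]),
                float(row["high"]), str(row["family"]),
                effective_n=None if pd.isna(eff) else float(eff),
                sd=None if sd is None or pd.isna(sd) else float(sd),
            )
        )
    return specs


# ---------------------------------------------------------------------------
# Enrollment fixtures

def generate_enrollment_series(years: int = 2, growth: float = 0.10) -> EnrollmentSeries:
    """Observed monthly enrollment for the first program years, with
    geometric within-year shape consistent with the published annual
    totals (the published monthly breakdown is graphical only)."""
    counts: list[int] = []
    levels: list[float] = []
    for y in range(1, years + 1):
        s = series_from_annual_total(USERS_BY_YEAR[y], growth)
        counts.extend(s.monthly_counts)
        levels.extend(s._levels)  # keep unrounded state contiguous
    return EnrollmentSeries(
        monthly_counts=counts, status=["observed"] * len(counts),
        start_month="2012-07", _levels=levels,
    )


# ---------------------------------------------------------------------------
# Individual-level records

def generate_individual_records(
    n_per_arm: int, truth: ScenarioTruth, seed: int = 0
) -> pd.DataFrame:
    """Per-woman utilization records drawn from a known truth.

    Joint construction: the comprehensive-care flag is drawn first
    (cc => anc4 and full immunization); conditional on not-cc, the woman
    falls in exactly one of {anc4 only, immunized only, neither} with
    probabilities chosen so the marginals match the truth.  Requires
    ``p_anc4 + p_imm - p_cc <= 1``.  User visit costs are lognormal
    around the truth means with coefficient of variation 0.5
    (interview-reported costs are right-skewed).
    """
    if n_per_arm < 1:
        raise ValueError("n_per_arm must be >= 1")
    rng = np.random.default_rng(seed)
    frames = []
    for arm, suffix in (("intervention", "int"), ("comparison", "comp")):
        p4 = truth.proportions[f"p_anc4_{suffix}"]
        pi = truth.proportions[f"p_imm_{suffix}"]
        pc = truth.proportions[f"p_cc_{suffix}"]
        cc = rng.random(n_per_arm) < pc
        anc4 = cc.copy()
        imm = cc.copy()
        not_cc = ~cc
        n_rest = int(not_cc.sum())
        if n_rest and pc < 1:
            rest = 1.0 - pc
            probs = np.array([
                max(0.0, p4 - pc) / rest,          # anc4 only
                max(0.0, pi - pc) / rest,          # immunized only
            ])
            probs = np.append(probs, max(0.0, 1.0 - probs.sum()))  # neither
            cells = rng.choice(3, size=n_rest, p=probs / probs.sum())
            anc4[not_cc] = cells == 0
            imm[not_cc] = cells == 1
        anc_visits = np.where(anc4, 4, rng.integers(0, 4, n_per_arm))
        sigma = math.sqrt(math.log(1 + USER_COST_CV**2))

        def lognormal(mean: float, size: int) -> np.ndarray:
            mu = math.log(mean) - sigma**2 / 2
            return rng.lognormal(mu, sigma, size)

        frames.append(
            pd.DataFrame(
                {
                    "arm": arm,
                    "anc_visits": anc_visits,
                    "anc4": anc4,
                    "immunizations_complete": imm,
                    "cc_flag": cc,
                    "user_cost_anc_visit": lognormal(
                        truth.unit_costs["cost_user_anc"], n_per_arm),
                    "user_cost_pnc_visit": lognormal(
                        truth.unit_costs["cost_user_pnc"], n_per_arm),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
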