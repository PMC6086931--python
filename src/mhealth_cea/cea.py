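"""Deterministic cost-effectiveness engine: provider and user visit
costs, incremental costs by perspective, ICERs with dominance
classification, and willingness-to-pay threshold classification.

Perspectives follow the societal-costing convention: the societal cost
is the sum of program (funder), health-system (provider time) and user
(out-of-pocket plus wages lost) costs.  The comparator is the status
quo, which bears no program or registration costs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

from .effects import ArmUtilization

Dominance = Literal["normal", "dominant", "dominated", "undefined", "cost-neutral"]

WTPClass = Literal["highly cost-effective", "cost-effective", "not cost-effective"]


@dataclass(frozen=True)
class UnitCosts:
    """Provider and user unit costs per registration and per visit (USD,
    base-year prices).

    Provider visit costs distinguish the first visit (which includes
    registration/counselling overhead) from subsequent visits.  User
    costs per visit are the sum of wages lost, transport, child care and
    food.  ``partial_anc_visits`` / ``partial_pnc_visits`` set how many
    visits a woman *not* completing the full schedule attends in the
    incremental cost model (default 0: a coverage converter gains the
    full schedule).
    """

    registration_provider: float = 0.08
    registration_range: tuple[float, float] = (0.04, 0.11)
    anc_visit_first: float = 1.28
    anc_visit_subsequent: float = 1.03
    pnc_visit_first: float = 1.03
    pnc_visit_subsequent: float = 0.51
    user_anc_visit: float = 1.66
    user_pnc_visit: float = 1.48
    n_anc_visits: int = 4
    n_pnc_visits: int = 6
    partial_anc_visits: int = 0
    partial_pnc_visits: int = 0

    def __post_init__(self) -> None:
        for name in (
            "registration_provider",
            "anc_visit_first",
            "anc_visit_subsequent",
            "pnc_visit_first",
            "pnc_visit_subsequent",
            "user_anc_visit",
            "user_pnc_visit",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.n_anc_visits < 1 or self.n_pnc_visits < 1:
            raise ValueError("visit schedules must contain at least one visit")


@dataclass(frozen=True)
class PerspectiveCosts:
    """Incremental annual costs by perspective; societal is their sum."""

    program: float
    health_system: float
    user: float

    @property
    def societal(self) -> float:
        return self.program + self.health_system + self.user


@dataclass(frozen=True)
class ICERResult:
    """An incremental cost-effectiveness ratio with dominance flag.

    ``icer`` is ``delta_cost / delta_effect`` when defined; ``dominant``
    means lower cost and better effect (negative ICER reported but the
    intervention simply wins); ``dominated`` the reverse.
    """

    delta_cost: float
    delta_effect: float
    icer: Optional[float]
    perspective: str = "societal"
    dominance: Dominance = "normal"


def provider_schedule_cost(
    unit_costs: UnitCosts,
    schedule: Literal["anc_full", "pnc_full", "registration"],
) -> float:
    """Provider cost per woman of completing a full visit schedule
    (first visit plus ``n - 1`` subsequent visits), or of registration."""
    if schedule == "registration":
        return unit_costs.registration_provider
    if schedule == "anc_full":
        return (
            unit_costs.anc_visit_first
            + (unit_costs.n_anc_visits - 1) * unit_costs.anc_visit_subsequent
        )
    if schedule == "pnc_full":
        return (
            unit_costs.pnc_visit_first
            + (unit_costs.n_pnc_visits - 1) * unit_costs.pnc_visit_subsequent
        )
    raise ValueError(f"unknown schedule {schedule!r}")


def user_visit_cost(
    wages: float, transport: float, childcare: float, food: float
) -> tuple[float, Optional[dict[str, float]]]:
    """Total user cost per visit and component shares.

    Shares are ``None`` (flagged undefined) when the total is zero."""
    components = {"wages": wages, "transport": transport, "childcare": childcare, "food": food}
    for name, v in components.items():
        if v < 0:
            raise ValueError(f"negative user cost component {name}")
    total = sum(components.values())
    if total == 0:
        return 0.0, None
    return total, {k: v / total for k, v in components.items()}


def _expected_schedule_costs(
    p_full: float, full_cost_first: float, full_cost_sub: float,
    n_full: int, n_partial: int,
) -> tuple[float, float]:
    """Expected (provider visits, provider cost) per woman given the
    probability of completing the full schedule; partial attenders take
    ``n_partial`` visits (0 means they contribute nothing)."""
    def visits_cost(n: int) -> tuple[float, float]:
        if n <= 0:
            return 0.0, 0.0
        return float(n), full_cost_first + (n - 1) * full_cost_sub

    v_full, c_full = visits_cost(n_full)
    v_part, c_part = visits_cost(n_partial)
    visits = p_full * v_full + (1 - p_full) * v_part
    cost = p_full * c_full + (1 - p_full) * c_part
    return visits, cost


def incremental_cost_by_perspective(
    program_annual: float,
    intervention: ArmUtilization,
    comparison: ArmUtilization,
    users: float,
    unit_costs: UnitCosts = UnitCosts(),
) -> PerspectiveCosts:
    """Incremental annual costs (intervention minus status quo) for a
    registered population of ``users`` women.

    Health-system delta: registration cost for every registered user
    (the comparator registers nobody) plus the difference in expected
    provider visit costs implied by each arm's coverage of the full
    antenatal schedule and (via full-immunization coverage, whose visit
    schedule coincides with postnatal visits) the postnatal schedule.
    User delta: difference in expected visits times user cost per visit.
    Program delta: the full program cost (the comparator has none).
    """
    if intervention.arm == comparison.arm:
        raise ValueError("intervention and comparison must be different arms")
    uc = unit_costs

    anc_v_i, anc_c_i = _expected_schedule_costs(
        intervention.p_anc4, uc.anc_visit_first, uc.anc_visit_subsequent,
        uc.n_anc_visits, uc.partial_anc_visits)
    anc_v_c, anc_c_c = _expected_schedule_costs(
        comparison.p_anc4, uc.anc_visit_first, uc.anc_visit_subsequent,
        uc.n_anc_visits, uc.partial_anc_visits)
    pnc_v_i, pnc_c_i = _expected_schedule_costs(
        intervention.p_full_imm, uc.pnc_visit_first, uc.pnc_visit_subsequent,
        uc.n_pnc_visits, uc.partial_pnc_visits)
    pnc_v_c, pnc_c_c = _expected_schedule_costs(
        comparison.p_full_imm, uc.pnc_visit_first, uc.pnc_visit_subsequent,
        uc.n_pnc_visits, uc.partial_pnc_visits)

    health_system = users * (
        uc.registration_provider + (anc_c_i - anc_c_c) + (pnc_c_i - pnc_c_c)
    )
    user = users * (
        (anc_v_i - anc_v_c) * uc.user_anc_visit
        + (pnc_v_i - pnc_v_c) * uc.user_pnc_visit
    )
    return PerspectiveCosts(program=program_annual, health_system=health_system, user=user)


def icer(
    delta_cost: float, delta_effect: float, perspective: str = "societal"
) -> ICERResult:
    """ICER with dominance classification; never divides by zero."""
    if delta_effect == 0:
        return ICERResult(delta_cost, delta_effect, None, perspective, "undefined")
    ratio = delta_cost / delta_effect
    if delta_cost < 0 and delta_effect > 0:
        dom: Dominance = "dominant"
    elif delta_cost > 0 and delta_effect < 0:
        dom = "dominated"
    elif delta_cost == 0 and delta_effect > 0:
        dom = "cost-neutral"
    else:
        dom = "normal"
    return ICERResult(delta_cost, delta_effect, ratio, perspective, dom)


def classify_wtp(icer_value: float, gni_per_capita: float) -> WTPClass:
    """Classify a cost-per-DALY ICER against income-based thresholds:
    highly cost-effective at or below 1x per-capita income, cost-effective
    at or below 3x, otherwise not cost-effective.  A negative ICER from a
    dominant intervention classifies as highly cost-effective."""
    if gni_per_capita <= 0:
        raise ValueError("threshold income must be positive")
    if icer_value <= gni_per_capita:
        return "highly cost-effective"
    if icer_value <= 3 * gni_per_capita:
        return "cost-effective"
    return "not cost-effective"
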