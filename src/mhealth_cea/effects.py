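"""Health effects: incremental service utilization, a calibrated
lives-saved proxy, and DALY conversion.

Deaths averted are translated into disability-adjusted life years (here
purely years of life lost) by discounting the residual life expectancy
``L`` at rate ``r`` with no age weighting:

* continuous discounting:  ``(1 - exp(-r L)) / r``
* discrete (annual) discounting:  ``sum_{t=1..L} (1+r)^{-t} = (1 - (1+r)^{-L}) / r``

Both reduce to ``L`` as ``r -> 0``.

The external cause-of-death model that maps coverage changes to deaths
averted is replaced by a linear proxy: lives saved are proportional to
the number of additional comprehensive-care users (coverage delta times
registered users), with the proportionality coefficient calibrated to a
reference scenario's published output and its uncertainty range scaling
proportionally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal


@dataclass(frozen=True)
class ArmUtilization:
    """Per-arm service-coverage proportions with the sample (or
    population) size they were estimated from.

    ``p_comprehensive`` is the proportion receiving comprehensive care
    (at least 4 antenatal visits *and* full childhood immunization), so
    it can exceed neither marginal.
    """

    arm: Literal["intervention", "comparison"]
    p_anc4: float
    p_full_imm: float
    p_comprehensive: float
    n: int

    def __post_init__(self) -> None:
        for name in ("p_anc4", "p_full_imm", "p_comprehensive"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be a proportion in [0, 1], got {v}")
        if self.p_comprehensive > min(self.p_anc4, self.p_full_imm) + 1e-12:
            raise ValueError(
                "comprehensive-care coverage cannot exceed either of its "
                "component coverages"
            )
        if self.n <= 0:
            raise ValueError("sample size must be positive")


@dataclass(frozen=True)
class LivesSavedParameter:
    """Published lives-saved estimate for a reference scenario.

    ``point`` with ``(low, high)`` range, produced for a scenario with
    ``reference_users`` registered users and a comprehensive-care
    coverage delta of ``reference_delta_cc``.
    """

    point: float
    low: float
    high: float
    reference_year: int
    reference_users: float
    reference_delta_cc: float

    def __post_init__(self) -> None:
        if not self.low <= self.point <= self.high:
            raise ValueError("lives-saved range must satisfy low <= point <= high")


@dataclass(frozen=True)
class DalyConfig:
    """DALY discounting convention: rate ``r``, residual life expectancy
    ``L`` in years, no age weighting (fixed), continuous or discrete
    discounting."""

    discount_rate: float = 0.03
    life_expectancy: float = 66.0
    age_weighting: bool = False
    discounting_form: Literal["continuous", "discrete"] = "continuous"

    def __post_init__(self) -> None:
        if not 0 <= self.discount_rate < 1:
            raise ValueError("discount rate must be in [0, 1)")
        if self.life_expectancy <= 0:
            raise ValueError("life expectancy must be positive")
        if self.age_weighting:
            raise ValueError("age weighting is not supported (fixed off)")


@dataclass(frozen=True)
class EffectEstimate:
    """Lives saved and DALYs averted, each with an uncertainty range."""

    lives_saved: float
    lives_low: float
    lives_high: float
    dalys_averted: float
    dalys_low: float
    dalys_high: float


def incremental_utilization(
    intervention: ArmUtilization, comparison: ArmUtilization
) -> dict[str, float]:
    """Coverage deltas (intervention minus comparison) per indicator.

    Negative deltas are valid outputs (the uncertainty analysis must be
    able to explore harm)."""
    return {
        "anc4": intervention.p_anc4 - comparison.p_anc4,
        "full_imm": intervention.p_full_imm - comparison.p_full_imm,
        "comprehensive": intervention.p_comprehensive - comparison.p_comprehensive,
    }


def lives_coefficient(calibration: LivesSavedParameter) -> float:
    """Lives saved per additional comprehensive-care user, from the
    reference scenario: ``k = point / (delta_cc * users)``."""
    denom = calibration.reference_delta_cc * calibration.reference_users
    if denom == 0:
        raise ValueError(
            "calibration reference requires nonzero coverage delta and users"
        )
    return calibration.point / denom


def lives_saved_proxy(
    delta_cc: float, users: float, calibration: LivesSavedParameter
) -> tuple[float, float, float]:
    """Lives saved per year for a scenario, scaled linearly from the
    calibration reference.

    Returns ``(point, low, high)``; all three scale with
    ``delta_cc * users`` (homogeneous of degree 1 in each), so the
    reference scenario reproduces its own published values exactly.
    """
    k = lives_coefficient(calibration)
    scale = delta_cc * users
    point = k * scale
    rel = scale / (calibration.reference_delta_cc * calibration.reference_users)
    return point, calibration.low * rel, calibration.high * rel


def daly_per_death(config: DalyConfig) -> float:
    """Discounted years of life lost per death averted."""
    r, L = config.discount_rate, config.life_expectancy
    if r == 0:
        return L
    if config.discounting_form == "continuous":
        return (1.0 - math.exp(-r * L)) / r
    return (1.0 - (1.0 + r) ** (-L)) / r


def lives_to_dalys(lives: float, config: DalyConfig) -> float:
    """DALYs averted per year from lives saved per year; ranges propagate
    multiplicatively through the same factor."""
    return lives * daly_per_death(config)


def effect_estimate(
    delta_cc: float,
    users: float,
    calibration: LivesSavedParameter,
    config: DalyConfig = DalyConfig(),
) -> EffectEstimate:
    """Full effect estimate for a scenario: lives saved (with range) and
    the corresponding DALYs averted."""
    point, low, high = lives_saved_proxy(delta_cc, users, calibration)
    f = daly_per_death(config)
    return EffectEstimate(point, low, high, point * f, low * f, high * f)
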