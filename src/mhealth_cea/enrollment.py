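"""Enrollment forecasting: compound monthly growth in program
registrations with an annual population-coverage cap.

The projection engine keeps an unrounded geometric state internally and
rounds to whole registrants (half-up) only in the reported monthly
series, so rounding error does not compound across the horizon.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .money import round_half_up

#: Annual pregnancies in the target province, back-computed from the
#: year-5 scale-up target (179,562 registrations = 60% coverage).
DEFAULT_ANNUAL_PREGNANCIES = 299_270


@dataclass
class ProjectionConfig:
    """Growth and coverage assumptions for the scale-up forecast.

    monthly_growth
        Compound growth rate per month in new registrations (default 10%).
    annual_pregnancies
        Denominator for coverage (pregnancies per year in the province).
    coverage_cap
        Maximum fraction of annual pregnancies that can be registered in
        any program year (default 60%, the scale-up target).
    """

    monthly_growth: float = 0.10
    annual_pregnancies: int = DEFAULT_ANNUAL_PREGNANCIES
    coverage_cap: float = 0.60

    def __post_init__(self) -> None:
        if self.monthly_growth < -1:
            raise ValueError("monthly growth below -100% is meaningless")
        if not 0 < self.coverage_cap <= 1:
            raise ValueError("coverage_cap must be in (0, 1]")
        if self.annual_pregnancies <= 0:
            raise ValueError("annual_pregnancies must be positive")


@dataclass
class EnrollmentSeries:
    """Monthly registration counts, observed and/or forecast.

    ``monthly_counts[i]`` is the number of *new* registrations in month
    ``i``; ``status[i]`` is ``"observed"`` or ``"forecast"``; months run
    from ``start_month`` (an ISO ``YYYY-MM`` string).  An internal
    unrounded level is carried alongside so that forecasts extended from
    this series do not accumulate integer-rounding error.
    """

    monthly_counts: list[int]
    status: list[str] = field(default_factory=list)
    start_month: str = "2012-07"
    _levels: Optional[list[float]] = None  # unrounded internal state

    def __post_init__(self) -> None:
        if not self.status:
            self.status = ["observed"] * len(self.monthly_counts)
        if len(self.status) != len(self.monthly_counts):
            raise ValueError("status and monthly_counts must have equal length")
        if any(c < 0 for c in self.monthly_counts):
            raise ValueError("registration counts must be nonnegative")
        seen_forecast = False
        for s in self.status:
            if s not in ("observed", "forecast"):
                raise ValueError(f"unknown month status {s!r}")
            if s == "forecast":
                seen_forecast = True
            elif seen_forecast:
                raise ValueError("observed months must precede forecast months")
        if self._levels is None:
            self._levels = [float(c) for c in self.monthly_counts]

    def __len__(self) -> int:
        return len(self.monthly_counts)

    def to_frame(self) -> pd.DataFrame:
        idx = pd.period_range(self.start_month, periods=len(self), freq="M")
        return pd.DataFrame(
            {"month": idx.astype(str), "count": self.monthly_counts, "status": self.status}
        )


def project_enrollment(
    observed: EnrollmentSeries,
    config: ProjectionConfig,
    horizon_months: int,
) -> EnrollmentSeries:
    """Extend an observed series ``horizon_months`` forward at compound
    monthly growth, capping each 12-month program year at
    ``coverage_cap * annual_pregnancies`` registrations.

    Each forecast month equals the previous (unrounded) month times
    ``1 + g``; months in a year that would exceed the cap are scaled
    proportionally so the year's total equals the cap.  Reported counts
    are rounded half-up per month.
    """
    if len(observed) == 0:
        raise ValueError("cannot project from an empty observed series")
    if horizon_months < 0:
        raise ValueError("horizon must be nonnegative")

    g = config.monthly_growth
    levels = list(observed._levels)
    status = list(observed.status)
    level = levels[-1]
    for _ in range(horizon_months):
        level = level * (1.0 + g)
        levels.append(level)
        status.append("forecast")

    # Annual coverage cap: scale months of an offending program year
    # (12-month blocks from the series start) proportionally.
    cap = config.coverage_cap * config.annual_pregnancies
    for start in range(0, len(levels), 12):
        block = levels[start : start + 12]
        total = sum(block)
        has_forecast = any(
            s == "forecast" for s in status[start : start + len(block)]
        )
        if total > cap and has_forecast:
            scale = cap / total
            for i in range(start, start + len(block)):
                levels[i] *= scale

    counts = [int(round_half_up(x)) for x in levels]
    return EnrollmentSeries(
        monthly_counts=counts,
        status=status,
        start_month=observed.start_month,
        _levels=levels,
    )


def annual_totals(
    series: EnrollmentSeries,
    annual_pregnancies: int = DEFAULT_ANNUAL_PREGNANCIES,
) -> pd.DataFrame:
    """Exact 12-month sums of registrations per program year.

    Returns a DataFrame indexed by program year with columns ``total``,
    ``coverage`` (total / annual pregnancies) and ``complete``.  A partial
    final year is flagged (``complete=False``) and a warning is emitted
    rather than silently truncating.
    """
    rows = []
    n = len(series)
    for year, start in enumerate(range(0, n, 12), start=1):
        block = series.monthly_counts[start : start + 12]
        complete = len(block) == 12
        if not complete:
            warnings.warn(
                f"program year {year} covers only {len(block)} months; "
                "its total is flagged as incomplete",
                stacklevel=2,
            )
        total = int(sum(block))
        rows.append(
            {
                "year": year,
                "total": total,
                "coverage": total / annual_pregnancies,
                "complete": complete,
            }
        )
    return pd.DataFrame(rows).set_index("year")


def geometric_months(annual_total: float, g: float, n_months: int = 12) -> list[float]:
    """Split an annual total into ``n_months`` unrounded counts growing
    geometrically at rate ``g`` per month (used to seed projections from
    a known annual total when the monthly breakdown is not recorded)."""
    if g == 0:
        return [annual_total / n_months] * n_months
    ratio = (1 + g) ** n_months - 1
    m0 = annual_total * g / ratio
    return [m0 * (1 + g) ** i for i in range(n_months)]


def series_from_annual_total(
    annual_total: float,
    g: float,
    start_month: str = "2012-07",
    status: str = "observed",
) -> EnrollmentSeries:
    """Build a 12-month series with geometric within-year shape whose
    unrounded months sum exactly to ``annual_total``."""
    levels = geometric_months(annual_total, g)
    return EnrollmentSeries(
        monthly_counts=[int(round_half_up(x)) for x in levels],
        status=[status] * 12,
        start_month=start_month,
        _levels=levels,
    )
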