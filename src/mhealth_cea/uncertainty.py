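"""Probabilistic and one-way uncertainty analysis.

Parameter uncertainty is expressed as named :class:`ParameterSpec`
entries (point, range, distribution family).  A Monte Carlo run draws a
table of parameter values, pushes each draw through a user-supplied
model ``draw -> (delta_cost, delta_effect)``, and summarizes the
resulting cloud on the cost-effectiveness plane: mean ICER (ratio of
means, not mean of ratios), percentile confidence intervals, the
cost-effectiveness acceptability curve (CEAC) via net monetary benefit,
and a one-way tornado analysis.

Sampling uses one independent, counter-based substream per parameter
derived from the global seed, so adding or removing a parameter does not
perturb the draws of the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

Family = str  # {"beta", "gamma", "uniform", "triangular", "pert", "fixed"}

_FAMILIES = ("beta", "gamma", "uniform", "triangular", "pert", "fixed")


@dataclass(frozen=True)
class ParameterSpec:
    """One uncertain model input.

    point, low, high
        Point estimate and one-way range (``low <= point <= high``).
    family
        Distribution family for probabilistic sampling:

        * ``beta`` — moment-matched to ``mean=point`` with pseudo-sample
          size ``effective_n`` (proportions);
        * ``gamma`` — ``mean=point``, ``sd=(high-low)/(2*1.96)`` unless
          ``sd`` is given (nonnegative costs);
        * ``uniform`` — on ``[low, high]``;
        * ``triangular`` — ``(low, mode=point, high)``;
        * ``pert`` — beta-PERT on ``(low, mode=point, high)``, the
          mode-weighted default for published point-plus-range inputs;
        * ``fixed`` — degenerate at ``point``.
    effective_n
        Pseudo-sample size for the beta family.
    sd
        Optional explicit standard deviation for the gamma family.
    """

    name: str
    point: float
    low: float
    high: float
    family: Family = "fixed"
    effective_n: Optional[float] = None
    sd: Optional[float] = None

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown distribution family {self.family!r}")
        if not self.low <= self.point <= self.high:
            raise ValueError(
                f"{self.name}: require low <= point <= high, got "
                f"({self.low}, {self.point}, {self.high})"
            )
        if self.family == "beta":
            if not (0 <= self.low and self.high <= 1):
                raise ValueError(f"{self.name}: beta support is [0, 1]")
            if not self.effective_n or self.effective_n <= 0:
                raise ValueError(f"{self.name}: beta family needs effective_n > 0")
        if self.family == "gamma" and self.point < 0:
            raise ValueError(f"{self.name}: gamma support is nonnegative")


@dataclass
class PSADraws:
    """Monte Carlo output: one ``(delta_cost, delta_effect)`` pair per
    iteration, plus the parameter draw table and bookkeeping."""

    delta_cost: np.ndarray
    delta_effect: np.ndarray
    seed: int
    n_iter: int
    parameters: Optional[pd.DataFrame] = None
    failures: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.delta_cost) != self.n_iter or len(self.delta_effect) != self.n_iter:
            raise ValueError("draw arrays must have length n_iter")

    def quadrant_counts(self) -> dict[str, int]:
        """Cost-effectiveness plane quadrant occupancy (NE, SE, SW, NW);
        counts sum to n_iter (boundary draws count toward the east/north
        side)."""
        dc, de = self.delta_cost, self.delta_effect
        ne = int(np.sum((de >= 0) & (dc >= 0)))
        se = int(np.sum((de >= 0) & (dc < 0)))
        sw = int(np.sum((de < 0) & (dc < 0)))
        nw = int(np.sum((de < 0) & (dc >= 0)))
        return {"NE": ne, "SE": se, "SW": sw, "NW": nw}


@dataclass
class CEACurve:
    """Probability of cost-effectiveness as a function of the
    willingness-to-pay threshold."""

    wtp: np.ndarray
    probability: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.wtp) < 0):
            raise ValueError("wtp grid must be ascending")
        if np.any((self.probability < 0) | (self.probability > 1)):
            raise ValueError("probabilities must lie in [0, 1]")

    def at(self, wtp_value: float) -> float:
        idx = int(np.argmin(np.abs(self.wtp - wtp_value)))
        return float(self.probability[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"wtp": self.wtp, "probability": self.probability})


@dataclass(frozen=True)
class TornadoEntry:
    """One bar of a one-way sensitivity analysis."""

    parameter: str
    icer_at_low: float
    icer_at_high: float

    @property
    def width(self) -> float:
        return abs(self.icer_at_high - self.icer_at_low)


def _substream(seed: int, name: str) -> np.random.Generator:
    """Independent generator for one parameter: the global seed plus a
    stable 32-bit counter derived from the parameter name."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(name.encode())])


def _sample_one(spec: ParameterSpec, n_iter: int, rng: np.random.Generator) -> np.ndarray:
    if spec.family == "fixed":
        return np.full(n_iter, spec.point)
    if spec.family == "uniform":
        return rng.uniform(spec.low, spec.high, n_iter)
    if spec.family == "beta":
        n = float(spec.effective_n)  # type: ignore[arg-type]
        a, b = spec.point * n, (1 - spec.point) * n
        if a <= 0 or b <= 0:
            return np.full(n_iter, spec.point)  # degenerate proportion 0 or 1
        return rng.beta(a, b, n_iter)
    if spec.family == "gamma":
        sd = spec.sd if spec.sd is not None else (spec.high - spec.low) / (2 * 1.96)
        if sd <= 0 or spec.point == 0:
            return np.full(n_iter, spec.point)
        shape = (spec.point / sd) ** 2
        scale = sd**2 / spec.point
        return rng.gamma(shape, scale, n_iter)
    if spec.family == "triangular":
        if spec.low == spec.high:
            return np.full(n_iter, spec.point)
        return rng.triangular(spec.low, spec.point, spec.high, n_iter)
    if spec.family == "pert":
        if spec.low == spec.high:
            return np.full(n_iter, spec.point)
        # Beta-PERT: shape parameters from (low, mode, high) with lambda=4.
        a = 1 + 4 * (spec.point - spec.low) / (spec.high - spec.low)
        b = 1 + 4 * (spec.high - spec.point) / (spec.high - spec.low)
        return spec.low + (spec.high - spec.low) * rng.beta(a, b, n_iter)
    raise AssertionError(spec.family)


def sample_parameters(
    specs: Sequence[ParameterSpec], n_iter: int, seed: int
) -> pd.DataFrame:
    """Draw an ``n_iter``-row table of parameter values, one column per
    spec, reproducible for a given seed."""
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    cols = {}
    for spec in specs:
        cols[spec.name] = _sample_one(spec, n_iter, _substream(seed, spec.name))
    return pd.DataFrame(cols)


Model = Callable[[Mapping[str, float]], tuple[float, float]]


def run_psa(
    specs: Sequence[ParameterSpec],
    model: Model,
    n_iter: int = 1000,
    seed: int = 0,
    max_failure_rate: float = 0.01,
) -> PSADraws:
    """Propagate parameter uncertainty through ``model``.

    ``model`` maps one draw (a name -> value mapping) to a
    ``(delta_cost, delta_effect)`` pair.  A failing iteration is recorded
    and skipped (its pair set to NaN); more than ``max_failure_rate`` of
    failures aborts the run.
    """
    table = sample_parameters(specs, n_iter, seed)
    dc = np.empty(n_iter)
    de = np.empty(n_iter)
    failures: list[int] = []
    rows = table.to_dict("records")
    for i, row in enumerate(rows):
        try:
            dc[i], de[i] = model(row)
        except Exception:
            dc[i] = de[i] = np.nan
            failures.append(i)
    if len(failures) > max_failure_rate * n_iter:
        raise RuntimeError(
            f"model failed on {len(failures)}/{n_iter} draws "
            f"(> {max_failure_rate:.0%} tolerated)"
        )
    return PSADraws(dc, de, seed=seed, n_iter=n_iter, parameters=table, failures=failures)


def mean_icer(draws: PSADraws) -> Optional[float]:
    """Ratio-of-means ICER: mean incremental cost divided by mean
    incremental effect (explicitly *not* the mean of per-draw ratios).
    Returns None (undefined) when the mean effect is zero."""
    me = float(np.nanmean(draws.delta_effect))
    if me == 0:
        return None
    return float(np.nanmean(draws.delta_cost)) / me


def percentile_ci(
    draws: PSADraws, level: float = 0.95
) -> tuple[float, float, int]:
    """Percentile confidence interval of the per-draw ICER.

    Ratios are only comparable among draws whose effects share a sign, so
    the interval is computed over the majority-sign draws; the number of
    excluded (opposite- or zero-sign) draws is returned alongside.
    Requires enough draws for the requested tails.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    min_n = int(np.ceil(2 / (1 - level)))
    ok = ~np.isnan(draws.delta_effect)
    de, dc = draws.delta_effect[ok], draws.delta_cost[ok]
    pos, neg = de > 0, de < 0
    if pos.sum() == 0 and neg.sum() == 0:
        raise ValueError("all draws have zero incremental effect; ICER undefined")
    use = pos if pos.sum() >= neg.sum() else neg
    excluded = int(len(de) - use.sum())
    if use.sum() < min_n:
        raise ValueError(
            f"need at least {min_n} consistent-sign draws for a {level:.0%} interval"
        )
    ratios = dc[use] / de[use]
    lo, hi = np.percentile(ratios, [100 * (1 - level) / 2, 100 * (1 + level) / 2])
    return float(lo), float(hi), excluded


def ceac(draws: PSADraws, wtp_grid: Sequence[float]) -> CEACurve:
    """Cost-effectiveness acceptability curve.

    At each willingness-to-pay ``lam``, the probability is the fraction
    of draws with strictly positive incremental net monetary benefit
    ``lam * delta_effect - delta_cost`` (ties count as not
    cost-effective)."""
    grid = np.asarray(sorted(wtp_grid), dtype=float)
    if grid.size == 0:
        raise ValueError("wtp grid must be non-empty")
    ok = ~(np.isnan(draws.delta_cost) | np.isnan(draws.delta_effect))
    dc, de = draws.delta_cost[ok], draws.delta_effect[ok]
    if dc.size == 0:
        raise ValueError("no valid draws")
    nmb = grid[:, None] * de[None, :] - dc[None, :]
    prob = (nmb > 0).mean(axis=1)
    return CEACurve(grid, prob)


def tornado(
    specs: Sequence[ParameterSpec],
    model: Model,
    base: Optional[Mapping[str, float]] = None,
) -> list[TornadoEntry]:
    """One-way sensitivity analysis: recompute the deterministic ICER at
    each parameter's low and high, all others held at their point
    estimates; bars sorted by descending width.  Degenerate parameters
    (low == high) keep their zero-width bar."""
    base_values = dict(base) if base is not None else {s.name: s.point for s in specs}

    def icer_at(values: Mapping[str, float]) -> float:
        dc, de = model(values)
        if de == 0:
            raise ValueError("one-way analysis hit a zero incremental effect")
        return dc / de

    entries = []
    for spec in specs:
        lo_vals = dict(base_values, **{spec.name: spec.low})
        hi_vals = dict(base_values, **{spec.name: spec.high})
        entries.append(
            TornadoEntry(spec.name, icer_at(lo_vals), icer_at(hi_vals))
        )
    return sorted(entries, key=lambda e: e.width, reverse=True)


def tornado_frame(entries: Sequence[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "parameter": e.parameter,
                "icer_at_low": e.icer_at_low,
                "icer_at_high": e.icer_at_high,
                "width": e.width,
            }
            for e in entries
        ]
    )
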