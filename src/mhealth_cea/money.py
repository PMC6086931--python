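"""Monetary primitives: base-year currency amounts, capital annualization,
and CPI / exchange-rate adjustment.

Ledger arithmetic is carried out in :class:`decimal.Decimal` at cent
precision so that printed cost tables reproduce exactly; model math
downstream of the ledger uses floats.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Union

CENT = Decimal("0.01")

#: Calendar-year sanity bounds for price years.
MIN_PRICE_YEAR, MAX_PRICE_YEAR = 1990, 2030


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (the convention of printed cost
    tables and whole-registrant counts), unlike banker's rounding."""
    q = Decimal(1).scaleb(-ndigits)
    d = Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP)
    return float(d) if ndigits else float(int(d))


def to_decimal(value: Union[int, float, str, Decimal]) -> Decimal:
    """Coerce a number to a cent-quantized Decimal."""
    if isinstance(value, Decimal):
        return value.quantize(CENT, rounding=ROUND_HALF_UP)
    return Decimal(repr(value) if isinstance(value, float) else str(value)).quantize(
        CENT, rounding=ROUND_HALF_UP
    )


@dataclass(frozen=True)
class MoneyAmount:
    """An amount of money tagged with its currency and price year.

    Parameters
    ----------
    value
        Nonnegative amount in currency units, held at cent precision.
    currency
        ISO currency code; the package handles ZAR and USD.
    price_year
        Calendar year of the price level the amount is expressed in.
    """

    value: Decimal
    currency: str = "USD"
    price_year: int = 2015

    def __post_init__(self) -> None:
        object.__setattr__(self, "value", to_decimal(self.value))
        if self.value < 0:
            raise ValueError(f"monetary amount must be nonnegative, got {self.value}")
        if not MIN_PRICE_YEAR <= self.price_year <= MAX_PRICE_YEAR:
            raise ValueError(
                f"price_year {self.price_year} outside plausible range "
                f"[{MIN_PRICE_YEAR}, {MAX_PRICE_YEAR}]"
            )

    def __float__(self) -> float:
        return float(self.value)


def annuity_factor(useful_life_years: int, r: float) -> float:
    """Present value of a 1-per-year annuity over ``useful_life_years``
    at discount rate ``r`` (payments at the end of each year).

    The annualized cost of a capital item is its present cost divided by
    this factor.  At ``r = 0`` the factor is the useful life itself
    (continuity limit).
    """
    if useful_life_years < 1:
        raise ValueError(f"useful life must be >= 1 year, got {useful_life_years}")
    if not 0 <= r < 1:
        raise ValueError(f"discount rate must be in [0, 1), got {r}")
    if r < 1e-12:  # includes r == 0 and rates below float resolution
        return float(useful_life_years)
    return (1.0 - (1.0 + r) ** (-useful_life_years)) / r


def annualize_capital(
    present_cost: Union[MoneyAmount, float],
    useful_life_years: int,
    r: float = 0.03,
) -> Union[MoneyAmount, float]:
    """Convert a one-time capital outlay into an equivalent annual cost.

    The annual payment ``A`` solves ``present_cost = A * af(n, r)`` where
    ``af`` is the annuity factor: repeating ``A`` for ``n`` years and
    discounting at ``r`` reconstructs the present cost.

    Floats pass through at full precision (so the amortization identity
    holds to machine accuracy); :class:`MoneyAmount` inputs return a
    cent-rounded :class:`MoneyAmount`, the ledger convention.
    """
    if isinstance(present_cost, MoneyAmount):
        annual = float(present_cost) / annuity_factor(useful_life_years, r)
        return replace(present_cost, value=to_decimal(annual))
    if present_cost < 0:
        raise ValueError(f"present cost must be nonnegative, got {present_cost}")
    return float(present_cost) / annuity_factor(useful_life_years, r)


def adjustment_factor(
    cpi_source: float, cpi_base: float, fx_rate: float = 1.0, usd: bool = False
) -> float:
    """Multiplicative factor taking a source-year amount to base-year USD.

    The mapping is purely multiplicative, hence exactly invertible:
    ``adjustment_factor(a, b, fx) * adjustment_factor(b, a, 1/fx) == 1``
    up to floating-point roundoff.
    """
    if cpi_source <= 0 or cpi_base <= 0:
        raise ValueError("CPI index values must be positive")
    if fx_rate <= 0:
        raise ValueError("exchange rate must be positive")
    factor = cpi_base / cpi_source
    if not usd:
        factor /= fx_rate
    return factor


def adjust_to_base_year(
    amount: MoneyAmount,
    cpi_source: float,
    cpi_base: float,
    fx_rate: float = 1.0,
    base_year: int = 2015,
) -> MoneyAmount:
    """Inflate/deflate an amount to base-year prices and convert local
    currency to USD.

    ``result = amount * (cpi_base / cpi_source) / fx_rate`` for amounts in
    local currency (ZAR); USD-denominated amounts skip the exchange-rate
    division.  ``fx_rate`` is local currency per USD (e.g. 15.40 ZAR/USD).
    """
    if amount.currency not in ("ZAR", "USD"):
        raise ValueError(
            f"unsupported currency {amount.currency!r}: expected 'ZAR' or 'USD'"
        )
    factor = adjustment_factor(
        cpi_source, cpi_base, fx_rate, usd=amount.currency == "USD"
    )
    return MoneyAmount(to_decimal(float(amount) * factor), currency="USD", price_year=base_year)
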