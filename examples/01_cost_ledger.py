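"""Program cost ledger: aggregate the 5-year scale-up cost table.

Builds the itemized cost ledger (two categories: implementation support
and technology), prints category shares and the combined personnel
share, and shows how a raw capital outlay is annualized.
"""

from mhealth_cea import MoneyAmount, annualize_capital
from mhealth_cea.ledger import aggregate_ledger, format_ledger_table, personnel_share
from mhealth_cea.synthetic import generate_cost_ledger

ledger = generate_cost_ledger()
print(format_ledger_table(ledger))

shares = aggregate_ledger(ledger, by="category")
pct, _ = personnel_share(ledger)
print(f"\nTechnology share of total cost: {shares.loc['technology', 'share_pct']}%")
print(f"Combined personnel share:       {pct}%")
print("(shares are percent of the 5-year grand total, rounded half-up)")

annual = annualize_capital(MoneyAmount(1000.0), useful_life_years=5, r=0.03)
print(f"\nAnnualizing a $1000 one-time outlay over 5 years at 3%: "
      f"${float(annual):.2f}/year")
print("(the 5 annual payments, discounted at 3%, sum back to $1000)")
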