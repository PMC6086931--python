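"""Deterministic value for money in year 5.

Converts the year-5 utilization gains into lives saved and DALYs
averted, assembles incremental costs by perspective, and prints the
ICERs with their threshold classification.
"""

from mhealth_cea import (
    ArmUtilization,
    DalyConfig,
    classify_wtp,
    daly_per_death,
    icer,
    incremental_utilization,
    lives_saved_proxy,
)
from mhealth_cea.scenario import perspective_costs_from_values, point_values
from mhealth_cea.synthetic import YEAR5_LIVES, generate_parameter_table

intervention = ArmUtilization("intervention", p_anc4=0.72, p_full_imm=0.95,
                              p_comprehensive=0.67, n=87)
comparison = ArmUtilization("comparison", p_anc4=0.46, p_full_imm=0.90,
                            p_comprehensive=0.39, n=90)
deltas = incremental_utilization(intervention, comparison)
print(f"Coverage deltas (intervention - comparison): {deltas}")

lives, lo, hi = lives_saved_proxy(deltas["comprehensive"], 179_562, YEAR5_LIVES)
factor = daly_per_death(DalyConfig())
print(f"Lives saved in year 5: {lives:.0f} (range {lo:.0f}-{hi:.0f})")
print(f"DALY factor (r=3%, L=66y, continuous): {factor:.2f} DALYs/death")

specs, _ = generate_parameter_table(year=5)
costs = perspective_costs_from_values(point_values(specs))
print(f"\nIncremental annual costs (USD): program {costs.program:,.0f}, "
      f"health system {costs.health_system:,.0f}, user {costs.user:,.0f}")
print(f"Societal total: {costs.societal:,.0f}")

per_life = icer(costs.societal, lives)
per_daly = icer(costs.societal, lives * factor)
print(f"\nICER: ${per_life.icer:,.0f} per life saved, "
      f"${per_daly.icer:,.0f} per DALY averted")
print(f"At the $6,080 GNI-per-capita threshold this is "
      f"'{classify_wtp(per_daly.icer, 6080)}'.")
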