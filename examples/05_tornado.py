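"""One-way sensitivity analysis (tornado) for year 5.

Varies each parameter across its one-way range while holding the rest
at their point estimates, and prints the bars sorted by impact on the
cost-per-DALY ICER.
"""

from mhealth_cea import tornado, scale_up_model
from mhealth_cea.uncertainty import tornado_frame
from mhealth_cea.synthetic import generate_parameter_table

specs, _ = generate_parameter_table(year=5)
entries = tornado(specs, scale_up_model())
df = tornado_frame(entries).round(1)
print(df.to_string(index=False))
print("\nBars are ICER ranges (USD/DALY). The widest bar is the lives-saved")
print("parameter (it scales the DALY denominator directly); the second is")
print("the SMS delivery cost, the dominant variable cost at scale.")
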