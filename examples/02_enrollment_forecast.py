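"""Enrollment forecast: compound monthly growth to 60% coverage.

Projects registrations forward from the year-4 annual total at 10%
compound monthly growth and prints the resulting annual totals and
coverage of the pregnant population.
"""

from mhealth_cea import ProjectionConfig, annual_totals, project_enrollment
from mhealth_cea.enrollment import series_from_annual_total

config = ProjectionConfig()  # 10%/month growth, 60% coverage cap
year4 = series_from_annual_total(57_214, config.monthly_growth)
projected = project_enrollment(year4, config, horizon_months=12)

totals = annual_totals(projected, config.annual_pregnancies)
print(totals[["total", "coverage"]].round({"coverage": 3}))
print("\nRow 1 is the year-4 base (57,214 registrations, 19% coverage);")
print("row 2 is the forecast year-5 total after 12 months of 10% compound")
print("growth — about 179,562 women, 60% of annual pregnancies, where the")
print("coverage cap binds.")
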