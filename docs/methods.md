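# Methods

This note documents the model, its assumptions, the defaults and why
they were chosen, what the synthetic data do and do not emulate, and the
numerical conventions. It states no empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Decision problem

The intervention is a stage-based SMS health-information service for
pregnant and postpartum women, scaled from a six-facility pilot to a
provincial program reaching 60% of pregnant women in its fifth year. The
comparator is the status quo (no program, no registration). Each program
year is evaluated as a standalone annual comparison: incremental annual
cost against incremental annual health effect. Effects are deaths
averted and the years-of-life-lost DALYs they imply; morbidity (YLD),
stillbirths and age-specific life tables are out of scope.

## Costing

Costs are economic, societal-perspective, in 2015 USD, split into:

* **Program costs** — an ingredients ledger with two categories
  (implementation support; technology) and subcategory rows, one column
  per program year. Ledger arithmetic uses `decimal.Decimal` at cent
  precision so printed tables reproduce exactly; only downstream model
  math uses floats. Capital items (useful life > 1 year) and one-time
  development/start-up activities are annualized with the annuity rule
  `A = C·r/(1 − (1+r)^{-n})` at `r = 3%` (`n` = item life or the 5-year
  project lifetime). The packaged ledger stores the published cost table
  row for row, already annualized; `annualize_capital` is therefore
  exercised on synthetic inputs, with a loan-amortization stream
  reconstruction as its test oracle.

  The published table is internally inconsistent in one place: the
  printed year-3 implementation subtotal is $1,703.19 smaller than the
  sum of its own printed items, while every printed *aggregate* row is
  self-consistent across years. The package preserves the printed item
  values verbatim, carries the printed subtotal/total rows as reference
  aggregates, and tests document the gap rather than silently
  reconciling it. Percentage shares (technology 63%, personnel 18%,
  integer percent, round half-up) are insensitive to the gap.

* **Health-system costs** — registration time (US $0.08 per user, range
  0.04–0.11) plus provider time per visit: ANC $1.28 (first) / $1.03
  (subsequent, 4-visit schedule); PNC $1.03 / $0.51 (6-visit schedule,
  which coincides with the childhood immunization contact schedule —
  full-immunization coverage is therefore used as the proportion
  completing the PNC schedule).

* **User costs** — US $1.66 per ANC visit and $1.48 per PNC visit
  (wages lost ≈ 90%, transport 5%, child care 4%, food 1%), included as
  measured with no productivity-cost refinements.

**Incremental cost model.** The expected visit cost per woman in an arm
is `p_full × (full-schedule cost) + (1 − p_full) × (partial-schedule
cost)`, with the partial schedule set by `partial_anc_visits` /
`partial_pnc_visits`. The default is 0 — a woman converted to full
coverage gains the whole schedule. This choice reproduces the
published health-system and societal increments at year 5 (the model's
societal increment is within 2% of the published US $1.03 million);
treating partial attenders as receiving some intermediate number of
visits is supported through the same parameters for sensitivity use.
Two published unit aggregates are mutually inconsistent at face value
(an abstract-level ANC schedule cost of $4.36 vs the $4.37 implied by
the per-visit inputs, and $3.08 vs $3.58 for PNC); the package follows
the per-visit inputs, and the 6-visit PNC schedule, throughout.

## Enrollment

Registrations grow at `g = 10%` per month, compounded. The engine keeps
an unrounded geometric state and rounds to whole registrants (half-up)
only in the reported series, so rounding never compounds. Annual totals
are exact 12-month sums; a partial final year is flagged, not truncated.
A coverage cap (60% of 299,270 annual pregnancies — the denominator
back-computed from the year-5 target) scales the months of an offending
forecast year proportionally. Growing the year-4 total (57,214) for 12
months reproduces the published year-5 total within ±2 registrants
(integer rounding). The published year-3→4 ratio (3.106) is slightly
below `1.1^12 = 3.138`, so chaining the growth engine from year 1
overshoots the published mid-series totals; the package exposes the
growth engine and per-year parameter tables pinned to the published
annual totals rather than reverse-engineering the original worksheet.

## Effects

The external cause-of-death model that produced the published
lives-saved estimates is out of scope. It is replaced by a linear
proxy: lives saved = `k × Δcc × users`, with `Δcc` the
comprehensive-care coverage delta and `k` calibrated so the year-5
reference scenario (Δcc = 0.28, 179,562 users) returns its published
182 (range 109–199). The proxy is homogeneous of degree one in both
arguments, matching how the published estimates scale effects with
registered users across years. Negative deltas yield negative lives
saved (harm) rather than clamping, so the PSA can explore dominated
regions.

DALYs per death averted use residual life expectancy `L = 66` years at
discount rate `r = 3%`, no age weighting. The default is the continuous
form `(1 − e^{−rL})/r` (≈ 28.73); the discrete annual sum
`(1 − (1+r)^{−L})/r` (≈ 28.60) is selectable, since at the ±0.5% level
the published arithmetic is ambiguous between the two. Oracles:
numerical integration and the explicit 66-term sum.

## Uncertainty analysis

**Distributions** (the per-year PSA input tables are regenerated by
`synthetic.generate_parameter_table`, since the original appendix
tables are not available):

| input | family | spread |
|---|---|---|
| utilization proportions | beta, mean = point | pseudo-sample size 87 / 90 (the analyzed case-control arms) |
| lives saved | beta-PERT(109, 182, 199) | published range |
| registration cost | gamma, mean = point | sd from the published range, `(high−low)/3.92` |
| provider visit costs, SMS delivery, other program cost | gamma | sd = 25% of point (no published range) |
| user visit costs | gamma | sd = standard error of an interview mean (CV 0.5, n = 177) |
| registered users | fixed | — |

Beta-PERT (mode-weighted mean 172.7) was chosen over a plain triangular
for the lives-saved input: the published 182 is a point estimate near
the top of its range, and a triangular's range-dominated mean (163.3)
would make the PSA's ratio-of-means ICER drift more than 10% from the
deterministic point even with all other inputs mean-matched — a
distortion of the summary statistic, not genuine parameter uncertainty.
User visit costs get the standard error of a sample mean rather than
the 25% fallback because the parameter *is* a sample mean from ~177
exit interviews; individual-level spread enters the record generator,
not the mean's uncertainty.

**Model wiring.** Comprehensive-care proportions are carried in the
parameter table for reporting, but inside the Monte Carlo model the
effect side is driven by the lives-saved parameter alone: its published
range came from running coverage data through the external model, so
routing the coverage betas through the proxy as well would double-count
that uncertainty.

**PSA.** 1000 iterations by default (matching the original analysis;
convergence tests may raise it). Sampling uses one counter-based
substream per parameter (`default_rng([seed, crc32(name)])`), so adding
a parameter never perturbs existing columns and identical seeds
reproduce draw tables bitwise. A failing model draw is flagged and
skipped; more than 1% failures aborts. Summaries: mean ICER = mean
costs / mean effects (explicitly not the mean of ratios); 95% CI from
per-draw ratio percentiles computed over draws whose effects share the
majority sign (ratios are not comparable across quadrants; the excluded
count is reported); CEAC membership by strict net monetary benefit
`λΔE − ΔC > 0`, ties counted as not cost-effective.

**Tornado.** Each parameter swept to its one-way low/high with the rest
at points, bars sorted by ICER width; degenerate (low = high) bars are
retained at zero width. One-way ranges: published ranges where they
exist; ±1.96 sd for cost parameters; ±1 binomial SE for utilization
proportions. The narrower proportion ranges reflect the same
double-counting concern as above — the sampling uncertainty of the
case-control proportions is already embodied in the lives-saved range,
which the tornado varies separately; giving proportions their full 95%
interval on the cost side as well would overstate their one-way claim
relative to the published driver ordering (lives saved first, SMS
delivery cost second).

## Synthetic data

`synthetic` generates everything the pipeline consumes: the cost-table
fixture, per-year parameter tables, monthly enrollment series with
geometric within-year shape pinned to published annual totals (the
original monthly series exists only as a figure), and individual-level
utilization records. Records draw the comprehensive-care flag first
(cc ⇒ ANC4+ and fully immunized), then assign non-cc women to exactly
one of {ANC4+ only, immunized only, neither} so the marginals match —
the simplest copula consistent with the published marginals, feasible
whenever `p_anc4 + p_imm − p_cc ≤ 1` (it holds with equality, 1.00, in
the intervention arm). User costs are lognormal (CV 0.5) around the
published means, reflecting right-skewed interview data. What the
generator does **not** emulate: case-control matching, loss to
follow-up, record incompleteness, within-woman correlation of costs and
utilization, seasonality in enrollment. Passing parameter-recovery
tests therefore shows the chain is self-consistent at the published
operating point, not that the original study's sampling process is
captured.

## Numerical conventions and problem sizes

Integer-percent shares and whole registrants round half-up. Ledger
sums are exact decimals; everything else is float64. The default test
suite uses 1000-iteration PSAs for the headline checks and 10,000-draw
samples for moment-matching and parameter-recovery properties; these
sizes give Monte Carlo standard errors comfortably inside the asserted
tolerances while keeping the suite fast. Zero-effect draws never reach
a division: ICERs carry explicit dominance/undefined flags instead.

## Known limitations

* The lives-saved proxy is linear in incremental comprehensive-care
  users; any saturation or cause-structure effects of the original
  epidemiological model are outside its reach, and per-year effect
  estimates other than year 5 inherit the published year-5 calibration.
* Published per-arm ANC/PNC cost totals (US $1,101,947 vs $857,070)
  are not derivable from the printed unit inputs; the model reproduces
  the societal increment to within a few percent but not those arm
  totals.
* Year-1 acceptability-curve values depend on the unavailable original
  year-1 input table and are not asserted anywhere.
* The coverage cap rescales forecast months proportionally within a
  year; alternative cap semantics (hard truncation mid-year) are not
  modelled.
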