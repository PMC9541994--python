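# Methods

## Model

The model compares the expected per-patient *labor* cost of two ways of
confirming a central venous catheter (CVC) after insertion: a portable
chest radiograph (protocol A) versus a three-step bedside ultrasound
(protocol B). It is a single-time-point decision tree. The radiograph
arm is deterministic: three labor line items (technician acquisition,
bedside-physician review, radiologist interpretation). The ultrasound
arm is a chance node with three paths — no complication suspected,
suspected malposition, suspected pneumothorax — where either suspicion
diverts the patient to the complete radiograph pathway *in addition to*
the ultrasound time already spent. No credit is taken for any overlap
between the ultrasound work and the subsequent radiograph review.

Scope is labor cost only: no equipment, maintenance, training,
facility or professional charges, no discounting, and no effectiveness
axis (this is a cost comparison, not a cost-effectiveness analysis).
Dollars are nominal USD.

Each line item is `minutes × wage`, with wages in $/minute. Because
every cost is a product of at most one varying factor, both protocol
costs are affine in each individual parameter; several design choices
below exploit that.

## Parameters

| parameter | meaning | central | range |
|---|---|---|---|
| techTimeA | technician time per radiograph | 15.0 min | 10–20 |
| mdTimeA | physician radiograph review | 3.0 min | 2–4 |
| radiologistRead | radiologist interpretation | 3.0 min | 2–4 |
| mdTimeB | physician ultrasound protocol | 5.6 min | 3.1–8.1 |
| rnTimeB | nurse assist during ultrasound | 5.6 min | 3.1–8.1 |
| mdWage | bedside physician | 1.72 $/min | 1.41–1.99 |
| radiologistWage | radiologist | 1.89 $/min | 1.66–2.06 |
| rnWage | registered nurse | 0.64 $/min | 0.52–0.79 |
| techWage | radiology technician | 0.51 $/min | 0.42–0.63 |
| pMalposition | suspected malposition on ultrasound | 0.068 | 0.026–0.176 |
| pPneumothorax | suspected pneumothorax on ultrasound | 0.011 | 0.011–0.032 |

Wage ranges span the 25th–75th percentile of the underlying salary
sources; the $/minute figures are taken as direct inputs (the
salary-to-minutes conversion behind them, which assumed roughly a
60-hour physician work week, is not re-derived here). Probability
ranges span the three published incidence sources packaged as scenarios
(`smit2018`, the central values; `ablordeppey2017`; `internal2019`).
Population counts: 2,045 radiograph-confirmed catheters in one
hospital-year (of 3,069 placed), and 3.3M supradiaphragmatic catheters
nationally (66% of 5M placed annually).

Each scenario also carries the sources' reported workflow intervals
(radiograph order-to-performed, order-to-read, ultrasound
start-to-complete) as annotation only; the cost equations always use
the task times above. The internal source reports a 9-minute ultrasound
completion time against the model's 5.6-minute task time — the two
measure different spans (whole-workflow versus hands-on labor) and are
deliberately not reconciled.

## Diversion conventions

Two conventions for combining the diversion probabilities are exposed,
because the published account uses both:

- **sequential** (default): overall diversion `p_mal + (1−p_mal)·p_ptx`
  = 7.83% at central values; matches the pneumothorax term
  `(1−0.068)·0.011·C_A` in the cost table.
- **additive**: `p_mal + p_ptx` = 7.9%, the figure quoted in prose.

Sequential diversion cost is never larger than additive (equal iff one
probability is zero). Both are available everywhere a convention is
accepted.

## Numerical conventions

- **Full precision first.** All model arithmetic is unrounded; display
  rounding (cents per patient, whole dollars per hospital-year, $0.1M
  nationally, whole percent for relative savings) lives in
  `cvccost.reporting`. This is load-bearing: the hospital total
  $29,984 equals 2045 × 14.66209696…, not 2045 × $14.66. The published
  cost table's $9.65/$3.57 cells for the ultrasound line items are
  display artifacts (exact products 9.632/3.584); only the exact
  products reconcile its $14.66 total, and a regression test pins this.
- **Display rounding** is decimal (half away from zero) to avoid binary
  round-off at the cent boundary.
- **Tree rollback** checks each chance node's probabilities sum to 1
  within 1e-9 and must agree with the closed form to 1e-9 (tested on
  1,000 random parameter sets per convention).
- **Break-even** exploits affineness: the root of the cost difference
  in one parameter is solved from two evaluations over a search window
  equal to the declared range extended 10-fold about its midpoint
  (clamped to the parameter's natural domain: positive for times and
  wages, a valid probability simplex for the probabilities). `None`
  means no root in that window. A bisection oracle (Brent's method)
  cross-checks the root to 1e-6 in the tests. Degenerate ranges with an
  identically zero difference return the central value.
- **Ties in the tornado** are broken lexicographically by parameter
  label so the ordering is reproducible.

## Sensitivity analysis

One-way analysis re-evaluates *both* arms at a parameter's bounds with
everything else central — varying a radiograph-side quantity moves the
ultrasound arm too, through its diversion terms. The tornado reports
the swing `|diff(high) − diff(low)|` of the savings A − B in dollars
(a percent-of-cost view can be derived from the exported table). By
default the four wages are excluded from the tornado — they price both
protocols and largely rescale rather than reorder them, and the source
analysis deliberately did not vary salaries — but `include_wages=True`
varies them like any other parameter. Two-way analysis evaluates an
evenly spaced grid (default 11 × 11) over two parameters' ranges.

With the default inputs the savings stay positive at every one-way
extreme except the bedside-physician ultrasound time at its upper bound
(8.1 min), where the ultrasound protocol becomes ~3% (2.6% unrounded)
more costly than radiography; the break-even sits at 7.82 min.

## Probabilistic sensitivity analysis

The published inputs carry only ranges, not distributions, so the draw
generator defaults are deliberately conservative: triangular(low,
mode=central, high) for times and probabilities (bounded support,
mode at the central estimate), uniform(low, high) for wages (the bounds
are salary percentiles, so no mode is claimed). Every spec is
overridable per parameter, including to `fixed`. Draws are independent
across parameters — no correlation information exists. Probability
draws are truncated to [0, 1]. Defaults: n = 10,000 draws, seed
20220915; identical (specs, n, seed) give identical results, and fixed
specs recover the deterministic base case exactly.

Under the default specs the ultrasound protocol is cheaper in ≈ 90% of
draws (mean saving ≈ $3.39, slightly below the deterministic $3.82
because the uniform wage draws center on the range midpoints and the
triangular malposition draw centers above its mode). The test suite
asserts the direction of this result (> 0.5) rather than the 0.90
point estimate.

## What the synthetic draws do and do not emulate

The generator emulates parameter *uncertainty* around a single
institution's central estimates. It does not emulate between-site
heterogeneity (case mix, staffing models, trainee involvement),
correlation between wages and times, or any clinical consequence of a
missed complication. Passing tests therefore show the arithmetic,
orderings and uncertainty propagation are correct under the stated
conditions — not that the dollar figures transport to another hospital.

## Known limitations

- Labor cost only; a protocol that is cheaper in labor could still lose
  on facility or downstream costs (out of scope by design).
- The diverted-patient cost adds the full radiograph cost with no
  overlap credit, an intentionally conservative convention for the
  ultrasound arm.
- The two diversion conventions differ in the third decimal of the
  diversion rate (7.83% vs 7.9%); results are reported under one
  explicitly chosen convention rather than blending them.
- Wage figures are nominal and period-specific; users comparing other
  settings or years should supply their own parameter file.
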