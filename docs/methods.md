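# Methods

## Model structure

The model is a discrete-time (1-year cycle) individual-level state-transition
model of HbA1c screening for type 2 diabetes, run independently for each of
12 age × BMI strata.  Six health states:

| state | meaning | annual cost (USD) | utility |
|---|---|---|---|
| `HEALTHY` | no diabetes, not flagged | 0 | 1.0 |
| `FALSE_POSITIVE` | no diabetes, flagged at the last screen | 1,400 | 1.0 |
| `UNDETECTED_T2DM` | diabetes, missed by screening | 0 | 0.785 |
| `TREATED_T2DM` | diabetes, detected and treated | 3,500 | 0.785 |
| `COMPLICATION` | diabetes with any complication | 8,000 | 0.638 |
| `DEAD` | absorbing | 0 | 0 |

Within each cycle `t` the order of events is fixed: (1) in screening years
(`t mod interval == 0`) members of the screening pool (`HEALTHY`,
`FALSE_POSITIVE`, `UNDETECTED_T2DM`) are tested — an undetected case is
detected with probability *sensitivity*, a healthy person is flagged with
probability *1 − specificity*, a previously flagged person reverts to
`HEALTHY` on a true negative — and the $100 test fee is charged; (2)
incidence moves `HEALTHY`/`FALSE_POSITIVE` to `UNDETECTED_T2DM`; (3)
complications arise from `UNDETECTED_T2DM` at 0.014/yr and from
`TREATED_T2DM` at the hazard-scale-reduced rate `1 − (1 − 0.014)^0.79`; (4)
death occurs at the life-table probability adjusted by the state's mortality
relative risk (1.0 healthy/false-positive/treated, 2.61 undetected, 5.22
with complication); (5) the post-transition state's cost and utility accrue,
discounted by `1.02^(−t)`.  No half-cycle correction is applied.  Simulation
stops at death or age 110.

Modelling commitments where the source design was open:

* **Relative risks act on the hazard scale**, `q' = 1 − (1 − q)^RR`, never by
  probability multiplication: this keeps probabilities in [0, 1] even for
  RR 5.22 at ages where baseline mortality is large, and reduces to `RR·q`
  for small `q`.
* **Screening exit**: treated and complication states leave the screening
  schedule; false positives keep being screened (and keep paying follow-up
  costs) until a true-negative result clears them.  A false positive who
  develops diabetes becomes `UNDETECTED_T2DM` — the earlier flag predates the
  disease and is not treated as a diagnosis.
* **A complication implies diagnosis**: `COMPLICATION` accrues the treated
  complication cost regardless of prior detection, and is absorbing among
  live states.
* **Entry age** is drawn uniformly over the stratum's integer age band
  (configurable to a fixed age).  Strata are fixed for life; there is no BMI
  migration.
* The "approximately zero" annual-interval sensitivities of the source are
  encoded as exactly 0.0 (config-overridable): zero is the only reproducible
  reading.

## Two evaluators, one dynamics

`run_microsim` is a vectorized first-order Monte Carlo simulation
(n independent individuals; four uniform draws per individual per cycle in a
fixed order, so identical seeds give bit-identical results).
`run_cohort_expectation` propagates the exact probability mass over the six
states with the same event ordering, averaged over the entry-age
distribution; it returns the exact expectation with zero standard error and
is reported with `n = 0`.  The two are held together by tests: exact
closed-form cases (zero-risk discounted annuities, immediate death), an
exhaustive path-tree enumeration oracle on a 3-cycle model (agreement to
1e−12), and 3-standard-error agreement on randomized configurations.  The
cohort evaluator conserves probability mass to 1e−12 every cycle and is the
default engine for PSA, where it removes individual-level noise from the
parameter-uncertainty signal.

## Incremental analysis

`build_cea_table` sorts strategies by cost (ties: higher QALY, then label),
marks weak dominance, removes extended dominance by restoring the strictly
increasing ICER sequence along the remaining chain, and computes
increments/ICERs between consecutive frontier strategies.  "Dominant" is
reserved for a strategy that weakly dominates every alternative.  The
recommendation at willingness-to-pay λ is the most effective frontier
strategy whose ICER chain from the cheapest option stays ≤ λ; property tests
verify this equals the net-monetary-benefit (`λ·QALY − cost`) argmax absent
ties, and that the frontier coincides with a brute-force convex-hull oracle.
Exactly tied (cost, QALY) pairs are both kept, with no ICER between them.
Presentation tables round costs, QALYs and ICERs to 2 decimals; raw CSVs
keep full precision.

## Parameters and their distributions

Base-case point estimates are the published values (screening $100;
treatment $3,500 / $8,000; false-positive $1,400; utilities 1 / 0.785 /
0.638; complication rate 0.014/yr; RRs 0.79, 2.61, 5.22; discount 2%; WTP
$50,000/QALY; cohort 50,000).  Where the source's text and table conflict,
the default preset takes the internally consistent reading (e.g. mortality
RR 5.22 ≈ exp(1.65), the log-mean of its own PSA distribution) and a
`variant="text"` preset exposes the alternates (80.00, 5.61, 0.78).

PSA distributions follow the published families: gamma for costs (printed
"λ = 1/x" read as scale x), lognormal for relative risks, beta for the
complication rate.  The printed gamma parameters are inconsistent with their
point estimates under any standard parameterization (e.g. shape 84,146 ×
scale 3 ≫ 3,500), so the shipped PSA rescales each gamma's scale to
`point/shape`, keeping the shape (hence the relative spread) — the base case
must match the point-estimate column, and the PSA must be centred on it.
`check_psa_consistency` reports any spec whose central value (mean; median
for lognormal) deviates from its point estimate by more than a relative
tolerance (default 5%) and suggests the rescaled gamma as a fix.  Parameters
are sampled independently (only marginals were published), with rejection
sampling into each parameter's legal domain; test sensitivities/
specificities and utilities have no published distributions and are held
fixed.

## Synthetic stand-ins

Two inputs of the original analysis are unrecoverable and are synthesized,
clearly labelled as such:

* **Life table**: Gompertz–Makeham, `qx(age) = 1 − exp(−(c + a·e^{b·age}))`
  with defaults a = 2e−5, b = 0.1, c = 5e−4, closing at age 110.  The
  defaults give a remaining life expectancy at age 30 of ≈ 49 years —
  high-income-country-like, but deliberately *not* any official national
  table.
* **Incidence**: `base · age_slope^i · bmi_slope^j` over the ordinal age-band
  index i (0–2) and BMI index j (0–3), clipped to [0, 0.5], defaults
  0.003 × 1.6^i × 1.8^j (0.3%/yr for young underweight to 4.5%/yr for obese
  60–74).  The direction (risk rising with age and BMI) is the source's
  premise; the magnitudes are round, documented choices, not estimates.
  The reference preset itself refuses to run until an incidence is supplied,
  so no fabricated value can masquerade as a published one.

Because these stand-ins replace the unpublished inputs, passing tests
demonstrate that the *machinery* (dynamics, accounting, dominance logic,
PSA) is correct and that simulated ICERs land in a plausible range — not
that the package reproduces the original absolute ICERs.  With the default
synthetic inputs the simulated obese-strata ICERs for 3-yearly vs annual
screening come out in the low five figures $/QALY and decrease with age, the
same magnitude and ordering as the published values; exact agreement is not
expected and not claimed.

## Problem sizes and numerics

Default runs use the published design (50,000 individuals per strategy;
1,000 PSA draws); the vectorized engine completes the 12-stratum base case
in seconds and the test suite keeps oracle comparisons at 20,000 individuals
and 10^5-draw moment checks.  All randomness flows from
`numpy.random.default_rng`; pipeline runs derive per-stratum × strategy
sub-seeds via `SeedSequence(seed, spawn_key=(i, j))` (masked to 31 bits), so
results are independent of execution order.  Weighted-utility aggregation
(`aggregate_utility`) requires weights summing to 1 within 1e−9 and uses
compensated summation.

## Known limitations and one expected test failure

* One aggregate complication state (no subtype-specific costs or utilities),
  no indirect costs, no currency/price-year adjustment, no recovery from the
  complication state, no sex-specific or cohort life tables.
* Individual HbA1c trajectories are not modelled; a screen is a pure
  (sensitivity, specificity) draw, which is how the source summarizes its
  trajectory model.
* The published outcome table is internally inconsistent for two strata
  (normal 30–44 and overweight 45–59): the QALYs as printed (2 decimals)
  imply frontiers that contradict the published unrounded ICERs and
  recommendations.  `tests/test_acceptance.py::
  test_recommendation_matrix_reproduces_all_published_entries` therefore
  fails by design, reporting 10/12 agreement; the other ten strata reproduce
  exactly, as do all printed incremental costs/QALYs and dominance labels in
  the self-consistent strata.
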