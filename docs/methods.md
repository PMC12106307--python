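# Methods

## Model structure

`gdcea` implements a discrete-time Markov cohort model of neuronopathic
(type II/III) Gaucher disease with eight health states: a state without
complications, five single-complication states (necessary tracheostomy,
necessary enteral feeding, epilepsy, interstitial lung disease, major
bleeding), a state with multiple complications, and absorbing death. The
cycle length is 1 month and the horizon 6 years (72 cycles); the entire
cohort enters in the uncomplicated state.

The structural adjacency encodes which transitions are possible:
self-loops everywhere, the uncomplicated state may move to every other
state, and every live state may move to death. Direct moves *between*
complication states are disallowed by default but can be enabled per edge
in the config (`adjacency.extra_edges`), since published diagrams of such
models sometimes carry arrows the accompanying text does not enumerate.
Transition matrices are supplied as sparse off-diagonal entries; the
diagonal of each live row is closed to one minus the off-diagonal sum
("remain in state"), so a perturbed or sampled entry can never break
row-stochasticity — an over-full row raises instead. Row sums are checked
to an absolute tolerance of 1e-9.

## Rewards, discounting, half-cycle correction

Each live state accrues the monthly drug-acquisition cost and a
QALY increment of `utility / 12` per cycle; death accrues nothing from the
cycle in which membership arrives. Non-drug direct medical costs and
adverse-event costs/disutilities are excluded, matching the source
analysis's healthcare-system perspective in which drug cost dominates.

Both costs and QALYs are discounted at 5%/year with cycle-end factors
`(1+r)^(-t/12)`. The half-cycle correction is trapezoidal — the membership
counted for cycle *t* is the mean of the cycle-start and cycle-end
occupancy — which is the standard cohort-model convention; the correction
applies to costs and effects alike and can be switched off
(`--no-half-cycle`) for comparison. A month is 365.25/12 days
(365.25/84 weeks), avoiding the ~1.7% bias of a 4-week month; fractional
packs are allowed because a cohort expectation is continuous in dose.

Key default inputs (all config-overridable):

| parameter | default | units |
|---|---|---|
| imiglucerase | 2.5 U/kg × 3/week, ¥21,870 / 400 U | — |
| ambroxol | 25 mg/kg/day, ¥5.25 / 600 mg | — |
| patient weight | 20 | kg |
| utilities | 0.86 / 0.44 / 0.68 / 0.50 / 0.55 / 0.55 / 0.52 / 0 | annual weight |
| discount rate | 0.05 | per year |
| GDP per capita | 89,358 | ¥ (2023) |
| WTP thresholds | 1–3 × GDP per capita | ¥/QALY |

At 20 kg these defaults give monthly drug costs of ¥35,660.79
(imiglucerase) and ¥133.16 (ambroxol).

## Deterministic economics

The base case runs both arms from the all-uncomplicated initial vector
and reports discounted per-arm totals, incremental cost and QALYs, the
ICER, and a dominance flag. When one strategy is both cheaper and more
effective the ICER is reported as undefined (NaN) with the dominance
classification instead of a misleading ratio. All numerics are kept at
full precision; rounding happens only in human-readable summaries.

## One-way sensitivity analysis

Each parameter in the roster — both drug prices, the seven live-state
utilities, and the discount rate by default; transition probabilities
opt-in — is multiplied by 0.9 and 1.1 in turn, the full base case is
re-run, and parameters are ranked by the width of the induced ICER
interval (ties broken lexicographically for determinism). Utilities that
would exceed 1 after an upward perturbation are clamped to 1 with a
logged warning; probability perturbations re-close the row diagonal and
raise if the row becomes infeasible.

## Probabilistic sensitivity analysis

Costs are sampled from normal distributions truncated at zero by
rejection (preserving the shape above zero); utilities and transition
probabilities from beta distributions parameterised by method of moments,
`alpha = m(m(1−m)/se² − 1)`, `beta = (1−m)(…)`. The standard error is 10%
of each mean. The SE rule is stated in the source analysis for costs and
utilities; applying the same rule to transition probabilities is this
package's default and can be disabled (`psa.sample_transitions: false`).

Each of the 1,000 draws samples one shared parameter set in a fixed
documented order (prices, utilities in state order, monotherapy
transition entries, combination entries) from a single seeded stream;
prices and utilities are common to both arms within a draw (common random
numbers, matching a paired two-arm PSA). Sampled transition rows are
re-closed onto the diagonal and redrawn (bounded) if over-full. Draws are
summarised by cost-effectiveness-plane quadrant counts, a 95% confidence
ellipse from the sample mean/covariance at the chi-square(2) quantile,
and a CEAC computed as the fraction of draws with strictly positive
incremental net monetary benefit over a 21-point WTP grid from 1× to 3×
GDP per capita.

## Synthetic inputs and calibration

The per-arm monthly transition matrices behind the published totals are
not publicly tabulated. The `synthetic` module therefore provides:

**Random inputs** — structurally valid random matrices (per live row, a
symmetric-Dirichlet simplex sample scaled to a random total in (0, 0.5],
diagonal-closed) and full random parameter sets (utilities uniform in
[0.3, 0.9], prices log-uniform within 10× of the defaults) for property
and smoke tests. These emulate the *structure* of real inputs, not their
clinical plausibility: passing property tests demonstrates engine
correctness (conservation, absorption, monotonicity), not predictive
validity for real GD cohorts.

**Calibration** — a deliberately low-dimensional inverse problem: per
arm, a monthly death hazard from the uncomplicated state, a
complication-onset hazard, and an excess death hazard once complicated,
with a shared (uniform by default) complication-mix weight vector. The
two arms decouple, and each is fitted by deterministic multi-start
Nelder–Mead (default 200 starts × 500 evaluations, seeded) in a
logit-transformed bounded space, minimising the maximum relative error of
that arm's published cost and QALY totals. The achieved error is always
reported; a result outside tolerance is returned flagged, never silently.

Two aspects deserve emphasis:

1. *Cost-accrual multiplier.* The published totals are mutually
   inconsistent under full lifelong drug-cost accrual: the monotherapy
   cost total implies ≈14.9 discounted alive-months at ¥35,660.79/month,
   while the QALY total requires ≥20.6 alive-months even at the maximum
   utility 0.86. The calibration therefore optionally fits a per-arm
   drug-cost accrual multiplier (solved analytically after the QALY
   match; fitted values ≈0.70 mono / ≈0.58 combo), which can be read as
   partial adherence, dose rounding, or partial-cycle costing in the
   original implementation. Both accrual modes are supported; the
   committed fixture uses the multiplier.

2. *Selection among endpoint-equivalent solutions.* Four endpoint targets
   do not identify the hazards: many solutions reproduce the totals while
   differing in how occupancy (and hence the QALY difference) is split
   between the uncomplicated and complication states. That split is
   exactly what drives the tornado ordering and the PSA spread, so when
   the published sensitivity outputs are supplied as additional targets
   (`ReportedSensitivity`: tornado topped by the imiglucerase price; CEAC
   of 93.6% at 3× GDP per capita) the calibration keeps several converged
   solutions per arm and picks the pair that reproduces them best —
   calibration to all reported outcomes rather than a subset. The
   committed fixture was built this way (seed 0). It remains a regression
   fixture: the true source estimates may differ, and the fixture's
   metadata (`calibrated_fixture_endpoints.json`) records the achieved
   endpoints, hazards, multipliers and selection diagnostics.

## Numerical choices

- Row-stochasticity and trace-conservation tolerance: 1e-9 absolute.
- Discount factors at cycle end, `t/12` years.
- CEAC uses strict inequality; ties have probability zero under
  continuous sampling.
- Beta feasibility requires `se² < m(1−m)`; violations raise naming the
  parameter.
- Degenerate PSA covariance omits the confidence ellipse with a warning
  rather than failing.
- Calibration bounds: death hazard ≤ 0.30/month, onset ≤ 0.60, excess
  ≤ 0.50, mapped through a logistic transform so the direct search is
  unconstrained.

## Problem sizes

The test suite and the acceptance script run the full 72-cycle model
throughout; the PSA uses the study's 1,000 draws; engine property sweeps
use 10,000 random matrices over a 12-cycle grid and 10,000-draw moment
checks — sizes chosen so the whole suite completes in seconds while
keeping Monte-Carlo standard errors well inside the asserted tolerances.

## Known limitations

- Transition matrices are cycle-constant; no age- or time-dependence, no
  weight growth over the 6-year horizon, and no treatment discontinuation
  or adherence model beyond the calibrated accrual multiplier.
- The calibrated fixture reproduces published *outputs*; it is not
  evidence about the underlying clinical transition rates, and analyses
  that depend on the occupancy mix beyond the calibrated outputs (e.g.
  state-specific budget impact) should not be read off it.
- Utilities and probabilities come from non-Chinese sources in the
  original analysis; the package inherits that transferability caveat.
- Two-strategy comparison only; no efficiency frontier for >2 arms, no
  EVPI.
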