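# Methods

## The cost-of-control model

The package implements a short-term, payer-perspective "cost of control"
comparison of two drugs evaluated head to head in the same trial. The unit
of output is the annual expenditure required to bring **one** patient to a
clinical target:

```
ARR(endpoint, arm)   = p − p_ref          p = responder share, p_ref = 0 by default
NNT(endpoint, arm)   = 1 / ARR            rounded half-up to 2 decimals
annual_cost(arm)     = monthly price × 12 rounded half-up to the nearest peso
cost_of_control      = annual_cost × NNT  kept at 2 decimals
relative_index       = cost_of_control / cost_of_control(focal arm)
scaled_index         = relative_index × 100,000, nearest integer
```

The **placebo-zero convention** (`p_ref = 0`) treats the NNT of each arm in
absolute terms — how many patients must receive the drug for one to reach
target — rather than against the other arm. This is what makes per-arm costs
of control comparable across arms and endpoints. A nonzero reference share
is accepted for generality; a negative ARR is a domain error rather than a
signed result.

Structural assumptions, hard-coded and stated in run metadata: a one-year
time horizon, no discounting (none is meaningful at one year), 100%
adherence (one pack per month), and drug acquisition costs only. The model
deliberately computes no ICERs, QALYs, or non-drug costs.

## Rounding conventions — why they are flags

Published cost tables of this kind are produced in spreadsheets, and the
*order* of rounding determines whether an implementation reproduces them to
the peso. The package's defaults are the conventions under which the
packaged reference analysis reproduces its published table exactly:

- **NNT before multiplication.** `1/ARR` is rounded half-up to 2 decimals
  *first*, then multiplied by the annual cost (e.g. `5877144 × 2.13 =
  12518316.72`). `nnt_decimals` is a model parameter; 1-decimal display
  (`1.5`, `12.5`) is how headline summaries print the same quantity.
- **Annual cost to the peso (base case).** `monthly × 12` is rounded to the
  nearest peso before the product (`486946.24 × 12 = 5843354.88 → 5843355`).
  The flag `round_annual_to_peso=False` keeps the unrounded annual, which is
  the variant the published *worked example* uses (annual 5,843,354.89-ish,
  cost of control 7,421,060.7x).
- **Annual cost unrounded (price scenarios).** The published best/worst
  scenario columns are consistent with *unrounded* annualization of the
  min/max prices (peso-rounding the dulaglutide minimum annual before the
  ×12.5 NNT would shift that cell by more than 5 COP). `run_price_scenario`
  therefore defaults min/max price points to unrounded annualization while a
  base price point keeps the peso-rounded convention; `round_annual`
  overrides either way. Residual sub-peso noise against the published
  scenario columns (≤ 0.6 COP, from sub-centavo price digits the source
  table truncates) is tolerated as such in tests.
- **Half-up everywhere.** Commercial rounding, not banker's rounding,
  matches printed values; all money is `decimal.Decimal` (binary floats
  never touch currency).
- **Drug-cost index.** For two arms the published price-parity pair
  (0.9931…/1.0069…) is each arm's annual cost divided by the *other*
  arm's — the pair multiplies to 1. Implemented as cost over the mean of the
  other arms' costs, which reduces to exactly that in the two-arm case.

## Sensitivity analyses

**One-way SE perturbation.** Each observed share moves by one binomial
standard error `SE = sqrt(p(1−p)/n)` in the direction adverse to the focal
drug (focal −1 SE, comparator +1 SE), and the whole table is recomputed at
base prices. Perturbed shares are clamped to [0, 1] with a warning (possible
at extreme `p` and small `n`); a share perturbed to exactly 0 gives an
undefined (infinite) NNT — the row is kept and flagged, never dropped.
Perturbed shares are *not* re-rounded to whole percentages; the NNT rounding
convention still applies, keeping the pipeline uniform.

**Price scenarios.** `best_for_focal` prices the focal drug at its observed
market minimum and the comparator at its maximum; `worst_for_focal` the
opposite; NNTs stay at base-case values. By construction, for every
endpoint the focal arm's cost satisfies best ≤ base ≤ worst (and the
comparator the reverse) — asserted as a property test.

**Arm size `n`.** The trial behind the reference inputs randomized ~299
patients per arm but its methods text also mentions the total (600). The SE
formula needs the per-arm `n`; the packaged fixture carries `n=299` per arm
and the reader's `default_n` makes any other choice explicit rather than
silently guessed.

## Synthetic data

`simulate_trial` draws responder counts `Binomial(n_per_arm, p_true)` per
(endpoint, arm) and builds a symmetric price corridor
`[base·(1−spread), base·(1+spread)]`. One integer seed feeds a single
explicit `numpy.random.Generator`; identical spec + seed is bit-identical.
Defaults (`reference_synthetic_spec`) mirror the packaged reference study:
the six true shares of the reference trial, `n_per_arm=299`, the reference
base prices, and spread half-widths of 2.5% (focal) / 0.6% (comparator)
chosen once to match the magnitude of the observed market ranges.

What passing synthetic tests show: the pipeline is unbiased against binomial
sampling theory (mean observed share within 0.5 SE of truth over 1000
replicates; empirical SD within 15% of the analytic SE) and the
truly-better arm wins the cost comparison in ~every replicate when shares
are separated by many SEs. What they do not show: real-trial features the
generator omits — correlation between nested endpoints (every responder at
HbA1c ≤6.5% is also <7.0%, but the generator draws endpoints
independently), dropout, partial adherence, and non-binomial price
variation.

## Numerical choices and degenerate inputs

- Ratio computations (relative indices, cost index) run at 28 significant
  digits and are stored unrounded; only display and the ×100,000 scaled
  index round.
- `NNT` is clamped below at 1.00 (a share of exactly 1 means every treated
  patient responds).
- `ARR = 0` raises a domain error naming the interpretation ("no patients
  reach target; NNT undefined/infinite") in direct calls; inside table
  recomputation the row is flagged `undefined` instead so sensitivity
  results are never silently truncated.
- Equal min=base=max price ranges collapse all three scenarios to the base
  case (tested).
- Problem sizes: the reference analysis is 6 endpoints × 2 arms and runs in
  milliseconds; the simulation self-check uses 1000 replicates of the full
  12-cell binomial draw, a sub-second vectorized computation.

## Known limitations

- Two arms only; relative indexing is pairwise to the focal arm.
- Deterministic sensitivity analyses only — no probabilistic (Monte Carlo)
  sensitivity analysis, tornado diagrams or acceptability curves.
- The published source tables themselves mix conventions (the worked
  example's comparator annual cost equals the *maximum* pack price × 12,
  while the scenario table's base column uses the base price × 12). The
  package computes from whichever price point and rounding a scenario
  requests and documents, rather than resolves, that inconsistency; the
  published "22%" worst-scenario excess corresponds to an unrounded ratio of
  ≈1.228, which the package reports unrounded.
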