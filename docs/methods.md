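# Methods

## Valuation model

A compound is described by a phase plan and a commercial model. Each phase
i carries a success probability `PoS_i` and three-point (min, mode, max)
estimates of its out-of-pocket cost ($M) and duration (years). The
deterministic engine values the program at its modal timeline; the Monte
Carlo layer re-times every cash flow per sampled path.

Cash flows:

* **Development costs.** Phase cost times `(1 + s)`, where
  `s = prerevenue_sga_of_rnd` (default 0.40) models SG&A during development
  as a share of contemporaneous R&D spend. Costs are spread uniformly over
  the phase and weighted by the probability of reaching it. Development
  losses generate no tax shield; the only pre-revenue tax offset is the
  optional credit below.
* **Revenue.** Prevalent patients per age group are
  `population (thousands) × prevalence (per 1,000)`; treated patients in
  post-launch year y are `patients × peak_rate × group multiplier ×
  ramp(y)`, with the ramp (default 1/3, 2/3, 1) holding at its last value
  through exclusivity. Annual after-tax cash flow is
  `patients × price × (1 − COGS − SG&A − R&D) × (1 − tax)`, spread
  uniformly within the year and weighted by the cumulative approval
  probability. Revenue stops at the end of exclusivity; there is no
  terminal value, price erosion, or ex-U.S. market.
* **Exclusivity.** `max(patent_term − launch_time, orphan_exclusivity)`:
  20 − 6 = 14 years at the modal timeline of the shipped fixtures, floored
  at the 7-year orphan-designation window when sampled development runs
  long.
* **Add-ons.** The R&D tax credit adds `tax_credit_rate` (25%) of the
  risk-adjusted present value of development costs through phase 3 — the
  bare R&D outlay, not the SG&A uplift riding on it (this is the reading
  under which the credit's published increment, ≈ $4.4M on the base case,
  is reproduced; crediting the uplifted cost would add ≈ $6.2M). The
  priority review voucher adds
  `P(alive at prv_year) × prv_value × (1+r)^(−t)`, with survival defined as
  success in every phase ending by `prv_year`.

## Discounting conventions

Two conventions are implemented for a stream spread uniformly over
[t0, t1] at annual-effective rate r:

* **annual** (default): slice at calendar-year boundaries and discount each
  slice at its year end, `PV = ∫ c(t)(1+r)^(−⌈t⌉) dt`. This is the discrete
  end-of-period convention of spreadsheet rNPV models, extended so that it
  is well defined for non-integer phase boundaries.
* **uniform**: the continuous closed form
  `amount·((1+r)^(−t0) − (1+r)^(−t1)) / ((t1−t0)·ln(1+r))`.

At r = 13% the uniform convention prices every annual stream ≈ 6.0% higher
(one-year factor 0.9413 vs 0.8850·1.0637). The annual convention is the
default because it is the one under which the engine reproduces the
reference headline values for this case study to ~0.1%; the choice is
recorded in every run manifest. Point cash flows (sale proceeds, vouchers)
discount as `(1+r)^(−t)` under either convention. The voucher's timing
flag books it at the start (`(1+r)^(−(y−1))`, default) or end of its year.

Two further accounting flags matter only for the Monte Carlo loss metrics,
below.

## Stochastic model

Per path, with one root seed split deterministically per stream:

* **Phase outcomes** — sequential Bernoulli: a phase is attempted iff all
  prior phases succeeded. Success draws are independent of the cost and
  duration draws.
* **Costs and durations** — PERT (classical λ = 4 scaled Beta:
  `α = 1 + 4(mode−min)/(max−min)`, `β = 1 + 4(max−mode)/(max−min)`) per
  phase. The phase-2/phase-3 block (duration and cost, four margins) is
  coupled by a Gaussian copula with the equicorrelation completion of "a
  pairwise correlation of 0.5 between the two clinical phases' time and
  cost" — the stated pairwise value fixes only part of the 4×4 matrix, and
  the equicorrelated completion is the symmetric PSD choice; the full
  matrix is user-overridable.
* **Price and peak adoption** — normals calibrated so their central 95% CI
  spans the scenario's (lo, hi) bounds (`sd = (hi−lo)/(2·1.959964)`),
  truncated by rejection at 0 (and 1 for adoption), drawn once per path —
  one price assumption per valuation, not per year.
* **Re-timing** — sampled durations shift the launch date and recompute the
  exclusivity window.

Per-path outputs: the PoS-weighted rNPV under the sampled inputs; the
remaining-project value at each phase end; the time-0 NPV of "develop
through phase k, then sell at its then-current value" (failures before k
carry sunk costs with zero proceeds); and the realized overall NPV with
all Bernoullis resolved.

**Loss-metric accounting.** The sale and overall metrics net sunk
development costs against discounted proceeds. The default nets
*discounted* sunk costs — the internally consistent NPV arithmetic. The
alternative `sunk_costs="nominal"` nets undiscounted outlays (the
cash-on-cash reading common in spreadsheet practice) and is the convention
under which the single-compound reference risk figures of this case study
are reproduced; the acceptance checks therefore run the single-compound
metrics under the spreadsheet convention set and say so in their manifests.
No single convention reproduces the reference single-compound and
portfolio risk figures simultaneously: the reference values' early-phase
loss probabilities among phase completers are thinner than any convention
of this engine produces (they are consistent only with a zero-floored,
log-normal sale-price distribution), while its portfolio aggregate is
incompatible with nominal cost accounting (the aggregate's mean would be
negative). The package reports both conventions rather than blending them.

## Portfolio model

Drugs are drawn jointly: per phase, each drug's success latent is
`√ρ·F + √(1−ρ)·ε_d` with a common factor F, giving pairwise correlation ρ
across drugs (PSD for any ρ ∈ [0,1)); within-drug structure is unchanged
and costs/prices are independent across drugs. Aggregate per-phase values
are summed across drugs ignoring their timing differences, and loss
probabilities are computed on the aggregate exactly as for one compound. A
one-drug portfolio consumes exactly the single-compound streams, so it
reduces bit-for-bit.

The alternative **lognormal mode** implements the calibrated shortcut:
per-phase conditional value distributions from a single-compound run are
moment-matched to log-normals (`σ² = ln(1 + sd²/mean²)`,
`μ = ln mean − σ²/2`), each drug resamples its values from them through
one cross-coupled latent, and costs/timing stay at their modal values.
This mode is the cleanest setting for comonotonicity experiments (ρ → 1
collapses the portfolio to a scaled single drug).

**Cross-drug correlation.** ρ is an assumption; the scenario default is
0.2 (monogenic rare-disease programs are usually argued to be only weakly
correlated). The constant `CROSS_DRUG_RHO_FITTED = 0.715` is the value at
which the full-simulation 8-drug base-case portfolio reproduces the
reference 56.1% probability of a negative overall NPV under this engine
(fitted once on a ρ grid at 100,000 paths; two seeds agree to ±0.15pp).
Every portfolio output embeds the ρ it used.

## Numerical choices

* Patient counts and all intermediates are carried unrounded; rounding
  happens only in rendered tables (2 decimals, $M).
* The "upper bound" column of risk tables is a configurable percentile
  (default 95th); the sample maximum is reported alongside.
* Conditional statistics over an empty completion set are NaN, never zero.
* Degenerate PERT triples return their constant; CI calibration rejects
  asymmetric intervals rather than silently recentering.
* Phase PoS may be 0 (forced failure); conditional values of unreachable
  phases are NaN.
* Copula matrices are validated symmetric, unit-diagonal and PSD (the
  offending eigenvalue is named); semidefinite matrices fall back to an
  eigen-factorization.
* Problem sizes: 10,000 paths for single-compound results and 100,000 for
  the 8-drug portfolio (the sizes at which the reference figures are
  quoted); property tests use 20,000–100,000 draws, which puts three
  binomial standard errors at or below ~1.5 percentage points for the
  probabilities checked.

## What the scenario fixtures do and do not capture

The fixtures transcribe a published assumption set for one U.S.-only case
study: consolidated discovery-through-phase-1, symmetric PoS bounds, a flat
price, and a prevalence-based market with a three-year adoption ramp. They
do not model competition, price erosion, payer mix, partial-phase failure
costs, correlated price/cost shocks across drugs, heterogeneous portfolio
compositions, or financing structure. Passing checks on these fixtures
therefore validate the valuation arithmetic and the dependence machinery,
not the realism of any particular assumption for another program.

## Known limitations

* The within-drug copula block structure beyond the stated pairwise value
  is a documented choice, not data.
* The reference single-compound risk figures are matched under the
  spreadsheet convention set except the phase-1 loss probability, which no
  convention of this engine reproduces (see Loss-metric accounting); the
  portfolio phase-1/phase-2 loss probabilities inherit the same gap.
* Bernoulli phase outcomes are independent of cost and duration draws
  within a drug; success-cost dependence (e.g., failing trials stopping
  early and cheap) is not modeled.
* No variance reduction (antithetic or quasi-random draws) and no
  non-Gaussian copulas.
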