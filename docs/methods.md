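# Methods

## The decision problem

Women with relapsing-remitting multiple sclerosis (MS) who become pregnant
while on natalizumab face a treatment decision with both clinical and
economic consequences: continuing the drug keeps the annualised relapse
rate (ARR) low but keeps accruing acquisition and infusion costs, while
discontinuing it — at conception or after the first trimester — saves drug
cost but raises relapse risk and the probability of disability progression
on the Expanded Disability Status Scale (EDSS). `natcea` models this
trade-off from a national healthcare system perspective (GBP, 2024 prices)
and reports discounted costs, QALYs, ICERs and net monetary benefit for
the three strategies, with stopping at conception as the reference.

## Model structure

The model is a Markov cohort simulation in monthly cycles over a 33-month
horizon: 12 months pre-conception, 9 months of pregnancy, 12 months
post-pregnancy. Cycle-to-cycle transition probability is 1 — every woman
advances one month per cycle; there is no mortality, no EDSS improvement,
and no washout period. The cohort is tracked as expected occupancy over
three EDSS bands (0–1, 2–3, 4+). All quantities are expectations: relapses
and progression enter as expected counts and mass flows, never as sampled
events, so the deterministic model is fully reproducible given parameters.

Per cycle, for a given strategy:

1. the phase determines the strategy's ARR (printed ranges reduce to their
   midpoints; the PSA explores the range);
2. expected relapses = (1 − exp(−ARR/12)) × classified occupancy — the
   constant-hazard conversion, standard in state-transition modelling, and
   within 0.2% of ARR/12 at these rates;
3. progression moves occupancy one band upward (4+ absorbs) at the
   constant monthly probability 1 − (1 − f)^(1/33), where f is the
   strategy's horizon-level progression proportion (21% / 16% / 12%).
   The continuation value is the linear interpolation y = −4.58·x + 25.63
   (percent) at strategy index x = 3, consistent with the two observed
   discontinuation anchors at x = 1, 2;
4. discounted cost accrues: relapse events × £1,623, band occupancy ×
   band annual cost / 12, and the cycle's drug cost share — all times
   (1.035)^(−t/12), with cycle 0 undiscounted;
5. discounted QALYs accrue: band occupancy × band utility / 12 minus
   0.07 × expected relapses, floored at zero per cycle (the floor only
   matters under extreme PSA perturbations).

## Key input conventions

Several inputs require a convention the source tables do not pin down;
each is a documented, configurable choice:

- **Baseline occupancy residual.** The printed band occupancy
  (53.9 / 35.6 / 5.9%) sums to 0.954. By default the residual 0.046 is
  carried as an unclassified stratum with zero cost and zero utility
  weight, which reproduces the reference QALY levels; `renormalise: true`
  instead scales occupancy to the full simplex (and raises all QALY
  totals by ~0.06–0.09, outside the reproduction band — hence not the
  default).
- **EDSS band costs.** Annual costs are priced per EDSS level 0–9
  (£488 … £35,545) but the cohort is banded. Band cost is the unweighted
  mean of member levels; the level range backing each band
  (`band_level_ranges`) is configurable because the aggregation of the
  open-ended 4+ band is the model's main cost-calibration knob. The
  default 4–9 mean (£16,111.50/yr) gives the best base-case cost
  reproduction among the admissible ranges.
- **Drug cost timing.** The 4-weekly cycle totals 6 / 6.75 / 8.25 are
  authoritative and equal 24 / 27 / 33 on-treatment months ÷ 4 — i.e.
  every strategy treats pre-conception and resumes post-pregnancy, and
  they differ only during pregnancy (none / first trimester / all).
  Total drug cost, cycles × (acquisition + administration), is spread
  uniformly over those on-treatment months so discounting is well
  defined; the spreading affects totals by well under 2%.
- **Relapse disutility** (0.07) is an absolute QALY decrement per
  expected event.

## Probabilistic sensitivity analysis

1000 draws by default. The ±20% adjustment range is interpreted as a 95%
interval of the perturbation distribution: SD = 0.20 × mean / 1.96,
moment-matched to a beta distribution for proportions and rates (ARRs,
progression proportions, band occupancy) and a gamma distribution for
costs (per-relapse, EDSS levels, drug acquisition and administration).
Rates too close to 1 for a valid beta fall back to the moment-matched
gamma. Utilities, cycle counts, the schedule and the discount rate are
held fixed. Within a draw the three strategies share one perturbed set
(correlated PSA — independent draws would overstate decision
uncertainty); strategy-specific entries are drawn independently of each
other since no correlation structure is given. Draws are deterministic in
(seed, draw index) via `numpy.random.default_rng([seed, index])`. The
CEAC reports, per willingness-to-pay value on a £0–£50,000 grid (£1,000
steps), the fraction of draws in which each strategy has the strictly
highest net monetary benefit, ties split equally.

## Economics

For strategy vs reference: ΔC, ΔE, ICER = ΔC/ΔE (undefined, not
infinite, when ΔE = 0), NMB = λ·ΔE − ΔC. Cost-effective means NMB > 0
strictly; for ΔE > 0 this is ICER < λ. Dominant means ΔC ≤ 0 and ΔE ≥ 0
with at least one strict; dominated is the reverse. Discounting is 3.5%
per year; the default threshold is £20,000/QALY with £30,000 as a
scenario value.

## Scenarios

Five named analyses run from one command: the base case (originator
price £1,130/cycle), generic (£870) and biosimilar (£666) price
variants, a logarithmic-progression variant (y = a·ln x + b refit
through the two discontinuation anchors, re-deriving only the
continuation proportion: 13.08% instead of 12%), and the £30,000
threshold. Price variants change only costs, so QALYs are bitwise
identical across them.

## Synthetic data and testing

No patient-level data backs the model, so the synthetic module generates
whole parameter sets dispersed multiplicatively (log-normal jitter)
around the packaged base case, enforcing every structural invariant
(rates in a plausible MS envelope, non-decreasing band cost means,
decreasing band utilities, occupancy renormalised to the base total).
These sets exercise the engine across input space; they emulate the
*shape* of real inputs, not any real population, so passing tests
demonstrate internal correctness and invariance, not external validity.
Degenerate known-answer fixtures (single band, zero discounting, drug
cost only) have closed-form totals and pin the engine to 1e-9 relative;
an independent plain-Python accumulation serves as a second oracle on
synthetic sets.

## Numerical choices

Occupancy mass is conserved to 1e-12 per cycle. Cost breakdowns sum to
totals within 1e-9 relative. Engine state is float64 throughout; a
33-cycle run takes well under a millisecond, a 1000-draw PSA a few
seconds on one CPU. Problem sizes used in the shipped analyses are the
study conditions themselves: 33 cycles, 1000 PSA draws.

## Known limitations

- The model reproduces the reference per-strategy cost and QALY *levels*
  for stopping at conception and continuing through pregnancy (within
  ±5% / ±0.03), and the QALY ordering across strategies, but not the
  reference *incremental* structure: with the printed inputs, continuing
  through pregnancy carries ~£1,200 more discounted cost than stopping
  at conception (drug cost difference of 2.25 cycles ≈ £3,044, partly
  offset by relapse and progression savings of ~£1,850), not ~£70; and
  stopping after the first trimester — which has lower relapse rates,
  less progression and only 0.75 more drug cycles than stopping at
  conception — cannot be the most expensive strategy under any admissible
  convention, as the reference reports. The derived acceptability
  probabilities are correspondingly lower than the reference values.
  The discrepancy is insensitive to every exposed knob (band-cost
  aggregation, renormalisation, drug timing, rate conversion).
- No neonatal or breastfeeding outcomes, no washout, no mortality, no
  EDSS improvement, no individual-level heterogeneity or dosing-interval
  variation: the cohort is homogeneous by construction.
- Utilities are held fixed in the PSA (only rates, proportions and costs
  are varied); this is configurable but the default mirrors the listed
  perturbation set.
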