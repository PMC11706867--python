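# natcea

Cost-effectiveness of natalizumab treatment strategies for pregnant women
with multiple sclerosis, from the UK healthcare system perspective.

Women with relapsing-remitting MS on natalizumab who plan a pregnancy
choose between three strategies: **stop at conception** (resume
post-pregnancy), **stop after the first trimester**, or **continue
through pregnancy**. Discontinuation saves drug acquisition and infusion
costs but raises the annualised relapse rate (ARR) and the risk of
EDSS disability progression; continuation does the opposite. `natcea`
quantifies that trade-off with a monthly-cycle Markov cohort model over a
33-month horizon (12 months pre-conception, 9 of pregnancy, 12
post-pregnancy), and is aimed at health-economics analysts who want the
whole pipeline — inputs, engine, incremental economics, scenarios, PSA —
as tested, scriptable code rather than a spreadsheet.

## Model

The cohort occupies three EDSS bands (0–1, 2–3, 4+) with band utilities
u_b and annual costs c_b. Per monthly cycle t (discount factor
(1+r)^(−t/12), r = 3.5%/yr):

- expected relapses  E_t = (1 − e^(−ARR/12)) · Σ_b occ_b,
- progression moves occupancy one band up at the constant monthly hazard
  p = 1 − (1 − f)^(1/33), with f the strategy's horizon-level progression
  proportion (21% / 16% / 12%),
- cost accrual:  E_t·c_relapse + Σ_b occ_b·c_b/12 + drug share,
- QALY accrual:  Σ_b occ_b·u_b/12 − 0.07·E_t  (floored at 0).

For strategy S vs the reference (stop at conception):
ICER = ΔC/ΔE and NMB = λ·ΔE − ΔC; S is cost-effective at threshold λ iff
NMB > 0. The PSA perturbs rates/proportions (beta) and costs (gamma)
with SD = 0.2·mean/1.96 (±20% read as a 95% interval) and reports
cost-effectiveness acceptability curves: P(highest NMB) per λ.

All base-case inputs ship in `src/natcea/data/base_case.yaml`; any field
can be overridden from a user YAML file.

## Worked example

```sh
natcea base-case --out out/ --verbose
```

prints

```
Per-person discounted totals
                  strategy total_cost total_qaly
        Stop at conception     18,954       1.87
Stop after first trimester     19,221       1.90
Continue through pregnancy     20,148       1.94

Incrementals vs stop at conception (WTP = 20,000 GBP/QALY)
                  strategy delta_cost delta_qaly   icer nmb dominance
        Stop at conception          -          -      -   -         -
Stop after first trimester        267       0.02 11,172 211 trade_off
Continue through pregnancy      1,194       0.06 19,215  49 trade_off
```

Reading: continuing natalizumab through pregnancy yields the most QALYs
(1.94 vs 1.87 for stopping at conception — fewer relapses, less
disability progression) at £1,194 more discounted cost per person, an
ICER of £19,215 per QALY — just under the £20,000 NICE lower bound, so
marginally cost-effective (NMB +£49). The same library calls are
available in Python:

```python
import natcea

params = natcea.default_parameters()
results = natcea.run_all_strategies(params)
inc = natcea.compute_incremental(
    results[natcea.Strategy.CONTINUE_THROUGH_PREGNANCY],
    results[natcea.Strategy.STOP_AT_CONCEPTION],
    wtp=20000,
)
print(round(inc.icer), round(inc.nmb))   # 19215 49
```

Other commands: `natcea psa --draws 1000 --seed 1 --out out/` (CE-plane
and CEAC CSVs, optional `--plot`), `natcea scenarios --out out/` (base
case, generic/biosimilar prices, logarithmic progression, £30,000
threshold), `natcea generate-fixtures` (synthetic parameter sets).

With generic (£870/cycle) or biosimilar (£666/cycle) acquisition prices
the continuation strategy's incremental cost falls to +£636 and +£197
respectively; QALYs are unaffected by price variants.

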