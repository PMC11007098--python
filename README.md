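# survcea

Cost-effectiveness analysis of adjuvant osimertinib versus placebo in
completely resected stage IB–IIIA EGFR-mutated non-small-cell lung cancer,
from a U.S. payer perspective — implemented as a tested, reusable Python
pipeline for health-economics practitioners and reproducers.

The package covers the whole chain such an analysis needs:

* **Parametric survival extrapolation** — seven closed-form families
  (exponential, Weibull, gamma, generalized gamma in the Prentice
  (mu, sigma, Q) form, log-normal, log-logistic, Gompertz), time in months.
* **Pseudo-IPD reconstruction** — invert a digitized Kaplan–Meier curve
  plus numbers-at-risk table into event/censoring times, and refit the
  candidate families by censored maximum likelihood with AIC/BIC selection.
* **Three-state cohort model** — disease-free / recurrence / death over
  275 three-week cycles (a 63-year-old cohort carried to the 78.8-year
  U.S. life expectancy), background-mortality floor from a bundled life
  table, 3% annual discounting, half-cycle correction, 3-year cap on
  active treatment.
* **Valuation** — utilities 0.83/0.74/0; drug, chemotherapy, monitoring,
  best-supportive-care and terminal-care costs in 2023 USD; incremental
  cost-effectiveness ratio ICER = ΔCost/ΔQALY.
* **Sensitivity analyses** — one-way tornado, 1,000-draw probabilistic
  sensitivity analysis (gamma costs, beta utilities/proportions, normal
  body surface area), cost-effectiveness acceptability curve from net
  monetary benefit (WTP·ΔQALY − ΔCost), and threshold-price bisection.
* **Synthetic data** — trial-like arms with known ground truth so every
  stage is testable end to end without downloads.

See `docs/methods.md` for the model, its assumptions and conventions.

## Worked example

```python
import survcea as sc

inputs = sc.default_inputs()          # the shipped base-case parameters
res = sc.base_case(inputs)
print(f"active : cost ${res.active.total_cost:,.0f}  QALYs {res.active.total_qalys:.2f}")
print(f"control: cost ${res.control.total_cost:,.0f}  QALYs {res.control.total_qalys:.2f}")
inc = res.incremental
print(f"ICER ${inc.icer:,.0f}/QALY")
print(f"price at $150k/QALY: ${sc.threshold_price(inputs, wtp=150_000):.2f} per 80 mg")
```

prints

```
active : cost $641,564  QALYs 8.14
control: cost $120,185  QALYs 6.60
ICER $339,607/QALY
price at $150k/QALY: $265.92 per 80 mg
```

Read: three years of adjuvant osimertinib adds about 1.54 quality-adjusted
life-years but over $500k in lifetime cost per patient, an ICER far above
the $150,000/QALY willingness-to-pay threshold; the daily price would have
to fall by more than half before adjuvant use becomes cost-effective. A
1,000-draw PSA (`sc.run_psa(inputs)`) puts every draw in the north-east
quadrant of the cost-effectiveness plane — costlier and more effective —
with a 0% probability of cost-effectiveness at that threshold.

The same analyses are available from a shell:

```bash
survcea base-case
survcea tornado
survcea psa --n-draws 1000
survcea threshold
survcea report --out-dir results/report   # everything, plus plots
```

All parameters live in one YAML document
(`src/survcea/data/base_case.yaml`); pass `--config your.yaml` to rerun the
whole pipeline under modified prices, utilities or curves.

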