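# Methods

`survcea` implements a lifetime cost-utility model comparing three years of
adjuvant osimertinib (80 mg daily) against placebo in completely resected
stage IB–IIIA EGFR-mutated NSCLC, from the perspective of a U.S. payer, plus
the upstream machinery needed to rebuild its survival inputs from published
Kaplan–Meier figures.

## Survival extrapolation

Disease-free survival (DFS) and overall survival (OS) in each arm are
represented by closed-form parametric distributions with time in months.
Seven families are supported (exponential, Weibull, gamma, generalized
gamma, log-normal, log-logistic, Gompertz). The shipped base case uses the
fitted curves printed with the analysis inputs:

| curve | family | parameters |
|---|---|---|
| DFS, osimertinib | log-logistic | shape 1.63351, scale 112.73457 |
| DFS, placebo | generalized gamma | mu 2.88767, sigma 1.45261, Q −1.30760 |
| OS, osimertinib | generalized gamma | mu 4.36038, sigma 1.26750, Q −3.13596 |
| OS, placebo | log-normal | meanlog 4.83614, sdlog 1.01581 |

Two conventions are deliberate choices, because fitted parameter tables of
this kind rarely state them:

* **Time unit is months.** The implied medians (log-logistic 112.7,
  log-normal ≈ 126.0) are clinically plausible for this population in
  months and absurd in weeks or cycles.
* **The generalized gamma uses the Prentice (mu, sigma, Q) form**, the
  parameterization under which published extrapolation triplets are
  reported (and the one `flexsurv` uses). With w = (log t − mu)/sigma and
  γ = Q⁻²: S(t) = P(γ, γe^{Qw}) for Q < 0 and 1 − P(γ, γe^{Qw}) for Q > 0,
  where P is the regularized lower incomplete gamma function. |Q| < 1e-6 is
  evaluated on the log-normal limit branch. Q = 1 reduces to a Weibull with
  shape 1/sigma and scale e^mu; both limits are verified to 1e-5 in tests,
  and the Q < 0 branch is cross-checked against R `flexsurv::pgengamma`.

## Pseudo-IPD reconstruction and refitting

`reconstruct_ipd` inverts a digitized KM step curve plus numbers-at-risk
table into individual event/censoring times, in the spirit of the published
curve-regeneration algorithms used for this kind of analysis. Within each
inter-risk-time interval the censored count is found by fixed-point
iteration starting from zero (corrected each pass by the at-risk mismatch),
censoring times are spread uniformly over the interval, and events at each
digitized step are the rounded product-limit drops; events precede
censorings at ties, and remaining patients are administratively censored at
the window end. Small overshoots of an at-risk target (rounding/digitizer
noise) are absorbed by trimming the latest events; overshoots beyond
max(2, 5% of the interval's starting at-risk count) raise a validation
error naming the interval. The construction is exact when the curve encodes
no censoring, and round-trips within the 1/n discretization in general.

`fit_family` maximizes the right-censored log-likelihood
Σ_events log f(t) + Σ_censored log S(t) by L-BFGS on transformed
parameters (positive parameters on the log scale; gengamma Q free), from
method-of-moments starts plus two seeded jittered restarts and, for the
gengamma, starts at Q ∈ {−1, 0.5, 1}. Model choice reports AIC and BIC;
selection defaults to AIC with ties broken by parsimony then family name.
The end-to-end chain (simulate → digitize → reconstruct → refit) recovers
the base-case log-logistic parameters within 10% at n = 2,000.

## Cohort model

A discrete-time three-state cohort (disease-free, recurrence, dead) runs
over 275 cycles of 21 days (21/30.4375 months; ≈ 15.8 years, carrying a
63-year-old cohort to the 78.8-year U.S. life expectancy). The per-cycle
death probability is the OS curve's conditional probability floored at the
age-specific background probability from a bundled abridged period life
table (ages 60–100, annual q converted by 1 − (1 − q)^(Δ/1yr)); the table
is a synthetic stand-in hard-coded from public U.S. period life-table
values. Only ages 63–79 are reached over the horizon, where the floor is
small relative to the modelled hazards.

Two occupancy constructions are provided:

* **`markov` (default).** Each cycle, every alive patient faces the floored
  OS death probability; disease-free survivors additionally face the DFS
  curve's conditional event probability as a recurrence transition. The
  products telescope to dfs = S_DFS·S_OS*, dead = 1 − S_OS*. This treats
  the whole DFS hazard as a recurrence hazard (the deaths inside the DFS
  composite are double-counted into recurrence occupancy), which is how
  three-state transition models built directly from a DFS and an OS curve
  are typically wired, and it is the construction that reproduces the
  published base-case results — in particular the placebo arm's recurrence
  time and hence its lifetime cost.
* **`partition`.** Partitioned-survival occupancy read directly off the
  curves (dfs = S_DFS, recurrence = S_OS* − S_DFS clipped at 0, with a
  warning if the DFS curve exceeds adjusted OS by more than 0.02). It
  reproduces the DFS curve exactly but understates recurrence occupancy
  whenever DFS events are deaths; with these inputs it understates the
  placebo arm's lifetime cost by roughly 25–30%.

Outcomes are discounted at 3%/year. Half-cycle correction evaluates
continuous accruals at the mean of start- and end-of-cycle occupancy,
discounted at mid-cycle; point events (scheduled disease-free assessments,
terminal care) use the boundary occupancy and cycle-end discount.

## Valuation

Utilities: 0.83 (disease-free), 0.74 (recurrence), 0 (death), per year
alive. Costs (2023 USD): osimertinib $566.64 per 80 mg day for the first 52
complete cycles (52 × 21 days ≈ 3 years) while disease-free; after
recurrence, 67.1% (osimertinib arm) / 66.3% (placebo arm) receive
pemetrexed (500 mg/m²) plus cisplatin (75 mg/m²) induction for four cycles
then pemetrexed maintenance while in state, doses at BSA 1.82 m² rounded up
to 10 mg billing units ($7.51 / $3.17 per 10 mg); the remainder receive
best supportive care at $481.57/cycle. Because the cohort does not track
time-in-state, the induction window is approximated by convolving positive
occupancy increments (new entrants) over four cycles, clipped at total
occupancy — the cisplatin component this gates is < 1% of recurrence costs.
Recurrence-state administration ($155.09), laboratory ($340.20) and
physician visit ($160.20) accrue every cycle and imaging ($249.48) every
second cycle; disease-free assessments (imaging + laboratory + physician)
fall at cycles 4 and 8 (weeks 12 and 24), every 8 cycles through cycle 80
(≈ 5 years), then every 17 cycles (annually) — nearest-cycle rounding of
the stated calendar. Terminal care ($10,187.64) attaches once to incident
deaths in their cycle of death. Adverse-event costs and disutilities are
exactly zero, mirroring the source analysis's finding of no grade ≥ 3 event
above 5% incidence. The ICER is Δcost/ΔQALY; non-positive QALY gains return
a dominance classification instead of a ratio.

## Sensitivity analyses

Sampled/varied quantities never touch the survival curves, so both arms'
traces are computed once and reused. One-way analysis moves each parameter
across its plausible range (utilities 0.67–0.99 and 0.59–0.89; discount
rate 0–5%; everything else ±20% of baseline) and ranks ICER spreads. The
PSA draws costs from gamma, utilities and proportions from beta, and BSA
from normal distributions, each moment-matched to the baseline mean with
sd = (max − min)/(2·1.96) — i.e. the plausible range is read as a central
95% interval, one convention for all families. The discount rate and the
survival parameters (for which no distributions are given) are fixed in the
PSA. With sd instead set to 20% of baseline, a handful of draws per
thousand cross into cost-effectiveness at $150,000/QALY, contradicting the
published all-points-in-the-first-quadrant scatter; the range-calibrated
convention reproduces it across seeds. Threshold pricing bisects the daily
drug price until the recomputed ICER hits the willingness-to-pay threshold
to a relative tolerance of 1e-6.

## Synthetic data

`simulate_ipd` draws event times by inverse-transform sampling, with
uniform accrual (default 24 months) and administrative cutoff, plus an
optional exponential drop-out hazard; `digitize` emits the KM step curve at
its step points with an exact at-risk table and optional truncated-Gaussian
jitter (re-monotonized) emulating manual graph digitization. Synthetic
arms exercise sampling correctness (moment and KS checks), reconstruction
round trips and parameter recovery; they do not emulate recurrence-to-death
trajectories (the engine is cohort-level), delayed treatment effects or
informative censoring, so passing tests validate the pipeline's mechanics
and the model's arithmetic, not the clinical fidelity of the extrapolation.

## Numerical and scale choices

The default analysis sizes are those of the base case itself: 275 cycles,
1,000 PSA draws, and n = 2,000 for the recovery study; everything runs in
seconds. Reproduction of the published results is tolerance-banded (QALYs
within 5%, incremental QALYs 10%, costs/ICER/threshold price 15%) because
several accrual details are not fully specified in the source: the
chemotherapy stopping rule, the week→cycle rounding of the monitoring
calendar, and the life-table values. Known limitations: no adverse-event
or societal costs by design; no covariate-adjusted or spline/cure-fraction
extrapolation; the recurrence state has a single cost profile regardless of
time since entry beyond the induction window.
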