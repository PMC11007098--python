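"""One-way (tornado) and probabilistic sensitivity analysis, CEAC and
threshold-price search.

The sampled and varied quantities (unit costs, utilities, proportions, body
surface area, discount rate) affect only valuation, never the survival
curves, so both arms' occupancy traces are computed once and reused across
all scenario evaluations.  PSA distributions are moment-matched to the
baseline mean with a standard deviation of (max - min)/(2 * 1.96), i.e. the
stated plausible range (generally +/-20% of baseline) is treated as a
central 95% interval; one convention for all sampled parameters (gamma,
beta and normal alike).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CohortTrace, run_cohort
from .params import EconomicInputs, ParameterSpec, parameter_specs
from .valuation import ArmResult, IncrementalResult, accrue_arm, compute_icer

__all__ = [
    "BaseCaseResult",
    "base_case",
    "one_way_tornado",
    "run_psa",
    "ceac",
    "threshold_price",
]



@dataclass(frozen=True)
class BaseCaseResult:
    active: ArmResult
    control: ArmResult
    incremental: IncrementalResult


def _traces(inputs: EconomicInputs) -> tuple[CohortTrace, CohortTrace]:
    s = inputs.survival
    active = run_cohort(inputs.spec, s.dfs_active, s.os_active, inputs.life_table)
    control = run_cohort(inputs.spec, s.dfs_control, s.os_control, inputs.life_table)
    return active, control


def _evaluate(
    inputs: EconomicInputs, traces: tuple[CohortTrace, CohortTrace]
) -> BaseCaseResult:
    tr_a, tr_c = traces
    active = accrue_arm(tr_a, inputs.spec, inputs.costs, inputs.utilities, inputs.schedule, "active")
    control = accrue_arm(tr_c, inputs.spec, inputs.costs, inputs.utilities, inputs.schedule, "control")
    return BaseCaseResult(active, control, compute_icer(active, control))


def base_case(inputs: EconomicInputs) -> BaseCaseResult:
    """Run both arms at baseline and form the incremental result."""
    return _evaluate(inputs, _traces(inputs))


def one_way_tornado(inputs: EconomicInputs) -> pd.DataFrame:
    """Re-run the model with each uncertain parameter at its lower and
    upper bound (all others at baseline); rows sorted by descending ICER
    spread."""
    traces = _traces(inputs)
    base = _evaluate(inputs, traces)
    rows = []
    for p in parameter_specs(inputs):
        icer_lo = _evaluate(p.apply(inputs, p.low), traces).incremental.icer
        icer_hi = _evaluate(p.apply(inputs, p.high), traces).incremental.icer
        rows.append(
            {
                "parameter": p.name,
                "low": p.low,
                "high": p.high,
                "icer_at_min": icer_lo,
                "icer_at_max": icer_hi,
                "spread": abs(icer_hi - icer_lo),
            }
        )
    df = pd.DataFrame(rows).sort_values("spread", ascending=False, kind="stable")
    df.attrs["base_icer"] = base.incremental.icer
    return df.reset_index(drop=True)


def _sample(p: ParameterSpec, rng: np.random.Generator, size: int) -> np.ndarray:
    if p.dist == "fixed":
        return np.full(size, p.baseline)
    sd = (p.high - p.low) / (2 * 1.96)
    if p.dist == "gamma":
        shape = (p.baseline / sd) ** 2
        return rng.gamma(shape, p.baseline / shape, size)
    if p.dist == "beta":
        m = p.baseline
        if sd**2 >= m * (1 - m):
            raise ValueError(
                f"beta moments infeasible for {p.name}: mean {m}, sd {sd}"
            )
        nu = m * (1 - m) / sd**2 - 1
        return rng.beta(m * nu, (1 - m) * nu, size)
    if p.dist == "normal":
        return rng.normal(p.baseline, sd, size)
    raise ValueError(f"unknown distribution {p.dist!r}")


def run_psa(
    inputs: EconomicInputs,
    n_draws: int | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Monte Carlo resampling of all uncertain parameters.

    Returns one row per draw with every sampled parameter value plus the
    resulting incremental cost and QALYs; bit-reproducible for a fixed
    seed.
    """
    n = n_draws if n_draws is not None else inputs.psa_draws
    rng = np.random.default_rng(seed if seed is not None else inputs.psa_seed)
    specs = [p for p in parameter_specs(inputs) if p.dist != "fixed"]
    draws = {p.name: _sample(p, rng, n) for p in specs}
    traces = _traces(inputs)
    rows = []
    for i in range(n):
        scen = inputs
        for p in specs:
            scen = p.apply(scen, float(draws[p.name][i]))
        res = _evaluate(scen, traces)
        row = {p.name: draws[p.name][i] for p in specs}
        row["delta_cost"] = res.incremental.delta_cost
        row["delta_qalys"] = res.incremental.delta_qalys
        rows.append(row)
    return pd.DataFrame(rows)


def ceac(samples: pd.DataFrame, wtp_grid) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve: at each willingness-to-pay,
    the fraction of draws with positive net monetary benefit
    ``wtp * dQALY - dCost``."""
    if samples.empty:
        raise ValueError("no PSA samples")
    dq = samples["delta_qalys"].to_numpy()
    dc = samples["delta_cost"].to_numpy()
    rows = [
        {"wtp": float(w), "prob_cost_effective": float(np.mean(w * dq - dc > 0))}
        for w in np.asarray(wtp_grid, dtype=float)
    ]
    return pd.DataFrame(rows)


def threshold_price(
    inputs: EconomicInputs,
    wtp: float | None = None,
    rel_tol: float = 1e-6,
    max_iter: int = 200,
) -> float:
    """Daily 80 mg drug price at which the base-case ICER equals the
    willingness-to-pay threshold, found by bisection with all other inputs
    at baseline."""
    wtp = wtp if wtp is not None else inputs.wtp
    traces = _traces(inputs)
    price_spec = next(
        p for p in parameter_specs(inputs) if p.name == "cost_osimertinib_80mg"
    )

    def icer_at(price: float) -> float:
        res = _evaluate(price_spec.apply(inputs, price), traces)
        if res.incremental.icer is None:
            raise RuntimeError("ICER undefined during threshold search")
        return res.incremental.icer

    lo, hi = 0.0, price_spec.baseline
    f_lo, f_hi = icer_at(lo), icer_at(hi)
    while f_hi < wtp:  # expand upward if the baseline ICER is below WTP
        hi *= 2.0
        f_hi = icer_at(hi)
        if hi > 1e7:
            raise RuntimeError("failed to bracket the threshold price")
    if f_lo > wtp:
        raise RuntimeError(
            f"no bracket: ICER at zero price {f_lo:.2f} already exceeds WTP {wtp:.2f}"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f_mid = icer_at(mid)
        if abs(f_mid - wtp) / wtp < rel_tol:
            return mid
        if f_mid < wtp:
            lo = mid
        else:
            hi = mid
    raise RuntimeError("threshold-price bisection did not converge")
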