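"""Cost and QALY accrual over a cohort trace, and incremental results.

Accrual conventions
-------------------
* Continuous accruals (drug, chemotherapy, best supportive care, per-cycle
  recurrence monitoring, utilities) use half-cycle-corrected occupancy (the
  mean of the cycle's start and end boundary) discounted at mid-cycle.
* Point events (scheduled disease-free assessments, terminal care at death)
  use the occupancy of the triggering boundary / the incident deaths of the
  cycle, discounted at the event cycle.
* Active-arm drug cost runs while disease-free, for the first 52 complete
  cycles (52 x 21 days ~ 3 years).
* Subsequent therapy in recurrence follows pemetrexed + cisplatin induction
  for four cycles then pemetrexed maintenance, for the subsequent-therapy
  fraction; the remaining fraction accrues best supportive care.  Doses are
  rounded up to whole 10 mg billing units.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CohortTrace, ModelSpec

__all__ = [
    "UtilityInputs",
    "CostInputs",
    "MonitoringSchedule",
    "ArmResult",
    "IncrementalResult",
    "default_dfs_schedule",
    "accrue_arm",
    "compute_icer",
]


@dataclass(frozen=True)
class UtilityInputs:
    """Per-year utility weights of the three health states."""

    dfs: float = 0.83
    recurrence: float = 0.74
    death: float = 0.0

    def __post_init__(self) -> None:
        for name in ("dfs", "recurrence", "death"):
            u = getattr(self, name)
            if not 0.0 <= u <= 1.0:
                raise ValueError(f"utility {name} must lie in [0, 1]")


@dataclass(frozen=True)
class CostInputs:
    """Unit costs (2023 USD) and dosing inputs."""

    osimertinib_per_80mg_day: float = 566.64
    pemetrexed_per_10mg: float = 7.51
    cisplatin_per_10mg: float = 3.17
    administration_per_cycle: float = 155.09
    imaging_per_event: float = 249.48
    laboratory_per_event: float = 340.20
    terminal_care_once: float = 10187.64
    physician_visit_per_event: float = 160.20
    bsc_per_cycle: float = 481.57
    body_surface_area: float = 1.82
    subsequent_therapy_fraction_active: float = 0.671
    subsequent_therapy_fraction_control: float = 0.663
    pemetrexed_mg_per_m2: float = 500.0
    cisplatin_mg_per_m2: float = 75.0

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"cost input {name} must be >= 0")
        for name in (
            "subsequent_therapy_fraction_active",
            "subsequent_therapy_fraction_control",
        ):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")

    def chemo_dose_cost(self, drug: str) -> float:
        """Per-cycle cost of one chemotherapy drug, dose rounded up to the
        next 10 mg billing unit."""
        if drug == "pemetrexed":
            mg, unit = self.pemetrexed_mg_per_m2 * self.body_surface_area, self.pemetrexed_per_10mg
        elif drug == "cisplatin":
            mg, unit = self.cisplatin_mg_per_m2 * self.body_surface_area, self.cisplatin_per_10mg
        else:
            raise ValueError(drug)
        return math.ceil(mg / 10.0) * unit


def default_dfs_schedule(n_cycles: int = 275) -> tuple[int, ...]:
    """Disease-free assessment cycles: weeks 12 and 24 (cycles 4 and 8),
    then every 24 weeks (8 cycles) through year 5 (cycle 87), then annually
    (every 17 cycles)."""
    cycles = [4, 8]
    k = 8
    while k + 8 <= 87:
        k += 8
        cycles.append(k)
    while k + 17 <= n_cycles:
        k += 17
        cycles.append(k)
    return tuple(cycles)


@dataclass(frozen=True)
class MonitoringSchedule:
    """Resource-use schedule: scheduled assessments while disease-free and
    per-cycle events in the recurrence state."""

    dfs_assessment_cycles: tuple[int, ...] = field(default_factory=default_dfs_schedule)
    recurrence_imaging_every: int = 2
    induction_cycles: int = 4
    maintenance_cap_cycles: int | None = None  # None = while in state

    def __post_init__(self) -> None:
        if any(c < 1 for c in self.dfs_assessment_cycles):
            raise ValueError("schedule cycles must be >= 1")
        if self.recurrence_imaging_every < 1:
            raise ValueError("recurrence_imaging_every must be >= 1")


@dataclass(frozen=True)
class ArmResult:
    """Discounted totals and per-cycle streams for one arm."""

    arm: str
    total_cost: float
    total_qalys: float
    cost_stream: np.ndarray
    qaly_stream: np.ndarray
    components: dict[str, float]

    def summary(self) -> pd.Series:
        return pd.Series(
            {"arm": self.arm, "total_cost": self.total_cost, "total_qalys": self.total_qalys}
        )


def _entrant_window_occupancy(rec: np.ndarray, window: int) -> np.ndarray:
    """Approximate occupancy of patients within their first `window` cycles
    in the recurrence state, from net incident entrants.  Cohort traces do
    not track time-in-state, so entrants are approximated by positive
    occupancy increments and assumed to remain in state over the short
    window; the result is clipped at total occupancy."""
    entrants = np.maximum(np.diff(rec, prepend=0.0), 0.0)
    kernel = np.ones(window)
    in_window = np.convolve(entrants, kernel)[: len(rec)]
    return np.minimum(in_window, rec)


def accrue_arm(
    trace: CohortTrace,
    spec: ModelSpec,
    costs: CostInputs,
    utils: UtilityInputs,
    sched: MonitoringSchedule,
    arm: str,
) -> ArmResult:
    """Accrue discounted costs and QALYs for one arm over its trace."""
    if arm not in ("active", "control"):
        raise ValueError("arm must be 'active' or 'control'")
    n = trace.n_cycles
    if max(sched.dfs_assessment_cycles, default=0) > n:
        raise ValueError("monitoring schedule extends beyond the model horizon")

    k = np.arange(1, n + 1)
    r = spec.annual_discount_rate
    if spec.half_cycle_correction:
        dfs_occ = trace.mid("dfs")
        rec_occ = trace.mid("recurrence")
        disc_flow = (1.0 + r) ** (-(k - 0.5) * spec.cycle_years)
    else:
        dfs_occ = trace.dfs[1:]
        rec_occ = trace.recurrence[1:]
        disc_flow = (1.0 + r) ** (-k * spec.cycle_years)
    disc_event = (1.0 + r) ** (-k * spec.cycle_years)

    # --- QALYs -------------------------------------------------------
    qaly_stream = (
        (utils.dfs * dfs_occ + utils.recurrence * rec_occ)
        * spec.cycle_years
        * disc_flow
    )

    comp: dict[str, np.ndarray] = {}

    # --- active-arm drug ---------------------------------------------
    drug = np.zeros(n)
    if arm == "active":
        on_tx = k <= spec.treatment_cap_cycles
        drug[on_tx] = (
            costs.osimertinib_per_80mg_day
            * spec.cycle_length_days
            * dfs_occ[on_tx]
            * disc_flow[on_tx]
        )
    comp["drug_active"] = drug

    # --- recurrence-state subsequent therapy -------------------------
    frac = (
        costs.subsequent_therapy_fraction_active
        if arm == "active"
        else costs.subsequent_therapy_fraction_control
    )
    pem = costs.chemo_dose_cost("pemetrexed")
    cis = costs.chemo_dose_cost("cisplatin")
    induction = _entrant_window_occupancy(trace.recurrence, sched.induction_cycles)
    induction_occ = np.minimum(0.5 * (induction[:-1] + induction[1:]), rec_occ)
    if sched.maintenance_cap_cycles is None:
        chemo_occ = rec_occ
    else:
        window = _entrant_window_occupancy(
            trace.recurrence, sched.maintenance_cap_cycles
        )
        chemo_occ = np.minimum(0.5 * (window[:-1] + window[1:]), rec_occ)
    comp["chemotherapy"] = frac * (pem * chemo_occ + cis * induction_occ) * disc_flow
    comp["bsc"] = (1.0 - frac) * costs.bsc_per_cycle * rec_occ * disc_flow

    # --- recurrence-state monitoring ---------------------------------
    per_cycle_monitoring = (
        costs.administration_per_cycle
        + costs.laboratory_per_event
        + costs.physician_visit_per_event
    )
    rec_monitor = per_cycle_monitoring * rec_occ * disc_flow
    imaging_cycles = (k % sched.recurrence_imaging_every) == 0
    rec_monitor = rec_monitor + np.where(
        imaging_cycles, costs.imaging_per_event * rec_occ * disc_flow, 0.0
    )
    comp["recurrence_monitoring"] = rec_monitor

    # --- disease-free scheduled assessments --------------------------
    dfs_monitor = np.zeros(n)
    assess_cost = (
        costs.imaging_per_event
        + costs.laboratory_per_event
        + costs.physician_visit_per_event
    )
    for c in sched.dfs_assessment_cycles:
        dfs_monitor[c - 1] = assess_cost * trace.dfs[c] * disc_event[c - 1]
    comp["dfs_monitoring"] = dfs_monitor

    # --- terminal care -----------------------------------------------
    comp["terminal_care"] = (
        costs.terminal_care_once * trace.incident_deaths[1:] * disc_flow
    )

    cost_stream = sum(comp.values())
    return ArmResult(
        arm=arm,
        total_cost=float(cost_stream.sum()),
        total_qalys=float(qaly_stream.sum()),
        cost_stream=cost_stream,
        qaly_stream=qaly_stream,
        components={name: float(v.sum()) for name, v in comp.items()},
    )


@dataclass(frozen=True)
class IncrementalResult:
    """Incremental cost, QALYs and their ratio for active vs control."""

    delta_cost: float
    delta_qalys: float
    icer: float | None
    classification: str

    def as_dict(self) -> dict:
        return {
            "delta_cost": self.delta_cost,
            "delta_qalys": self.delta_qalys,
            "icer": self.icer,
            "classification": self.classification,
        }


def compute_icer(active: ArmResult, control: ArmResult) -> IncrementalResult:
    """Incremental cost-effectiveness of the active arm versus control.

    When the active arm gains no QALYs the ratio is undefined and a
    dominance classification is returned instead: "equivalent" (both deltas
    ~0), "dominant" (cheaper, no QALY loss... strictly: non-positive cost
    delta with non-negative QALY delta), or "dominated" (costlier with a
    QALY loss).
    """
    dc = active.total_cost - control.total_cost
    dq = active.total_qalys - control.total_qalys
    tol = 1e-12
    if abs(dc) < tol and abs(dq) < tol:
        return IncrementalResult(dc, dq, None, "equivalent")
    if dq > tol:
        if dc <= 0:
            return IncrementalResult(dc, dq, dc / dq, "dominant")
        return IncrementalResult(dc, dq, dc / dq, "icer")
    if dc > 0:
        return IncrementalResult(dc, dq, None, "dominated")
    return IncrementalResult(dc, dq, None, "dominant" if dq >= -tol else "southwest")
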