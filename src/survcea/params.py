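"""Typed parameter registry and serialization.

The base case ships as a YAML document (``survcea/data/base_case.yaml``)
holding the fitted survival curves, utilities, unit costs and structural
model settings; :func:`load_inputs` turns it into a validated
:class:`EconomicInputs` bundle.  :func:`parameter_specs` derives the list of
uncertain parameters (baseline, range, sampling distribution) used by the
one-way and probabilistic sensitivity analyses.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable

import yaml

from .cohort import LifeTable, ModelSpec, us_life_table
from .survival import FAMILIES, PARAM_NAMES, BaseCaseSurvivalSet, ParametricSurvival
from .valuation import CostInputs, MonitoringSchedule, UtilityInputs

__all__ = [
    "EconomicInputs",
    "ParameterSpec",
    "load_inputs",
    "default_inputs",
    "parameter_specs",
    "dump_inputs",
]


@dataclass(frozen=True)
class EconomicInputs:
    """Everything needed to run the full analysis."""

    spec: ModelSpec
    survival: BaseCaseSurvivalSet
    costs: CostInputs
    utilities: UtilityInputs
    schedule: MonitoringSchedule
    life_table: LifeTable
    wtp: float = 150_000.0
    psa_draws: int = 1000
    psa_seed: int = 20240328
    ranges: dict[str, tuple[float, float]] = field(default_factory=dict)

    def replace(self, **kw) -> "EconomicInputs":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class ParameterSpec:
    """One uncertain scalar input: its baseline, plausible range, sampling
    family for the PSA, and how to apply a value to the input bundle."""

    name: str
    baseline: float
    low: float
    high: float
    dist: str  # gamma | beta | normal | fixed
    apply: Callable[[EconomicInputs, float], EconomicInputs]


def _curve(doc: dict) -> ParametricSurvival:
    doc = dict(doc)
    family = doc.pop("family")
    if family not in FAMILIES:
        raise ValueError(f"unknown survival family {family!r} in parameter document")
    missing = set(PARAM_NAMES[family]) - set(doc)
    if missing:
        raise ValueError(f"{family} curve is missing parameters {sorted(missing)}")
    return ParametricSurvival(family, {k: float(v) for k, v in doc.items()})


def load_inputs(path=None) -> EconomicInputs:
    """Load a parameter document (YAML); default is the shipped base case."""
    if path is None:
        text = (
            resources.files("survcea").joinpath("data/base_case.yaml").read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    doc = yaml.safe_load(text)

    m = doc.get("model", {})
    spec = ModelSpec(
        cycle_length_days=m.get("cycle_length_days", 21.0),
        n_cycles=m.get("n_cycles", 275),
        annual_discount_rate=m.get("annual_discount_rate", 0.03),
        start_age=m.get("start_age", 63.0),
        life_expectancy_cap=m.get("life_expectancy_cap", 78.8),
        half_cycle_correction=m.get("half_cycle_correction", True),
        treatment_cap_cycles=m.get("treatment_cap_cycles", 52),
        mode=m.get("mode", "markov"),
    )
    surv = doc["survival"]
    survival = BaseCaseSurvivalSet(
        dfs_active=_curve(surv["dfs_active"]),
        dfs_control=_curve(surv["dfs_control"]),
        os_active=_curve(surv["os_active"]),
        os_control=_curve(surv["os_control"]),
    )
    u = doc.get("utilities", {})
    utilities = UtilityInputs(
        dfs=u.get("dfs", 0.83), recurrence=u.get("recurrence", 0.74), death=u.get("death", 0.0)
    )
    costs = CostInputs(**doc.get("costs", {}))
    sched_doc = doc.get("schedule", {})
    schedule = MonitoringSchedule(
        dfs_assessment_cycles=tuple(
            sched_doc.get("dfs_assessment_cycles", MonitoringSchedule().dfs_assessment_cycles)
        ),
        recurrence_imaging_every=sched_doc.get("recurrence_imaging_every", 2),
        induction_cycles=sched_doc.get("induction_cycles", 4),
        maintenance_cap_cycles=sched_doc.get("maintenance_cap_cycles"),
    )
    lt_doc = doc.get("life_table")
    life_table = (
        LifeTable([r["age"] for r in lt_doc], [r["q"] for r in lt_doc])
        if lt_doc
        else us_life_table()
    )
    ranges = {k: (float(v[0]), float(v[1])) for k, v in doc.get("ranges", {}).items()}
    psa = doc.get("psa", {})
    return EconomicInputs(
        spec=spec,
        survival=survival,
        costs=costs,
        utilities=utilities,
        schedule=schedule,
        life_table=life_table,
        wtp=doc.get("wtp", 150_000.0),
        psa_draws=psa.get("n_draws", 1000),
        psa_seed=psa.get("seed", 20240328),
        ranges=ranges,
    )


def default_inputs() -> EconomicInputs:
    """The shipped base case."""
    return load_inputs(None)


def dump_inputs(inputs: EconomicInputs, path) -> None:
    """Serialize an input bundle back to YAML."""
    doc = {
        "model": {
            "cycle_length_days": inputs.spec.cycle_length_days,
            "n_cycles": inputs.spec.n_cycles,
            "annual_discount_rate": inputs.spec.annual_discount_rate,
            "start_age": inputs.spec.start_age,
            "life_expectancy_cap": inputs.spec.life_expectancy_cap,
            "half_cycle_correction": inputs.spec.half_cycle_correction,
            "treatment_cap_cycles": inputs.spec.treatment_cap_cycles,
            "mode": inputs.spec.mode,
        },
        "survival": {
            name: {"family": c.family, **c.params}
            for name, c in (
                ("dfs_active", inputs.survival.dfs_active),
                ("dfs_control", inputs.survival.dfs_control),
                ("os_active", inputs.survival.os_active),
                ("os_control", inputs.survival.os_control),
            )
        },
        "utilities": {
            "dfs": inputs.utilities.dfs,
            "recurrence": inputs.utilities.recurrence,
            "death": inputs.utilities.death,
        },
        "costs": {f: getattr(inputs.costs, f) for f in inputs.costs.__dataclass_fields__},
        "schedule": {
            "dfs_assessment_cycles": list(inputs.schedule.dfs_assessment_cycles),
            "recurrence_imaging_every": inputs.schedule.recurrence_imaging_every,
            "induction_cycles": inputs.schedule.induction_cycles,
            "maintenance_cap_cycles": inputs.schedule.maintenance_cap_cycles,
        },
        "ranges": {k: list(v) for k, v in inputs.ranges.items()},
        "wtp": inputs.wtp,
        "psa": {"n_draws": inputs.psa_draws, "seed": inputs.psa_seed},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def _cost_setter(fieldname: str):
    def apply(inputs: EconomicInputs, value: float) -> EconomicInputs:
        return inputs.replace(costs=dataclasses.replace(inputs.costs, **{fieldname: value}))

    return apply


def _utility_setter(fieldname: str):
    def apply(inputs: EconomicInputs, value: float) -> EconomicInputs:
        return inputs.replace(
            utilities=dataclasses.replace(inputs.utilities, **{fieldname: value})
        )

    return apply


def _discount_setter(inputs: EconomicInputs, value: float) -> EconomicInputs:
    return inputs.replace(spec=dataclasses.replace(inputs.spec, annual_discount_rate=value))


def parameter_specs(inputs: EconomicInputs) -> list[ParameterSpec]:
    """Uncertain parameters for the tornado and the PSA.

    Costs follow gamma distributions, utilities and proportions beta, body
    surface area normal; the discount rate is varied in the tornado but held
    fixed in the PSA.  Ranges default to +/-20% of baseline unless the
    parameter document names an explicit range (utilities and the discount
    rate do).
    """
    c, u = inputs.costs, inputs.utilities

    def rng(name: str, baseline: float) -> tuple[float, float]:
        if name in inputs.ranges:
            return inputs.ranges[name]
        return 0.8 * baseline, 1.2 * baseline

    rows: list[tuple[str, float, str, Callable]] = [
        ("utility_dfs", u.dfs, "beta", _utility_setter("dfs")),
        ("utility_recurrence", u.recurrence, "beta", _utility_setter("recurrence")),
        ("cost_osimertinib_80mg", c.osimertinib_per_80mg_day, "gamma", _cost_setter("osimertinib_per_80mg_day")),
        ("cost_pemetrexed_10mg", c.pemetrexed_per_10mg, "gamma", _cost_setter("pemetrexed_per_10mg")),
        ("cost_cisplatin_10mg", c.cisplatin_per_10mg, "gamma", _cost_setter("cisplatin_per_10mg")),
        ("cost_administration_cycle", c.administration_per_cycle, "gamma", _cost_setter("administration_per_cycle")),
        ("cost_imaging", c.imaging_per_event, "gamma", _cost_setter("imaging_per_event")),
        ("cost_laboratory", c.laboratory_per_event, "gamma", _cost_setter("laboratory_per_event")),
        ("cost_terminal_care", c.terminal_care_once, "gamma", _cost_setter("terminal_care_once")),
        ("cost_physician_visit", c.physician_visit_per_event, "gamma", _cost_setter("physician_visit_per_event")),
        ("cost_bsc_cycle", c.bsc_per_cycle, "gamma", _cost_setter("bsc_per_cycle")),
        ("body_surface_area", c.body_surface_area, "normal", _cost_setter("body_surface_area")),
        ("subsequent_therapy_fraction_active", c.subsequent_therapy_fraction_active, "beta", _cost_setter("subsequent_therapy_fraction_active")),
        ("subsequent_therapy_fraction_control", c.subsequent_therapy_fraction_control, "beta", _cost_setter("subsequent_therapy_fraction_control")),
        ("discount_rate", inputs.spec.annual_discount_rate, "fixed", _discount_setter),
    ]
    specs = []
    for name, baseline, dist, setter in rows:
        low, high = rng(name, baseline)
        if not low <= baseline <= high:
            raise ValueError(f"range for {name} does not bracket its baseline")
        specs.append(ParameterSpec(name, baseline, low, high, dist, setter))
    return specs
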