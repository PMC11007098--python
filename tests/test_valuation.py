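"""Cost/QALY accrual identities and incremental-result semantics."""
import dataclasses

import numpy as np
import pytest

import survcea as sc
from survcea.valuation import ArmResult, default_dfs_schedule


def zero_costs():
    fields = {
        f: 0.0
        for f in sc.CostInputs.__dataclass_fields__
        if f not in ("body_surface_area", "pemetrexed_mg_per_m2", "cisplatin_mg_per_m2")
    }
    return sc.CostInputs(body_surface_area=1.82, **fields)


def test_zero_unit_costs_zero_total_cost(base_traces, base_inputs):
    res = sc.accrue_arm(
        base_traces[0], base_inputs.spec, zero_costs(), base_inputs.utilities,
        base_inputs.schedule, "active",
    )
    assert res.total_cost == 0.0
    ref = sc.accrue_arm(
        base_traces[0], base_inputs.spec, base_inputs.costs, base_inputs.utilities,
        base_inputs.schedule, "active",
    )
    assert res.total_qalys == pytest.approx(ref.total_qalys, rel=1e-12)


def test_unit_utilities_no_discount_recover_life_years(base_inputs):
    spec0 = dataclasses.replace(base_inputs.spec, annual_discount_rate=0.0)
    s = base_inputs.survival
    tr = sc.run_cohort(spec0, s.dfs_active, s.os_active, base_inputs.life_table)
    res = sc.accrue_arm(
        tr, spec0, base_inputs.costs, sc.UtilityInputs(1.0, 1.0, 0.0),
        base_inputs.schedule, "active",
    )
    assert res.total_qalys == pytest.approx(tr.life_years(spec0), rel=1e-12)


def test_single_cycle_drug_cost_arithmetic():
    """One cycle fully disease-free, undiscounted: 21 days x $566.64."""
    spec = sc.ModelSpec(n_cycles=1, annual_discount_rate=0.0)
    tr = sc.CohortTrace(
        dfs=np.array([1.0, 1.0]),
        recurrence=np.zeros(2),
        dead=np.zeros(2),
        incident_deaths=np.zeros(2),
        ages=np.array([63.0, 63.06]),
    )
    sched = sc.MonitoringSchedule(dfs_assessment_cycles=())
    res = sc.accrue_arm(tr, spec, sc.CostInputs(), sc.UtilityInputs(), sched, "active")
    assert res.components["drug_active"] == pytest.approx(21 * 566.64, rel=1e-12)
    assert res.total_cost == pytest.approx(21 * 566.64, rel=1e-12)


def test_treatment_cap_stops_drug_cost(base_inputs, base_traces):
    res = sc.accrue_arm(
        base_traces[0], base_inputs.spec, base_inputs.costs, base_inputs.utilities,
        base_inputs.schedule, "active",
    )
    k = np.arange(1, base_inputs.spec.n_cycles + 1)
    # rebuild with a 10-cycle cap: the drug component must shrink
    capped_spec = dataclasses.replace(base_inputs.spec, treatment_cap_cycles=10)
    capped = sc.accrue_arm(
        base_traces[0], capped_spec, base_inputs.costs, base_inputs.utilities,
        base_inputs.schedule, "active",
    )
    assert capped.components["drug_active"] < res.components["drug_active"]
    assert (k > 52).any()


def test_control_arm_has_no_active_drug_cost(base_result):
    assert base_result.control.components["drug_active"] == 0.0


def test_cost_monotone_in_unit_prices(base_inputs, base_traces):
    base = sc.accrue_arm(
        base_traces[1], base_inputs.spec, base_inputs.costs, base_inputs.utilities,
        base_inputs.schedule, "control",
    )
    for fieldname in ("bsc_per_cycle", "laboratory_per_event", "terminal_care_once", "pemetrexed_per_10mg"):
        bumped = dataclasses.replace(
            base_inputs.costs, **{fieldname: getattr(base_inputs.costs, fieldname) * 1.5}
        )
        res = sc.accrue_arm(
            base_traces[1], base_inputs.spec, bumped, base_inputs.utilities,
            base_inputs.schedule, "control",
        )
        assert res.total_cost > base.total_cost


def test_discounting_shrinks_both_totals(base_inputs):
    s = base_inputs.survival
    for rate_lo, rate_hi in ((0.0, 0.03), (0.03, 0.05)):
        for arm, dfs, os_ in (("active", s.dfs_active, s.os_active), ("control", s.dfs_control, s.os_control)):
            res = {}
            for rate in (rate_lo, rate_hi):
                spec = dataclasses.replace(base_inputs.spec, annual_discount_rate=rate)
                tr = sc.run_cohort(spec, dfs, os_, base_inputs.life_table)
                res[rate] = sc.accrue_arm(
                    tr, spec, base_inputs.costs, base_inputs.utilities, base_inputs.schedule, arm
                )
            assert res[rate_lo].total_cost > res[rate_hi].total_cost
            assert res[rate_lo].total_qalys > res[rate_hi].total_qalys


def test_totals_equal_stream_sums(base_result):
    for arm in (base_result.active, base_result.control):
        assert arm.total_cost == pytest.approx(arm.cost_stream.sum(), rel=1e-12)
        assert arm.total_qalys == pytest.approx(arm.qaly_stream.sum(), rel=1e-12)
        assert arm.total_cost >= 0 and arm.total_qalys >= 0
        assert arm.total_cost == pytest.approx(sum(arm.components.values()), rel=1e-12)


def test_dfs_schedule_matches_stated_calendar():
    sched = default_dfs_schedule(275)
    assert sched[:2] == (4, 8)                      # weeks 12 and 24
    assert all(b - a == 8 for a, b in zip(sched[1:10], sched[2:11]))  # q24w to year 5
    assert max(c for c in sched if c <= 87) == 80
    annual = [c for c in sched if c > 87]
    assert all(b - a == 17 for a, b in zip(annual, annual[1:]))       # annual after
    assert max(sched) <= 275


def test_schedule_beyond_horizon_rejected(base_inputs, base_traces):
    sched = sc.MonitoringSchedule(dfs_assessment_cycles=(300,))
    with pytest.raises(ValueError, match="horizon"):
        sc.accrue_arm(
            base_traces[0], base_inputs.spec, base_inputs.costs, base_inputs.utilities,
            sched, "active",
        )


def _arm(cost, qalys):
    return ArmResult("x", cost, qalys, np.array([cost]), np.array([qalys]), {})


class TestIcer:
    def test_identical_arms_are_equivalent(self):
        a = _arm(1000.0, 2.0)
        inc = sc.compute_icer(a, _arm(1000.0, 2.0))
        assert inc.classification == "equivalent"
        assert inc.delta_cost == 0.0 and inc.delta_qalys == 0.0

    def test_printed_rounded_deltas(self):
        inc = sc.compute_icer(_arm(492_710.0, 8.05), _arm(0.0, 6.46))
        assert inc.icer == pytest.approx(309_880.50, abs=0.01)

    def test_dominated_classification(self):
        inc = sc.compute_icer(_arm(2000.0, 1.0), _arm(1000.0, 2.0))
        assert inc.classification == "dominated"
        assert inc.icer is None

    def test_dominant_classification(self):
        inc = sc.compute_icer(_arm(500.0, 3.0), _arm(1000.0, 2.0))
        assert inc.classification == "dominant"

    def test_icer_identity(self, base_result):
        inc = base_result.incremental
        assert inc.icer * inc.delta_qalys == pytest.approx(inc.delta_cost, abs=1e-9)
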