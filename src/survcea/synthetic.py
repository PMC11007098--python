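"""Trial-like synthetic data with known ground truth.

Emulates what the upstream stages consume: individual event/censoring
times drawn from a chosen parametric survival distribution under staggered
accrual with administrative cutoff (plus optional independent drop-out),
and "digitized" Kaplan-Meier artifacts — step-curve coordinates with
at-risk tables, optionally perturbed by truncated Gaussian jitter to mimic
graph-digitizer noise.  Everything is reproducible from a seed.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .km import DigitizedCurve, PseudoIPD, km_estimator
from .survival import ParametricSurvival

__all__ = ["TrialSimSpec", "simulate_ipd", "digitize"]


@dataclass(frozen=True)
class TrialSimSpec:
    """Generating model and follow-up design for one simulated arm.

    Patients accrue uniformly over ``accrual_months`` and are
    administratively censored at ``accrual_months + followup_months`` after
    study start, i.e. individual censoring times are uniform on
    [followup, followup + accrual] months.  ``dropout_rate`` adds an
    independent exponential loss-to-follow-up hazard (per month).
    """

    model: ParametricSurvival
    n: int = 250
    accrual_months: float = 24.0
    followup_months: float = 36.0
    dropout_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 10:
            raise ValueError("n must be >= 10")
        if self.accrual_months < 0 or self.followup_months < 0:
            raise ValueError("accrual and follow-up windows must be non-negative")
        if self.dropout_rate < 0:
            raise ValueError("dropout_rate must be >= 0")


def simulate_ipd(spec: TrialSimSpec) -> PseudoIPD:
    """Draw event times by inverse-transform sampling and apply censoring."""
    rng = np.random.default_rng(spec.seed)
    t_event = spec.model.rvs(spec.n, rng)
    entry = rng.uniform(0.0, spec.accrual_months, spec.n)
    t_admin = spec.accrual_months + spec.followup_months - entry
    if spec.dropout_rate > 0:
        t_drop = rng.exponential(1.0 / spec.dropout_rate, spec.n)
        t_cens = np.minimum(t_admin, t_drop)
    else:
        t_cens = t_admin
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    # guard against exactly-zero observation times (flat censoring window)
    time = np.maximum(time, 1e-9)
    return PseudoIPD(time, event)


def digitize(
    ipd: PseudoIPD,
    risk_times,
    jitter: float = 0.0,
    seed: int = 0,
) -> DigitizedCurve:
    """Turn IPD into a digitized-curve artifact.

    The KM step curve is sampled at its step points; with ``jitter`` > 0
    each survival ordinate is perturbed by truncated Gaussian noise (sd
    ``jitter``) and then re-monotonized and clipped to [0, 1], emulating
    manual graph digitization.  The at-risk table is computed exactly.
    """
    curve = km_estimator(ipd, risk_times=risk_times)
    if jitter <= 0:
        return curve
    rng = np.random.default_rng(seed)
    noise = np.clip(rng.normal(0.0, jitter, len(curve.survival)), -3 * jitter, 3 * jitter)
    s = curve.survival + noise
    s[0] = 1.0
    s = np.clip(np.minimum.accumulate(s), 0.0, 1.0)
    return DigitizedCurve(curve.times, s, curve.risk_times, curve.n_at_risk)
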