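"""Pseudo individual-patient data from digitized Kaplan-Meier curves.

Published survival curves only show the product-limit estimate and a
numbers-at-risk table.  :func:`reconstruct_ipd` inverts that summary into
event/censoring times whose KM estimate reproduces the digitized curve and
whose at-risk counts match the table exactly, so the parametric fitting
stage can run on data equivalent to what the original trial supplied.

The allocation is deterministic: within each inter-risk-time interval the
number of censored observations is found by fixed-point iteration (start at
zero, correct by the at-risk mismatch), censoring times are spread uniformly
over the interval, and event counts at each digitized step are the rounded
product-limit drops.  Events precede censorings at tied times, the standard
KM convention.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

__all__ = ["DigitizedCurve", "PseudoIPD", "reconstruct_ipd", "km_estimator"]


@dataclass(frozen=True)
class DigitizedCurve:
    """Step-curve coordinates plus the numbers-at-risk table."""

    times: np.ndarray
    survival: np.ndarray
    risk_times: np.ndarray
    n_at_risk: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        s = np.asarray(self.survival, dtype=float)
        rt = np.asarray(self.risk_times, dtype=float)
        n = np.asarray(self.n_at_risk, dtype=int)
        if t.shape != s.shape or rt.shape != n.shape:
            raise ValueError("curve and risk-table arrays must pair up")
        if t.size == 0 or not (t[0] == 0.0 and abs(s[0] - 1.0) < 1e-12):
            raise ValueError("curve must start at (0, 1)")
        if np.any(np.diff(t) < 0) or np.any(np.diff(rt) < 0):
            raise ValueError("times must be sorted")
        if np.any((s < 0) | (s > 1)):
            raise ValueError("survival values must lie in [0, 1]")
        if np.any(np.diff(s) > 1e-9):
            k = int(np.argmax(np.diff(s) > 1e-9))
            raise ValueError(f"survival rises between points {k} and {k + 1}")
        if np.any(n < 0) or np.any(np.diff(n) > 0):
            raise ValueError("numbers at risk must be non-negative and non-increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "survival", s)
        object.__setattr__(self, "risk_times", rt)
        object.__setattr__(self, "n_at_risk", n)

    def survival_at(self, t: float) -> float:
        """Step-function lookup of the digitized curve."""
        idx = int(np.searchsorted(self.times, t, side="right")) - 1
        return float(self.survival[max(idx, 0)])

    def to_csv(self, curve_path, risk_path) -> None:
        pd.DataFrame({"time": self.times, "survival": self.survival}).to_csv(
            curve_path, index=False
        )
        pd.DataFrame({"time": self.risk_times, "n_at_risk": self.n_at_risk}).to_csv(
            risk_path, index=False
        )

    @classmethod
    def from_csv(cls, curve_path, risk_path) -> "DigitizedCurve":
        c = pd.read_csv(curve_path)
        r = pd.read_csv(risk_path)
        return cls(
            c["time"].to_numpy(),
            c["survival"].to_numpy(),
            r["time"].to_numpy(),
            r["n_at_risk"].to_numpy(),
        )


@dataclass(frozen=True)
class PseudoIPD:
    """Reconstructed (or simulated) event/censoring times."""

    times: np.ndarray
    events: np.ndarray  # 1 = event, 0 = censored

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        e = np.asarray(self.events, dtype=int)
        if t.shape != e.shape:
            raise ValueError("times and events must have equal length")
        if np.any(t <= 0):
            raise ValueError("times must be positive")
        if not set(np.unique(e)).issubset({0, 1}):
            raise ValueError("events must be 0/1")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "events", e)

    def __len__(self) -> int:
        return len(self.times)

    @property
    def n_events(self) -> int:
        return int(self.events.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "event": self.events})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PseudoIPD":
        df = pd.read_csv(path)
        return cls(df["time"].to_numpy(), df["event"].to_numpy())


def _simulate_interval(points, censor_times, n_start, s_start):
    """Walk one interval: rounded product-limit drops at digitized points,
    unit decrements at censor times (events first at ties)."""
    items = [(t, 0, s) for t, s in points] + [(t, 1, None) for t in censor_times]
    items.sort(key=lambda x: (x[0], x[1]))
    n, s = n_start, s_start
    event_out = []
    for t, kind, s_target in items:
        if kind == 0:
            d = 0
            if n > 0 and s > 0:
                d = int(round(n * (1.0 - s_target / s)))
                d = min(max(d, 0), n)
            if d > 0:
                s *= 1.0 - d / n
                n -= d
                event_out.append((t, d))
        else:
            if n > 0:
                n -= 1
    return event_out, n, s


def reconstruct_ipd(curve: DigitizedCurve) -> PseudoIPD:
    """Invert a digitized KM curve + at-risk table into pseudo-IPD.

    The KM estimate recomputed from the output reproduces the digitized
    survival within the 1/n rounding granularity, and at-risk counts at the
    risk-table times match the table exactly; any patients still at risk at
    the end of the observation window are censored there.
    """
    if len(curve.risk_times) < 2:
        raise ValueError("risk table needs at least 2 rows")
    window_end = float(max(curve.times[-1], curve.risk_times[-1]))
    times: list[float] = []
    events: list[int] = []
    n_cur = int(curve.n_at_risk[0])
    s_cur = 1.0

    pts_all = [(float(t), float(s)) for t, s in zip(curve.times, curve.survival) if t > 0]

    for j in range(len(curve.risk_times) - 1):
        lo, hi = float(curve.risk_times[j]), float(curve.risk_times[j + 1])
        target_n = int(curve.n_at_risk[j + 1])
        pts = [(t, s) for t, s in pts_all if lo <= t < hi]
        if target_n > n_cur:
            raise ValueError(
                f"interval [{lo}, {hi}): at-risk count {target_n} exceeds the "
                f"{n_cur} patients still at risk"
            )
        c = 0
        best = None
        for _ in range(200):
            censor_times = lo + (np.arange(1, c + 1) - 0.5) * (hi - lo) / max(c, 1)
            ev, n_end, s_end = _simulate_interval(pts, censor_times[:c], n_cur, s_cur)
            diff = n_end - target_n
            if best is None or abs(diff) < abs(best[0]):
                best = (diff, c, ev, n_end, s_end, censor_times[:c])
            if diff == 0 or (diff < 0 and c == 0):
                break
            c += diff
            if c < 0:
                c = 0
        diff, c, ev, n_end, s_end, censor_times = best
        if diff < 0:
            # a small overshoot of the at-risk target is rounding/digitizer
            # noise and is absorbed by trimming the latest events; a large
            # one means the curve and the table contradict each other
            if -diff > max(2, 0.05 * n_cur):
                raise ValueError(
                    f"interval [{lo}, {hi}): survival drop implies "
                    f"{n_end} at risk but the table claims {target_n}"
                )
            ev = [[t, d] for t, d in ev]
            for item in reversed(ev):
                take = min(item[1], -diff)
                item[1] -= take
                n_end += take
                diff += take
                if diff == 0:
                    break
            ev = [(t, d) for t, d in ev if d > 0]
            if diff < 0:
                raise ValueError(
                    f"interval [{lo}, {hi}): cannot reach at-risk count {target_n}"
                )
        for t, d in ev:
            times.extend([t] * d)
            events.extend([1] * d)
        times.extend(censor_times.tolist())
        events.extend([0] * len(censor_times))
        n_cur, s_cur = n_end, s_end

    # beyond the last risk-table time: events at remaining digitized points,
    # then administrative censoring of everyone still at risk
    tail = [(t, s) for t, s in pts_all if t >= float(curve.risk_times[-1])]
    ev, n_cur, s_cur = _simulate_interval(tail, [], n_cur, s_cur)
    for t, d in ev:
        times.extend([t] * d)
        events.extend([1] * d)
    if n_cur > 0:
        end = window_end if window_end > 0 else 1.0
        times.extend([end] * n_cur)
        events.extend([0] * n_cur)

    order = np.argsort(times, kind="stable")
    return PseudoIPD(np.asarray(times)[order], np.asarray(events)[order])


def km_estimator(ipd: PseudoIPD, risk_times=None) -> DigitizedCurve:
    """Product-limit estimate of a pseudo-IPD sample as a digitized curve,
    with at-risk counts reported at the requested times (default: time 0
    and the last observation)."""
    if len(ipd) == 0:
        raise ValueError("empty pseudo-IPD")
    kmf = KaplanMeierFitter()
    kmf.fit(ipd.times, ipd.events)
    event_times = np.unique(ipd.times[ipd.events == 1])
    times = np.concatenate([[0.0], event_times])
    surv = kmf.predict(times).to_numpy() if len(times) > 1 else np.ones(1)
    surv = np.asarray(surv, dtype=float).reshape(-1)
    surv[0] = 1.0
    if risk_times is None:
        risk_times = np.array([0.0, float(ipd.times.max())])
    risk_times = np.asarray(risk_times, dtype=float)
    n_at_risk = np.array([(ipd.times >= t).sum() for t in risk_times], dtype=int)
    return DigitizedCurve(times, surv, risk_times, n_at_risk)
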