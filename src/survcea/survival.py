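"""Closed-form parametric survival families for curve extrapolation.

Seven candidate time-to-event families are supported, matching the set
routinely fitted when extrapolating digitized trial Kaplan-Meier curves:
exponential, Weibull, gamma, generalized gamma, log-normal, log-logistic
and Gompertz.  Time is measured in months throughout.

The generalized gamma uses the Prentice (mu, sigma, Q) parameterization,
the convention under which fitted triplets are reported in the
survival-extrapolation literature: with ``w = (log t - mu)/sigma`` and
``gamma = Q**-2``, the survival function for ``Q < 0`` is the regularized
lower incomplete gamma function ``P(gamma, gamma*exp(Q*w))`` and for
``Q > 0`` its complement.  ``Q -> 0`` recovers the log-normal
(meanlog=mu, sdlog=sigma) and ``Q = 1`` the Weibull with shape ``1/sigma``
and scale ``exp(mu)``.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import special, stats

__all__ = [
    "FAMILIES",
    "PARAM_NAMES",
    "ParametricSurvival",
    "BaseCaseSurvivalSet",
    "ExhaustedSurvivalError",
    "survival_at",
    "interval_event_prob",
    "median_survival",
]

FAMILIES = (
    "exponential",
    "weibull",
    "gamma",
    "gengamma",
    "lognormal",
    "loglogistic",
    "gompertz",
)

PARAM_NAMES: dict[str, tuple[str, ...]] = {
    "exponential": ("rate",),
    "weibull": ("shape", "scale"),
    "gamma": ("shape", "rate"),
    "gengamma": ("mu", "sigma", "Q"),
    "lognormal": ("meanlog", "sdlog"),
    "loglogistic": ("shape", "scale"),
    "gompertz": ("shape", "rate"),
}

# parameters that must be strictly positive; the rest are unrestricted reals
_POSITIVE: dict[str, tuple[str, ...]] = {
    "exponential": ("rate",),
    "weibull": ("shape", "scale"),
    "gamma": ("shape", "rate"),
    "gengamma": ("sigma",),
    "lognormal": ("sdlog",),
    "loglogistic": ("shape", "scale"),
    "gompertz": ("shape", "rate"),
}

# below this |Q| the gengamma is evaluated on its log-normal limit branch
_Q_LOGNORMAL_EPS = 1e-6


class ExhaustedSurvivalError(RuntimeError):
    """Raised when a conditional probability is requested past the point
    where the survival function has reached zero."""


def _check_time(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("survival time must be non-negative")
    return t


@dataclass(frozen=True)
class ParametricSurvival:
    """A fitted survival-time distribution (family + named parameters).

    Parameters are validated on construction: unknown families, missing or
    extra parameter names, and non-positive values for scale-like
    parameters all raise ``ValueError``.
    """

    family: str
    params: Mapping[str, float]
    time_unit: str = "months"

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown survival family {self.family!r}")
        expected = set(PARAM_NAMES[self.family])
        got = set(self.params)
        if got != expected:
            raise ValueError(
                f"{self.family} expects parameters {sorted(expected)}, got {sorted(got)}"
            )
        for name in _POSITIVE[self.family]:
            if not self.params[name] > 0:
                raise ValueError(f"{self.family} parameter {name!r} must be > 0")
        object.__setattr__(self, "params", dict(self.params))

    # -- scipy frozen-distribution mapping (all but gengamma) ------------
    def _dist(self):
        p = self.params
        f = self.family
        if f == "exponential":
            return stats.expon(scale=1.0 / p["rate"])
        if f == "weibull":
            return stats.weibull_min(c=p["shape"], scale=p["scale"])
        if f == "gamma":
            return stats.gamma(a=p["shape"], scale=1.0 / p["rate"])
        if f == "lognormal":
            return stats.lognorm(s=p["sdlog"], scale=math.exp(p["meanlog"]))
        if f == "loglogistic":
            return stats.fisk(c=p["shape"], scale=p["scale"])
        if f == "gompertz":
            # S(t) = exp(-(b/a)(e^{a t} - 1)) with shape a, rate b
            return stats.gompertz(c=p["rate"] / p["shape"], scale=1.0 / p["shape"])
        raise AssertionError(f)

    def survival(self, t) -> np.ndarray | float:
        """S(t); vectorized over ``t`` (months)."""
        t = _check_time(t)
        if self.family == "gengamma":
            out = _gengamma_sf(t, **self.params)
        else:
            out = self._dist().sf(t)
        return out if out.ndim else float(out)

    def log_density(self, t) -> np.ndarray | float:
        t = _check_time(t)
        if self.family == "gengamma":
            out = _gengamma_logpdf(t, **self.params)
        else:
            out = self._dist().logpdf(t)
        return out if np.ndim(out) else float(out)

    def inverse_survival(self, p) -> np.ndarray | float:
        """Return t with S(t) = p for p in (0, 1]."""
        p = np.asarray(p, dtype=float)
        if np.any((p <= 0) | (p > 1)):
            raise ValueError("survival probability must be in (0, 1]")
        if self.family == "gengamma":
            out = _gengamma_isf(p, **self.params)
        else:
            out = self._dist().isf(p)
        out = np.maximum(out, 0.0)
        return out if out.ndim else float(out)

    def median(self) -> float:
        return float(self.inverse_survival(0.5))

    def rvs(self, size: int, rng: np.random.Generator) -> np.ndarray:
        """Inverse-transform sampling of event times."""
        return np.asarray(self.inverse_survival(rng.uniform(size=size)))


def _gengamma_sf(t: np.ndarray, mu: float, sigma: float, Q: float) -> np.ndarray:
    shape = np.shape(t)
    t = np.atleast_1d(np.asarray(t, dtype=float))
    out = np.ones_like(t)
    pos = t > 0
    if not np.any(pos):
        return out.reshape(shape)
    w = (np.log(t[pos]) - mu) / sigma
    if abs(Q) < _Q_LOGNORMAL_EPS:
        out[pos] = stats.norm.sf(w)
    else:
        gam = Q**-2
        with np.errstate(over="ignore"):
            u = gam * np.exp(Q * w)
        if Q < 0:
            out[pos] = special.gammainc(gam, u)
        else:
            out[pos] = special.gammaincc(gam, u)
    return out.reshape(shape)


def _gengamma_logpdf(t: np.ndarray, mu: float, sigma: float, Q: float) -> np.ndarray:
    shape = np.shape(t)
    t = np.atleast_1d(np.asarray(t, dtype=float))
    out = np.full_like(t, -np.inf)
    pos = t > 0
    logt = np.log(t[pos])
    w = (logt - mu) / sigma
    if abs(Q) < _Q_LOGNORMAL_EPS:
        out[pos] = -0.5 * w**2 - 0.5 * math.log(2 * math.pi) - math.log(sigma) - logt
    else:
        gam = Q**-2
        with np.errstate(over="ignore"):
            u = gam * np.exp(Q * w)
        # density of u ~ Gamma(gam, 1) pushed through t -> u
        out[pos] = (
            gam * np.log(u)
            - u
            + math.log(abs(Q))
            - special.gammaln(gam)
            - math.log(sigma)
            - logt
        )
    return out.reshape(shape)


def _gengamma_isf(p: np.ndarray, mu: float, sigma: float, Q: float) -> np.ndarray:
    shape = np.shape(p)
    p = np.atleast_1d(np.asarray(p, dtype=float))
    if abs(Q) < _Q_LOGNORMAL_EPS:
        return np.exp(mu + sigma * stats.norm.isf(p)).reshape(shape)
    gam = Q**-2
    u = special.gammaincinv(gam, p) if Q < 0 else special.gammainccinv(gam, p)
    w = np.log(u / gam) / Q
    return np.exp(mu + sigma * w).reshape(shape)


def survival_at(model: ParametricSurvival, t) -> np.ndarray | float:
    """Survival probability S(t) at time t (months)."""
    return model.survival(t)


def interval_event_prob(
    model: ParametricSurvival, cycle_index: int, cycle_length: float
) -> float:
    """Conditional probability of the event during cycle k of width Delta:
    ``1 - S(k*Delta) / S((k-1)*Delta)``."""
    if cycle_index < 1:
        raise ValueError("cycle_index must be >= 1")
    s0 = float(model.survival((cycle_index - 1) * cycle_length))
    if s0 <= 0.0:
        raise ExhaustedSurvivalError(
            f"survival exhausted before cycle {cycle_index}"
        )
    s1 = float(model.survival(cycle_index * cycle_length))
    return 1.0 - s1 / s0


def median_survival(model: ParametricSurvival) -> float:
    """Time t (months) with S(t) = 0.5."""
    return model.median()


@dataclass(frozen=True)
class BaseCaseSurvivalSet:
    """The four extrapolation curves driving the cohort model: disease-free
    survival and overall survival, one of each per treatment arm."""

    dfs_active: ParametricSurvival
    dfs_control: ParametricSurvival
    os_active: ParametricSurvival
    os_control: ParametricSurvival
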