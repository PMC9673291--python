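"""Parametric survival families used for curve extrapolation.

Six standard two-state oncology extrapolation families: exponential, gamma,
Weibull, Gompertz, log-normal and log-logistic. Each family exposes the
censored-data likelihood pieces (``logpdf`` for events, ``logsf`` for
right-censored records), random variates, the analytic median, and the
unconstrained reparameterisation used by the maximum-likelihood optimiser.

Parameterisations
-----------------
exponential
    ``(rate,)`` — hazard ``rate``, ``S(t) = exp(-rate * t)``.
gamma
    ``(shape, rate)`` — scipy's gamma with ``scale = 1/rate``.
weibull
    ``(shape, scale)`` — ``S(t) = exp(-(t/scale)^shape)``.
gompertz
    ``(shape, rate)`` — hazard ``rate * exp(shape * t)``; ``shape`` may be
    negative, in which case the survivor function plateaus at
    ``exp(-rate/|shape|)`` and the distribution is improper (documented
    explicitly; selection can exclude such fits, see ``survival.select_best``).
log-normal
    ``(mu, sigma)`` — location/scale of log-time.
log-logistic
    ``(mu, sigma)`` — location/scale of log-time;
    ``S(t) = 1 / (1 + exp((log t - mu)/sigma))``.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
from scipy import special, stats

FAMILY_ORDER = (
    "exponential",
    "gamma",
    "weibull",
    "gompertz",
    "log-normal",
    "log-logistic",
)

_EULER_GAMMA = 0.5772156649015329


class UnknownFamilyError(ValueError):
    """Raised when a distribution-family name is not one of the six."""


def _as_times(t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    return t


class _Base:
    name: str = ""
    n_params: int = 0
    param_names: tuple[str, ...] = ()
    # True where the parameter is constrained positive (log-transformed for
    # unconstrained optimisation), False where it lives on the real line.
    positive: tuple[bool, ...] = ()

    @classmethod
    def to_unconstrained(cls, params: Sequence[float]) -> np.ndarray:
        params = np.asarray(params, dtype=float)
        out = params.copy()
        for i, pos in enumerate(cls.positive):
            if pos:
                out[i] = np.log(params[i])
        return out

    @classmethod
    def from_unconstrained(cls, x: Sequence[float]) -> tuple[float, ...]:
        x = np.asarray(x, dtype=float)
        out = x.copy()
        for i, pos in enumerate(cls.positive):
            if pos:
                out[i] = np.exp(x[i])
        return tuple(out)

    @classmethod
    def validate(cls, params: Sequence[float]) -> None:
        if len(params) != cls.n_params:
            raise ValueError(
                f"{cls.name} takes {cls.n_params} parameters, got {len(params)}"
            )
        for val, pos, name in zip(params, cls.positive, cls.param_names):
            if pos and not val > 0:
                raise ValueError(f"{cls.name} parameter {name} must be > 0")
            if not np.isfinite(val):
                raise ValueError(f"{cls.name} parameter {name} must be finite")

    @classmethod
    def sf(cls, t, params) -> np.ndarray:
        return np.exp(cls.logsf(t, params))


class Exponential(_Base):
    name = "exponential"
    n_params = 1
    param_names = ("rate",)
    positive = (True,)

    @staticmethod
    def logpdf(t, params):
        (rate,) = params
        return np.log(rate) - rate * _as_times(t)

    @staticmethod
    def logsf(t, params):
        (rate,) = params
        return -rate * _as_times(t)

    @staticmethod
    def median(params):
        (rate,) = params
        return np.log(2.0) / rate

    @staticmethod
    def rvs(params, size, rng):
        (rate,) = params
        return rng.exponential(scale=1.0 / rate, size=size)

    @staticmethod
    def init(times, events):
        d = max(events.sum(), 1.0)
        return (d / times.sum(),)


class Gamma(_Base):
    name = "gamma"
    n_params = 2
    param_names = ("shape", "rate")
    positive = (True, True)

    @staticmethod
    def logpdf(t, params):
        shape, rate = params
        return stats.gamma.logpdf(_as_times(t), a=shape, scale=1.0 / rate)

    @staticmethod
    def logsf(t, params):
        shape, rate = params
        return stats.gamma.logsf(_as_times(t), a=shape, scale=1.0 / rate)

    @staticmethod
    def median(params):
        shape, rate = params
        return stats.gamma.ppf(0.5, a=shape, scale=1.0 / rate)

    @staticmethod
    def rvs(params, size, rng):
        shape, rate = params
        return rng.gamma(shape=shape, scale=1.0 / rate, size=size)

    @staticmethod
    def init(times, events):
        obs = times[events == 1] if events.sum() >= 2 else times
        m, v = obs.mean(), max(obs.var(ddof=1), 1e-12)
        return (max(m * m / v, 1e-3), max(m / v, 1e-9))


class Weibull(_Base):
    name = "weibull"
    n_params = 2
    param_names = ("shape", "scale")
    positive = (True, True)

    @staticmethod
    def logpdf(t, params):
        shape, scale = params
        return stats.weibull_min.logpdf(_as_times(t), c=shape, scale=scale)

    @staticmethod
    def logsf(t, params):
        shape, scale = params
        t = _as_times(t)
        return -np.power(t / scale, shape)

    @staticmethod
    def median(params):
        shape, scale = params
        return scale * np.log(2.0) ** (1.0 / shape)

    @staticmethod
    def rvs(params, size, rng):
        shape, scale = params
        return scale * rng.weibull(shape, size=size)

    @staticmethod
    def init(times, events):
        obs = times[events == 1] if events.sum() >= 2 else times
        logs = np.log(np.maximum(obs, 1e-12))
        sd = max(logs.std(ddof=1), 1e-6)
        shape = np.pi / (np.sqrt(6.0) * sd)
        scale = np.exp(logs.mean() + _EULER_GAMMA / shape)
        return (shape, scale)


class Gompertz(_Base):
    name = "gompertz"
    n_params = 2
    param_names = ("shape", "rate")
    positive = (False, True)

    @staticmethod
    def _cumhaz(t, shape, rate):
        t = _as_times(t)
        if abs(shape) < 1e-12:
            return rate * t
        return rate * np.expm1(shape * t) / shape

    @staticmethod
    def logpdf(t, params):
        shape, rate = params
        t = _as_times(t)
        return np.log(rate) + shape * t - Gompertz._cumhaz(t, shape, rate)

    @staticmethod
    def logsf(t, params):
        shape, rate = params
        return -Gompertz._cumhaz(t, shape, rate)

    @staticmethod
    def plateau(params) -> float:
        """Limiting survival ``S(inf)``; 0 unless shape < 0 (improper fit)."""
        shape, rate = params
        if shape < 0:
            return float(np.exp(-rate / abs(shape)))
        return 0.0

    @staticmethod
    def median(params):
        shape, rate = params
        if abs(shape) < 1e-12:
            return np.log(2.0) / rate
        arg = 1.0 + shape * np.log(2.0) / rate
        if arg <= 0:  # plateau above 0.5: the median does not exist
            return np.inf
        return np.log(arg) / shape

    @staticmethod
    def rvs(params, size, rng):
        shape, rate = params
        if shape <= 0:
            raise ValueError(
                "gompertz simulation requires shape > 0 (proper distribution)"
            )
        h = -np.log(rng.uniform(size=size))  # cumulative hazard draws
        return np.log1p(shape * h / rate) / shape

    @staticmethod
    def init(times, events):
        d = max(events.sum(), 1.0)
        return (0.01, d / times.sum())


class LogNormal(_Base):
    name = "log-normal"
    n_params = 2
    param_names = ("mu", "sigma")
    positive = (False, True)

    @staticmethod
    def logpdf(t, params):
        mu, sigma = params
        t = np.maximum(_as_times(t), 1e-300)
        logt = np.log(t)
        return stats.norm.logpdf(logt, loc=mu, scale=sigma) - logt

    @staticmethod
    def logsf(t, params):
        mu, sigma = params
        t = np.maximum(_as_times(t), 1e-300)
        return stats.norm.logsf(np.log(t), loc=mu, scale=sigma)

    @staticmethod
    def median(params):
        mu, _ = params
        return np.exp(mu)

    @staticmethod
    def rvs(params, size, rng):
        mu, sigma = params
        return np.exp(rng.normal(loc=mu, scale=sigma, size=size))

    @staticmethod
    def init(times, events):
        obs = times[events == 1] if events.sum() >= 2 else times
        logs = np.log(np.maximum(obs, 1e-12))
        return (logs.mean(), max(logs.std(ddof=1), 1e-6))


class LogLogistic(_Base):
    name = "log-logistic"
    n_params = 2
    param_names = ("mu", "sigma")
    positive = (False, True)

    @staticmethod
    def logpdf(t, params):
        mu, sigma = params
        t = np.maximum(_as_times(t), 1e-300)
        z = (np.log(t) - mu) / sigma
        return z + 2.0 * special.log_expit(-z) - np.log(sigma) - np.log(t)

    @staticmethod
    def logsf(t, params):
        mu, sigma = params
        t = np.maximum(_as_times(t), 1e-300)
        z = (np.log(t) - mu) / sigma
        return special.log_expit(-z)

    @staticmethod
    def median(params):
        mu, _ = params
        return np.exp(mu)

    @staticmethod
    def rvs(params, size, rng):
        mu, sigma = params
        u = rng.uniform(size=size)
        return np.exp(mu + sigma * (np.log(u) - np.log1p(-u)))

    @staticmethod
    def init(times, events):
        obs = times[events == 1] if events.sum() >= 2 else times
        logs = np.log(np.maximum(obs, 1e-12))
        sigma = max(logs.std(ddof=1) * np.sqrt(3.0) / np.pi, 1e-6)
        return (logs.mean(), sigma)


_FAMILIES: dict[str, type[_Base]] = {
    cls.name: cls
    for cls in (Exponential, Gamma, Weibull, Gompertz, LogNormal, LogLogistic)
}

# accepted spelling variants
_ALIASES = {
    "lognormal": "log-normal",
    "loglogistic": "log-logistic",
    "lnorm": "log-normal",
    "llogis": "log-logistic",
}


def get_family(name: str) -> type[_Base]:
    """Look up a family class by name (case-insensitive, common aliases)."""
    key = name.strip().lower()
    key = _ALIASES.get(key, key)
    try:
        return _FAMILIES[key]
    except KeyError:
        raise UnknownFamilyError(
            f"unknown distribution family {name!r}; expected one of {FAMILY_ORDER}"
        ) from None
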