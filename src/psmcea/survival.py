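"""Survival-curve machinery behind the partitioned survival model.

Covers four jobs: product-limit (Kaplan–Meier) estimation of a right-censored
cohort; reconstruction of pseudo patient-level data from a digitized published
curve plus its numbers-at-risk table; maximum-likelihood fitting of the six
extrapolation families to censored data with AIC/BIC model selection; and
proportional-hazards adjustment of the fitted reference curve to obtain a
comparator arm's survivor function from a hazard ratio.

Hazard-ratio convention: all stored HRs are *reference arm vs. comparator*
(HR < 1 means the reference arm has the lower hazard). Under proportional
hazards on the cumulative hazard the comparator survivor function is
``S_ref(t) ** (1 / hr)``. Note the log-normal family is not closed under this
transform — the comparator curve is then no longer log-normal, which is the
standard caveat of HR adjustment on a best-fitting accelerated-failure-time
curve and is accepted here deliberately.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import optimize

from .distributions import FAMILY_ORDER, Gompertz, get_family
from .synthetic import DigitizedCurve, SurvivalDataset


class FittingError(RuntimeError):
    """Raised when censored maximum likelihood cannot produce a usable fit."""


# ---------------------------------------------------------------------------
# Kaplan–Meier
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KMEstimate:
    """Product-limit estimate: per-event-time survival, risk and event counts."""

    times: np.ndarray
    survival: np.ndarray
    n_risk: np.ndarray
    n_events: np.ndarray

    def survival_at(self, t) -> np.ndarray:
        """Step-function evaluation, right-continuous, S(t) = 1 before the
        first event."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if self.times.size == 0:  # no events: the estimate is flat at 1
            return np.ones_like(t)
        idx = np.searchsorted(self.times, t, side="right") - 1
        out = np.where(idx >= 0, self.survival[np.maximum(idx, 0)], 1.0)
        return out


def km_estimate(dataset: SurvivalDataset) -> KMEstimate:
    """Kaplan–Meier estimate of a right-censored dataset.

    Delegates to lifelines' ``KaplanMeierFitter``; ties are handled by
    grouping events at identical times (the product-limit convention).
    """
    kmf = KaplanMeierFitter()
    kmf.fit(dataset.time, event_observed=dataset.event)
    table = kmf.event_table
    mask = table["observed"] > 0
    times = table.index.to_numpy(float)[mask.to_numpy()]
    surv = kmf.survival_function_at_times(times).to_numpy(float)
    n_risk = table.loc[mask, "at_risk"].to_numpy(float)
    n_events = table.loc[mask, "observed"].to_numpy(float)
    return KMEstimate(times=times, survival=surv, n_risk=n_risk, n_events=n_events)


# ---------------------------------------------------------------------------
# Pseudo-IPD reconstruction from a digitized curve
# ---------------------------------------------------------------------------

def reconstruct_ipd(curve: DigitizedCurve) -> SurvivalDataset:
    """Rebuild pseudo patient-level records from a digitized KM curve.

    Interval-by-interval allocation in the style of the standard published
    reconstruction scheme, specialised to a risk table aligned with the
    survival grid: within each grid interval ``(t_i, t_{i+1}]`` the number of
    events follows from the survival drop ``1 - S_{i+1}/S_i`` applied to the
    incoming risk set, and censorings absorb the remaining decline of the
    risk count. Events are spread evenly across the interval and censorings
    placed at its right endpoint; because censorings come last, the
    product-limit ratio over the interval telescopes to ``1 - d/n``
    regardless of event spacing, so the KM curve of the output reproduces
    the input probabilities exactly on the grid (up to integer rounding of
    event counts) while approximating the within-interval path.
    """
    if len(curve.risk_table) != len(curve.time_points):
        raise ValueError("risk table must cover every grid time")
    t = curve.time_points
    s = curve.survival_probs
    n = np.array([c for _, c in curve.risk_table], dtype=int)
    if n[0] <= 0:
        raise ValueError("initial number at risk must be positive")

    times: list[float] = []
    events: list[int] = []
    n_model = n[0]  # risk count implied by the allocation so far
    s_model = 1.0
    for i in range(len(t) - 1):
        if n_model <= 0:
            break
        target = s[i + 1]
        if s_model > 0 and target < s_model:
            d = int(round(n_model * (1.0 - target / s_model)))
            d = min(max(d, 0), n_model)
        else:
            d = 0
        c = max(n_model - d - n[i + 1], 0)
        c = min(c, n_model - d)
        width = t[i + 1] - t[i]
        times.extend(t[i] + width * (j + 1) / d for j in range(d))
        times.extend([t[i + 1]] * c)
        events.extend([1] * d + [0] * c)
        if d > 0:
            s_model *= 1.0 - d / n_model
        n_model -= d + c
    # anyone still at risk past the grid is censored at the last grid time
    if n_model > 0:
        times.extend([t[-1]] * n_model)
        events.extend([0] * n_model)
    return SurvivalDataset(
        time=np.asarray(times, float),
        event=np.asarray(events, int),
        label="reconstructed",
    )


# ---------------------------------------------------------------------------
# Parametric fitting and selection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParametricFit:
    """One family fitted to right-censored data by maximum likelihood."""

    family: str
    params: tuple[float, ...]
    loglik: float
    n: int
    n_events: int

    @property
    def k(self) -> int:
        return get_family(self.family).n_params

    @property
    def aic(self) -> float:
        return 2.0 * self.k - 2.0 * self.loglik

    @property
    def bic(self) -> float:
        return self.k * np.log(self.n) - 2.0 * self.loglik

    def sf(self, t) -> np.ndarray:
        return get_family(self.family).sf(t, self.params)

    def median(self) -> float:
        return float(get_family(self.family).median(self.params))


def _neg_loglik(fam, x, time, event):
    params = fam.from_unconstrained(x)
    with np.errstate(all="ignore"):
        ll = np.where(
            event == 1, fam.logpdf(time, params), fam.logsf(time, params)
        )
    if not np.all(np.isfinite(ll)):
        return 1e12
    return -float(ll.sum())


def fit_parametric(dataset: SurvivalDataset, family: str) -> ParametricFit:
    """Censored maximum-likelihood fit of one family.

    Maximises ``sum(event * log f(t) + (1 - event) * log S(t))``. Positive
    parameters are optimised on the log scale; starts are method-of-moments
    values plus scale perturbations (and, for Gompertz, both hazard-slope
    signs); Nelder–Mead with a 1e-8 function tolerance, best start kept.
    The exponential rate has the closed form ``n_events / sum(times)`` and
    is used directly.
    """
    fam = get_family(family)
    time, event = dataset.time, dataset.event
    if event.sum() < 1:
        raise FittingError("dataset has no observed events; cannot fit")

    if fam.name == "exponential":
        rate = event.sum() / time.sum()
        ll = -_neg_loglik(fam, fam.to_unconstrained((rate,)), time, event)
        return ParametricFit(
            family=fam.name, params=(float(rate),), loglik=ll,
            n=len(dataset), n_events=dataset.n_events,
        )

    base = np.asarray(fam.init(time, event), dtype=float)
    starts = [base]
    for factor in (0.5, 2.0):
        starts.append(
            np.array([
                p * factor if pos else p
                for p, pos in zip(base, fam.positive)
            ])
        )
    if fam.name == "gompertz":
        starts.append(np.array([-0.05, base[1]]))
        starts.append(np.array([0.1, base[1]]))

    best = None
    for s0 in starts:
        x0 = fam.to_unconstrained(s0)
        res = optimize.minimize(
            lambda x: _neg_loglik(fam, x, time, event),
            x0,
            method="Nelder-Mead",
            options={"fatol": 1e-8, "xatol": 1e-8, "maxiter": 4000},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e12:
        raise FittingError(
            f"{fam.name} fit failed to converge "
            f"(status={getattr(best, 'status', 'n/a')})"
        )
    params = fam.from_unconstrained(best.x)
    return ParametricFit(
        family=fam.name, params=tuple(float(p) for p in params),
        loglik=-float(best.fun), n=len(dataset), n_events=dataset.n_events,
    )


def fit_all_families(dataset: SurvivalDataset) -> list[ParametricFit]:
    """Fit all six families in the canonical order."""
    return [fit_parametric(dataset, name) for name in FAMILY_ORDER]


def select_best(
    fits: list[ParametricFit], gompertz_plateau_floor: float = 0.05
) -> ParametricFit:
    """Pick the fit with minimal AIC; ties broken by BIC, then family order.

    A Gompertz fit with a negative shape whose survivor plateau exceeds
    ``gompertz_plateau_floor`` is excluded: such a curve never reaches zero
    and is unusable for lifetime extrapolation.
    """
    if not fits:
        raise ValueError("no fits to select from")
    eligible = []
    for f in fits:
        if f.family == "gompertz" and Gompertz.plateau(f.params) > gompertz_plateau_floor:
            continue
        eligible.append(f)
    if not eligible:
        eligible = list(fits)
    order = {name: i for i, name in enumerate(FAMILY_ORDER)}
    return min(eligible, key=lambda f: (f.aic, f.bic, order.get(f.family, 99)))


def fit_report(fits: list[ParametricFit]) -> pd.DataFrame:
    """One row per family: parameters, log-likelihood, AIC, BIC."""
    rows = []
    for f in fits:
        fam = get_family(f.family)
        row = {"family": f.family}
        for name, value in zip(fam.param_names, f.params):
            row[name] = value
        row.update({"loglik": f.loglik, "aic": f.aic, "bic": f.bic})
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# HR-adjusted survival model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SurvivalModel:
    """A fitted reference curve, optionally HR-adjusted for a comparator arm.

    ``hr_vs_reference`` is the hazard ratio of the *reference arm vs. this
    arm*; 1.0 yields the reference curve itself.
    """

    fit: ParametricFit
    hr_vs_reference: float = 1.0

    def __post_init__(self):
        if not self.hr_vs_reference > 0:
            raise ValueError("hazard ratio must be > 0")

    def survival_at(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("time must be >= 0")
        s_ref = self.fit.sf(t)
        if self.hr_vs_reference == 1.0:
            return s_ref
        return np.power(s_ref, 1.0 / self.hr_vs_reference)


def survival_at(model: SurvivalModel, t) -> np.ndarray:
    """Functional alias for ``SurvivalModel.survival_at``."""
    return model.survival_at(t)
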