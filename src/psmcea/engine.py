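"""Three-state partitioned survival model with discounted cost/QALY accounting.

State occupancy is read directly off the two endpoint curves rather than from
transition probabilities: at model time ``t`` the progression-free share is
``S_PFS(t)``, the dead share is ``1 - S_OS(t)``, and the post-progression
share is the difference. The cohort enters progression-free; a 3-week cycle
is the accounting unit, and all flows are discounted per cycle at the
compound-equivalent of the annual rate.

Accounting conventions (config-exposed where noted):

* Cycle ``k`` (k = 1..horizon) represents the interval ``(t_{k-1}, t_k]``;
  occupancy is measured at the cycle end ``t_k`` and each flow at cycle ``k``
  is discounted by ``(1 + r)^(-k)``. No half-cycle correction by default; the
  flag replaces end-of-cycle occupancy with the interval mean (trapezoid).
* Drug + administration costs accrue on progression-free occupancy while the
  cycle index is within the treatment cap; follow-up costs accrue on all
  alive occupancy; subsequent-treatment costs accrue per cycle on
  post-progression occupancy; the end-of-life cost attaches to the increment
  of the dead state each cycle.
* Adverse-event costs and disutilities accrue on progression-free occupancy
  during the AE window (first year by default, fractional final cycle), one
  cost per event and one cycle of disutility per event.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .survival import SurvivalModel

DAYS_PER_YEAR = 365.0
MONTHS_PER_YEAR = 12.0


def per_cycle_discount(annual_rate: float, cycle_weeks: float) -> float:
    """Compound-equivalent per-cycle discount rate:
    ``(1 + annual)^(weeks/52) - 1`` (5%/yr, 3 weeks -> 0.28%/cycle)."""
    if annual_rate < 0:
        raise ValueError("annual discount rate must be >= 0")
    return (1.0 + annual_rate) ** (cycle_weeks / 52.0) - 1.0


def annual_to_cycle_probability(
    annual_incidence: float, cycles_per_year: float
) -> float:
    """Uniform-spread conversion of a cumulative annual incidence to a
    per-cycle probability: ``incidence / cycles_per_year``."""
    if not 0.0 <= annual_incidence <= 1.0:
        raise ValueError("annual incidence must lie in [0, 1]")
    if cycles_per_year <= 0:
        raise ValueError("cycles_per_year must be > 0")
    return annual_incidence / cycles_per_year


@dataclass(frozen=True)
class AdverseEvent:
    """A grade >=3 treatment-related event carried in the model."""

    name: str
    per_cycle_probability: float
    cost_per_event: float
    disutility: float = 0.0  # utility decrement (<= 0) applied for one cycle

    def __post_init__(self):
        if not 0.0 <= self.per_cycle_probability <= 1.0:
            raise ValueError(f"{self.name}: probability must lie in [0, 1]")
        if self.cost_per_event < 0:
            raise ValueError(f"{self.name}: cost must be >= 0")
        if self.disutility > 0:
            raise ValueError(f"{self.name}: disutility must be <= 0")


@dataclass(frozen=True)
class StrategyDefinition:
    """One treatment arm: survival models plus its per-cycle cost structure."""

    name: str
    pfs_model: SurvivalModel
    os_model: SurvivalModel
    drug_cost_per_cycle: float
    admin_cost_per_cycle: float
    followup_cost_per_cycle: float
    subsequent_cost_per_cycle: float
    treatment_cap_cycles: int | None = None
    ae_profile: tuple[AdverseEvent, ...] = ()

    def __post_init__(self):
        for label in (
            "drug_cost_per_cycle",
            "admin_cost_per_cycle",
            "followup_cost_per_cycle",
            "subsequent_cost_per_cycle",
        ):
            if getattr(self, label) < 0:
                raise ValueError(f"{label} must be >= 0")
        if self.treatment_cap_cycles is not None and self.treatment_cap_cycles <= 0:
            raise ValueError("treatment_cap_cycles must be > 0 when present")
        object.__setattr__(self, "ae_profile", tuple(self.ae_profile))


@dataclass(frozen=True)
class EconSettings:
    """Global economic settings shared by both arms."""

    cycle_length_weeks: float = 3.0
    horizon_cycles: int = 522  # 30 years of 3-week cycles
    annual_discount: float = 0.05
    per_cycle_discount_override: float | None = None
    utility_pfs: float = 0.745
    utility_pp: float = 0.678
    end_of_life_cost: float = 2132.67
    ae_window_years: float = 1.0
    half_cycle_correction: bool = False
    wtp_thresholds: tuple[float, ...] = (12516.0, 25031.0, 37547.0)

    def __post_init__(self):
        if self.horizon_cycles < 1:
            raise ValueError("horizon_cycles must be >= 1")
        if not (0.0 <= self.utility_pp <= self.utility_pfs <= 1.0):
            raise ValueError("require 0 <= u_PP <= u_PFS <= 1")
        if self.end_of_life_cost < 0:
            raise ValueError("end_of_life_cost must be >= 0")

    @property
    def discount_per_cycle(self) -> float:
        if self.per_cycle_discount_override is not None:
            return self.per_cycle_discount_override
        return per_cycle_discount(self.annual_discount, self.cycle_length_weeks)

    @property
    def cycle_days(self) -> float:
        return self.cycle_length_weeks * 7.0

    @property
    def cycle_years(self) -> float:
        return self.cycle_days / DAYS_PER_YEAR

    @property
    def cycle_months(self) -> float:
        return self.cycle_days / (DAYS_PER_YEAR / MONTHS_PER_YEAR)

    @property
    def cycles_per_year(self) -> float:
        return DAYS_PER_YEAR / self.cycle_days

    @property
    def ae_window_cycles(self) -> float:
        return self.ae_window_years * self.cycles_per_year


COST_CATEGORIES = ("drug", "admin", "followup", "subsequent", "ae", "eol")


@dataclass(frozen=True)
class CohortTrace:
    """Per-cycle state occupancy and discounted accumulators for one arm."""

    strategy: str
    times_months: np.ndarray  # t_0 .. t_H
    pfs_occupancy: np.ndarray
    pp_occupancy: np.ndarray
    dead_occupancy: np.ndarray
    new_deaths: np.ndarray
    cost_by_category: dict[str, np.ndarray]  # discounted, per cycle
    qaly: np.ndarray  # discounted, per cycle
    ly: np.ndarray  # discounted, per cycle
    warnings: tuple[str, ...] = ()

    @property
    def total_cost(self) -> float:
        return float(sum(v.sum() for v in self.cost_by_category.values()))

    @property
    def total_qaly(self) -> float:
        return float(self.qaly.sum())

    @property
    def total_ly(self) -> float:
        return float(self.ly.sum())

    def cost_breakdown(self) -> dict[str, float]:
        return {k: float(v.sum()) for k, v in self.cost_by_category.items()}

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "time_months": self.times_months,
                "pfs": self.pfs_occupancy,
                "pp": self.pp_occupancy,
                "dead": self.dead_occupancy,
                "new_deaths": self.new_deaths,
                "qaly": self.qaly,
                "ly": self.ly,
            }
        )
        for cat in COST_CATEGORIES:
            df[f"cost_{cat}"] = self.cost_by_category[cat]
        return df


def run_trace(strategy: StrategyDefinition, settings: EconSettings) -> CohortTrace:
    """Run the partitioned survival model for one arm.

    Occupancy at each cycle time comes straight from the survival models;
    whenever the progression-free curve sits above the overall-survival curve
    the progression-free share is capped at the alive share (post-progression
    clamped to zero) so the three states always partition the cohort exactly.
    An excess beyond 0.05 is reported in the trace's run log.
    """
    h = settings.horizon_cycles
    k = np.arange(h + 1)
    t_months = k * settings.cycle_months

    s_pfs = np.clip(strategy.pfs_model.survival_at(t_months), 0.0, 1.0)
    s_os = np.clip(strategy.os_model.survival_at(t_months), 0.0, 1.0)

    warnings: list[str] = []
    excess = float(np.max(s_pfs - s_os))
    if excess > 0.05:
        warnings.append(
            f"{strategy.name}: S_PFS exceeds S_OS by up to {excess:.3f}; "
            "progression-free share capped at the alive share"
        )
    pfs = np.minimum(s_pfs, s_os)
    dead = 1.0 - s_os
    pp = s_os - pfs  # >= 0 by construction; pfs + pp + dead == 1 exactly

    new_deaths = np.diff(dead, prepend=dead[0])
    new_deaths[0] = dead[0]

    # interval occupancy for accrual: end-of-cycle by default, interval mean
    # under half-cycle correction; entry 0-th entry carries no accrual
    def interval(x: np.ndarray) -> np.ndarray:
        if settings.half_cycle_correction:
            return 0.5 * (x[:-1] + x[1:])
        return x[1:]

    pfs_i, pp_i = interval(pfs), interval(pp)
    alive_i = pfs_i + pp_i
    deaths_i = new_deaths[1:]

    disc = (1.0 + settings.discount_per_cycle) ** (-k[1:].astype(float))

    on_treatment = np.ones(h)
    if strategy.treatment_cap_cycles is not None:
        on_treatment[k[1:] > strategy.treatment_cap_cycles] = 0.0

    # AE window weight per cycle: cycle j covers (j-1, j] in cycle units
    w_ae = np.clip(settings.ae_window_cycles - (k[1:] - 1), 0.0, 1.0)
    ae_cost_rate = sum(
        ae.per_cycle_probability * ae.cost_per_event for ae in strategy.ae_profile
    )
    ae_disutility_rate = sum(
        ae.per_cycle_probability * (-ae.disutility) for ae in strategy.ae_profile
    )

    cost = {
        "drug": strategy.drug_cost_per_cycle * pfs_i * on_treatment * disc,
        "admin": strategy.admin_cost_per_cycle * pfs_i * on_treatment * disc,
        "followup": strategy.followup_cost_per_cycle * alive_i * disc,
        "subsequent": strategy.subsequent_cost_per_cycle * pp_i * disc,
        "ae": ae_cost_rate * pfs_i * w_ae * disc,
        "eol": settings.end_of_life_cost * deaths_i * disc,
    }
    utility = (
        settings.utility_pfs * pfs_i
        + settings.utility_pp * pp_i
        - ae_disutility_rate * pfs_i * w_ae
    )
    qaly = utility * settings.cycle_years * disc
    ly = alive_i * settings.cycle_years * disc

    # prepend the zero-accrual entry cycle so arrays align with times
    pad = lambda x: np.concatenate(([0.0], x))
    return CohortTrace(
        strategy=strategy.name,
        times_months=t_months,
        pfs_occupancy=pfs,
        pp_occupancy=pp,
        dead_occupancy=dead,
        new_deaths=new_deaths,
        cost_by_category={cat: pad(v) for cat, v in cost.items()},
        qaly=pad(qaly),
        ly=pad(ly),
        warnings=tuple(warnings),
    )


# ---------------------------------------------------------------------------
# Incremental results
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StrategyTotals:
    name: str
    cost: float
    qaly: float
    ly: float


@dataclass(frozen=True)
class CEAResult:
    """Per-strategy totals plus the incremental comparison.

    The increment is *intervention minus comparator*. ``icer`` is reported
    only when it is a meaningful ratio; dominance and zero-effect cases are
    labelled instead.
    """

    intervention: StrategyTotals
    comparator: StrategyTotals
    delta_cost: float
    delta_qaly: float
    delta_ly: float
    icer: float | None
    label: str  # "icer", "dominant", "dominated", "undefined"

    def to_frame(self) -> pd.DataFrame:
        if self.label == "icer":
            head_icer: float | str = self.icer
        else:
            head_icer = self.label
        rows = [
            {
                "strategy": self.intervention.name,
                "cost": self.intervention.cost,
                "qaly": self.intervention.qaly,
                "ly": self.intervention.ly,
                "icer": head_icer,
            },
            {
                "strategy": self.comparator.name,
                "cost": self.comparator.cost,
                "qaly": self.comparator.qaly,
                "ly": self.comparator.ly,
                "icer": "-",
            },
        ]
        return pd.DataFrame(rows)


def cea_from_totals(
    intervention: StrategyTotals, comparator: StrategyTotals
) -> CEAResult:
    """Incremental comparison from per-strategy totals (printed or computed)."""
    dc = intervention.cost - comparator.cost
    dq = intervention.qaly - comparator.qaly
    dly = intervention.ly - comparator.ly
    if dq == 0:
        icer, label = None, "undefined"
    elif dq > 0 and dc < 0:
        icer, label = None, "dominant"
    elif dq < 0 and dc > 0:
        icer, label = None, "dominated"
    else:
        icer, label = dc / dq, "icer"
    return CEAResult(
        intervention=intervention,
        comparator=comparator,
        delta_cost=dc,
        delta_qaly=dq,
        delta_ly=dly,
        icer=icer,
        label=label,
    )


def compare(intervention: CohortTrace, comparator: CohortTrace) -> CEAResult:
    """Incremental cost-effectiveness of the intervention arm vs. comparator."""
    return cea_from_totals(
        StrategyTotals(
            intervention.strategy,
            intervention.total_cost,
            intervention.total_qaly,
            intervention.total_ly,
        ),
        StrategyTotals(
            comparator.strategy,
            comparator.total_cost,
            comparator.total_qaly,
            comparator.total_ly,
        ),
    )


# ---------------------------------------------------------------------------
# Drug-cost arithmetic
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegimenComponent:
    """One drug line of a regimen.

    ``kind`` is one of ``flat_iv`` (fixed mg per administration, whole-vial
    wastage), ``weight_iv`` (mg per kg body weight, whole-vial wastage) or
    ``oral_daily`` (mg per day, whole tablets per day).
    """

    drug: str
    kind: str
    unit_mg: float  # vial or tablet strength
    unit_price: float
    dose_mg: float = 0.0  # flat_iv
    mg_per_kg: float = 0.0  # weight_iv
    mg_per_day: float = 0.0  # oral_daily

    def __post_init__(self):
        if self.kind not in ("flat_iv", "weight_iv", "oral_daily"):
            raise ValueError(f"unknown regimen component kind {self.kind!r}")
        if self.unit_mg <= 0 or self.unit_price < 0:
            raise ValueError("unit strength must be > 0 and price >= 0")


def drug_cost_per_cycle(
    components: tuple[RegimenComponent, ...] | list[RegimenComponent],
    body_weight_kg: float = 65.0,
    days_per_cycle: float = 21.0,
) -> float:
    """Acquisition cost of one treatment cycle, with whole-vial wastage."""
    total = 0.0
    for comp in components:
        if comp.kind == "flat_iv":
            units = math.ceil(comp.dose_mg / comp.unit_mg)
        elif comp.kind == "weight_iv":
            if body_weight_kg <= 0:
                raise ValueError("body weight must be > 0 for weight-based dosing")
            units = math.ceil(body_weight_kg * comp.mg_per_kg / comp.unit_mg)
        else:  # oral_daily
            units = math.ceil(comp.mg_per_day / comp.unit_mg) * days_per_cycle
        total += units * comp.unit_price
    return total
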