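"""Deterministic and probabilistic sensitivity analysis.

One-way DSA re-runs the whole model at each parameter's lower and upper
bound (95% CI when reported, otherwise ±20% of the base value) and ranks
parameters by the width of the resulting ICER interval (tornado diagram).

PSA samples every parameter jointly from its assigned family — beta for
probabilities and utilities, gamma for costs, log-normal for hazard ratios —
with beta and gamma parameterised by moment matching: mean at the base value
and standard deviation ``(high - low) / (2 * 1.959964)``. Each iteration
re-runs both arms and records the incremental cost and QALY pair; the
cost-effectiveness acceptability curve is the fraction of iterations with
positive incremental net monetary benefit at each willingness-to-pay value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .engine import CEAResult

Z975 = 1.959963984540054

PSA_FAMILIES = ("beta", "gamma", "lognormal", "fixed")


@dataclass(frozen=True)
class ParameterSpec:
    """One uncertain model input: DSA bounds and PSA sampling family.

    ``path`` points into the nested model-input mapping (see ``psmcea.config``)
    so that an override can be applied mechanically before a re-run.
    """

    name: str
    base_value: float
    low: float
    high: float
    psa_family: str = "fixed"
    path: tuple[str, ...] = ()

    def __post_init__(self):
        if not (self.low <= self.base_value <= self.high):
            raise ValueError(
                f"{self.name}: require low <= base <= high "
                f"({self.low}, {self.base_value}, {self.high})"
            )
        if self.psa_family not in PSA_FAMILIES:
            raise ValueError(f"{self.name}: unknown PSA family {self.psa_family!r}")

    @property
    def sd(self) -> float:
        return (self.high - self.low) / (2.0 * Z975)


def default_bounds(base: float, fraction: float = 0.2) -> tuple[float, float]:
    """±20% bounds used when no interval is reported."""
    lo, hi = base * (1 - fraction), base * (1 + fraction)
    return (min(lo, hi), max(lo, hi))


# ---------------------------------------------------------------------------
# One-way DSA
# ---------------------------------------------------------------------------

def _icer_or_label(result: CEAResult) -> tuple[float | None, str]:
    return (result.icer, result.label)


def one_way_dsa(
    specs: list[ParameterSpec],
    evaluate: Callable[[dict[str, float]], CEAResult],
) -> pd.DataFrame:
    """Tornado table: one row per parameter, ranked by |ICER_high - ICER_low|.

    ``evaluate`` maps ``{parameter name: value}`` overrides to a full model
    run. Bounds that produce a non-positive QALY gain are labelled rather
    than folded into the ratio; their bar width uses only the defined end(s).
    """
    base = evaluate({})
    rows = []
    for spec in specs:
        icer_lo, label_lo = _icer_or_label(evaluate({spec.name: spec.low}))
        icer_hi, label_hi = _icer_or_label(evaluate({spec.name: spec.high}))
        defined = [x for x in (icer_lo, icer_hi) if x is not None]
        if len(defined) == 2:
            width = abs(icer_hi - icer_lo)
        elif len(defined) == 1:
            width = abs(defined[0] - base.icer) if base.icer is not None else np.nan
        else:
            width = np.nan
        rows.append(
            {
                "parameter": spec.name,
                "low": spec.low,
                "high": spec.high,
                "icer_low": icer_lo if icer_lo is not None else label_lo,
                "icer_high": icer_hi if icer_hi is not None else label_hi,
                "width": width,
            }
        )
    df = pd.DataFrame(rows)
    return df.sort_values("width", ascending=False, ignore_index=True)


# ---------------------------------------------------------------------------
# PSA sampling
# ---------------------------------------------------------------------------

def _draw_beta(base: float, sd: float, rng: np.random.Generator) -> float:
    """Moment-matched beta draw; negative bases sample the magnitude and
    restore the sign (used for utility decrements reported as negatives)."""
    sign = -1.0 if base < 0 else 1.0
    m = abs(base)
    if sd == 0 or m == 0:
        return base
    var = sd * sd
    if var >= m * (1 - m) or not 0 < m < 1:
        warnings.warn(
            f"beta moment matching infeasible (mean={m}, sd={sd}); "
            "falling back to a clipped normal draw",
            stacklevel=2,
        )
        return sign * float(np.clip(rng.normal(m, sd), 0.0, 1.0))
    nu = m * (1 - m) / var - 1.0
    return sign * float(rng.beta(m * nu, (1 - m) * nu))


def _draw_gamma(base: float, sd: float, rng: np.random.Generator) -> float:
    if sd == 0 or base == 0:
        return base
    var = sd * sd
    shape = base * base / var
    scale = var / base
    return float(rng.gamma(shape, scale))


def _draw_lognormal(
    base: float, low: float, high: float, rng: np.random.Generator
) -> float:
    if low <= 0 or high <= low:
        return base
    log_sd = np.log(high / low) / (2.0 * Z975)
    return float(np.exp(rng.normal(np.log(base), log_sd)))


def draw_parameters(
    specs: list[ParameterSpec], rng: np.random.Generator | int
) -> dict[str, float]:
    """One joint PSA draw, deterministic given the generator state.

    Parameters are drawn in list order, one variate each, so a fixed seed
    yields a bit-stable sequence.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    out: dict[str, float] = {}
    for spec in specs:
        if spec.psa_family == "fixed":
            out[spec.name] = spec.base_value
        elif spec.psa_family == "beta":
            out[spec.name] = _draw_beta(spec.base_value, spec.sd, rng)
        elif spec.psa_family == "gamma":
            out[spec.name] = _draw_gamma(spec.base_value, spec.sd, rng)
        else:  # lognormal
            out[spec.name] = _draw_lognormal(
                spec.base_value, spec.low, spec.high, rng
            )
    return out


# ---------------------------------------------------------------------------
# PSA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PSAResult:
    """Monte Carlo incremental draws plus acceptability summaries."""

    delta_cost: np.ndarray
    delta_qaly: np.ndarray
    n_iterations: int
    seed: int
    wtp_grid: np.ndarray
    n_failures: int = 0

    @property
    def draws(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"delta_cost": self.delta_cost, "delta_qaly": self.delta_qaly}
        )

    def ceac(self) -> pd.DataFrame:
        """P(intervention cost-effective) = fraction of draws with
        ``wtp * dQ - dC > 0``, per willingness-to-pay grid value."""
        probs = [
            float(np.mean(w * self.delta_qaly - self.delta_cost > 0))
            for w in self.wtp_grid
        ]
        return pd.DataFrame({"wtp": self.wtp_grid, "probability": probs})

    def probability_cost_effective(self, wtp: float) -> float:
        return float(np.mean(wtp * self.delta_qaly - self.delta_cost > 0))

    def crossover_wtp(self) -> float | None:
        """Smallest grid WTP at which the intervention is the preferred
        strategy in at least half the draws."""
        ceac = self.ceac()
        hit = ceac[ceac["probability"] >= 0.5]
        if hit.empty:
            return None
        return float(hit["wtp"].iloc[0])


def run_psa(
    evaluate: Callable[[dict[str, float]], CEAResult],
    specs: list[ParameterSpec],
    n_iterations: int = 5000,
    seed: int = 0,
    wtp_grid: np.ndarray | None = None,
    max_failure_fraction: float = 0.01,
) -> PSAResult:
    """Probabilistic sensitivity analysis.

    Per iteration: one joint parameter draw, a full two-arm model run, and
    the incremental (cost, QALY) pair. Iteration failures are recorded and
    skipped; more than ``max_failure_fraction`` of them aborts the analysis.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    if wtp_grid is None:
        wtp_grid = np.arange(0.0, 50_000.0 + 1, 500.0)
    rng = np.random.default_rng(seed)
    dc, dq = [], []
    failures = 0
    for _ in range(n_iterations):
        values = draw_parameters(specs, rng)
        try:
            result = evaluate(values)
        except Exception:  # engine-level failure for this draw
            failures += 1
            if failures > max_failure_fraction * n_iterations:
                raise RuntimeError(
                    f"PSA aborted: {failures} failed iterations "
                    f"(> {max_failure_fraction:.0%} of {n_iterations})"
                )
            continue
        dc.append(result.delta_cost)
        dq.append(result.delta_qaly)
    return PSAResult(
        delta_cost=np.asarray(dc),
        delta_qaly=np.asarray(dq),
        n_iterations=n_iterations,
        seed=seed,
        wtp_grid=np.asarray(wtp_grid, dtype=float),
        n_failures=failures,
    )
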