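"""Synthetic pseudo-IPD and digitized-curve generation.

The trial whose patient-level data the economic model consumes is not publicly
deposited, so every downstream stage (Kaplan–Meier estimation, parametric
fitting, curve reconstruction, the partitioned survival model itself) is
exercised against synthetic cohorts whose statistical structure matches what
the analysis assumes: latent event times from a named parametric family,
uniform accrual, and administrative censoring at a fixed follow-up cutoff.

Draw order is fixed so cohorts are bit-stable for a given seed: latent event
times first (one block of ``n_patients`` draws), then entry times (a second
block of ``n_patients`` uniform draws).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .distributions import get_family


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for one synthetic single-arm cohort of right-censored times.

    Parameters
    ----------
    n_patients : int
        Cohort size (>= 2).
    endpoint : str
        Label, ``"PFS"`` or ``"OS"``.
    family : str
        Latent event-time family (one of the six extrapolation families).
    params : tuple of float
        Family parameters; for log-normal ``(mu, sigma)`` on log-months.
    accrual_months : float
        Entry times are uniform on ``[0, accrual_months]``.
    followup_months : float
        Administrative data cutoff measured from the start of accrual;
        a patient entering at ``e`` is censored at ``followup_months - e``.
        ``math.inf`` disables censoring.
    seed : int
        Governs the whole draw.
    """

    n_patients: int
    endpoint: str
    family: str
    params: tuple[float, ...]
    accrual_months: float = 0.0
    followup_months: float = math.inf
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if self.endpoint not in ("PFS", "OS"):
            raise ValueError("endpoint must be 'PFS' or 'OS'")
        fam = get_family(self.family)  # raises UnknownFamilyError
        fam.validate(self.params)
        if self.accrual_months < 0:
            raise ValueError("accrual_months must be >= 0")
        if not self.followup_months > 0:
            raise ValueError("followup_months must be > 0")
        if self.accrual_months >= self.followup_months:
            raise ValueError("accrual_months must be < followup_months")
        object.__setattr__(self, "params", tuple(float(p) for p in self.params))


@dataclass(frozen=True)
class SurvivalDataset:
    """Right-censored patient-level times: the model's IPD surrogate."""

    time: np.ndarray  # positive months
    event: np.ndarray  # 1 = event observed, 0 = right-censored
    endpoint: str = ""
    label: str = ""

    def __post_init__(self):
        time = np.asarray(self.time, dtype=float)
        event = np.asarray(self.event, dtype=int)
        if time.shape != event.shape or time.ndim != 1:
            raise ValueError("time and event must be 1-d arrays of equal length")
        if time.size == 0:
            raise ValueError("dataset is empty")
        if np.any(time <= 0):
            raise ValueError("all times must be > 0")
        if not np.isin(event, (0, 1)).all():
            raise ValueError("event indicators must be 0 or 1")
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "event", event)

    def __len__(self) -> int:
        return self.time.size

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.time, "event": self.event})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, endpoint: str = "", label: str = ""):
        df = pd.read_csv(path)
        if not {"time", "event"} <= set(df.columns):
            raise ValueError(f"{path}: expected columns 'time,event'")
        return cls(
            time=df["time"].to_numpy(float),
            event=df["event"].to_numpy(int),
            endpoint=endpoint,
            label=label,
        )


@dataclass(frozen=True)
class DigitizedCurve:
    """A published-figure stand-in: survival read off a grid plus a risk table."""

    time_points: np.ndarray
    survival_probs: np.ndarray
    risk_table: tuple[tuple[float, int], ...] = field(default_factory=tuple)

    def __post_init__(self):
        t = np.asarray(self.time_points, dtype=float)
        s = np.asarray(self.survival_probs, dtype=float)
        if t.shape != s.shape or t.ndim != 1 or t.size < 2:
            raise ValueError("time_points/survival_probs must match, length >= 2")
        if t[0] != 0:
            raise ValueError("time grid must start at 0")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if s[0] != 1.0:
            raise ValueError("survival must start at 1")
        if np.any(s < 0) or np.any(s > 1):
            raise ValueError("survival probabilities must lie in [0, 1]")
        if np.any(np.diff(s) > 1e-12):
            raise ValueError("survival probabilities must be non-increasing")
        counts = [c for _, c in self.risk_table]
        if any(b > a for a, b in zip(counts, counts[1:])):
            raise ValueError("risk-table counts must be non-increasing")
        object.__setattr__(self, "time_points", t)
        object.__setattr__(self, "survival_probs", s)
        object.__setattr__(
            self,
            "risk_table",
            tuple((float(a), int(b)) for a, b in self.risk_table),
        )

    def to_csv(self, curve_path: str | Path, risk_path: str | Path) -> None:
        pd.DataFrame(
            {"time": self.time_points, "survival": self.survival_probs}
        ).to_csv(curve_path, index=False)
        pd.DataFrame(self.risk_table, columns=["time", "n_risk"]).to_csv(
            risk_path, index=False
        )

    @classmethod
    def from_csv(cls, curve_path: str | Path, risk_path: str | Path):
        curve = pd.read_csv(curve_path)
        risk = pd.read_csv(risk_path)
        return cls(
            time_points=curve["time"].to_numpy(float),
            survival_probs=curve["survival"].to_numpy(float),
            risk_table=tuple(zip(risk["time"], risk["n_risk"])),
        )


def simulate_ipd(spec: CohortSpec) -> SurvivalDataset:
    """Draw one right-censored cohort according to `spec`.

    Latent event times come from ``spec.family``; entry times are uniform on
    ``[0, accrual_months]``; the administrative censoring time for a patient
    entering at ``e`` is ``followup_months - e``. The observed time is the
    minimum of the two, with ``event = 1`` iff the latent time comes first.
    Observed times are floored at a small positive epsilon so that zero
    latent draws cannot violate the ``time > 0`` contract.
    """
    fam = get_family(spec.family)
    rng = np.random.default_rng(spec.seed)
    latent = fam.rvs(spec.params, size=spec.n_patients, rng=rng)
    entry = rng.uniform(0.0, spec.accrual_months, size=spec.n_patients) \
        if spec.accrual_months > 0 else np.zeros(spec.n_patients)
    censor = np.full(spec.n_patients, np.inf)
    if math.isfinite(spec.followup_months):
        censor = spec.followup_months - entry
    time = np.minimum(latent, censor)
    event = (latent <= censor).astype(int)
    time = np.maximum(time, 1e-9)
    return SurvivalDataset(
        time=time, event=event, endpoint=spec.endpoint, label=spec.family
    )


def median_of(spec: CohortSpec) -> float:
    """Analytic median of the latent event-time distribution (months)."""
    fam = get_family(spec.family)
    return float(fam.median(spec.params))


def digitize(dataset: SurvivalDataset, grid: Sequence[float]) -> DigitizedCurve:
    """Read the Kaplan–Meier curve of `dataset` off a time grid.

    Emulates digitizing a published figure: the product-limit estimate is
    evaluated at each grid time (right-continuous step convention) and the
    risk table records, at each grid time ``t``, the number of patients whose
    observed time exceeds ``t`` — the risk set for events after ``t``, which
    is what the reconstruction algorithm consumes.
    """
    from .survival import km_estimate  # deferred: avoids an import cycle

    grid = np.asarray(grid, dtype=float)
    if grid.size < 2 or grid[0] != 0 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be increasing and start at 0")
    km = km_estimate(dataset)
    surv = km.survival_at(grid)
    n_risk = [(float(g), int((dataset.time > g).sum())) for g in grid]
    return DigitizedCurve(
        time_points=grid, survival_probs=surv, risk_table=tuple(n_risk)
    )
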