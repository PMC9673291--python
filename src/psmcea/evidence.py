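"""Anchored indirect treatment comparison through a common comparator arm.

Two first-line trials share a sorafenib control arm; the head-to-head hazard
ratio between the experimental regimens is obtained by anchored indirect
comparison: on the log scale, ``log HR(A vs B) = log HR(A vs anchor) -
log HR(B vs anchor)``, with variances adding (the Bucher method). A Bayesian
fixed-effect counterpart with vague priors is provided as a cross-check; on
a two-trial star network its posterior coincides with the Bucher normal
approximation, so the two must agree up to Monte Carlo error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

Z975 = 1.959963984540054  # standard normal 97.5% quantile


class MissingIntervalError(ValueError):
    """An operation needed an uncertainty interval (or SE) that is absent."""


@dataclass(frozen=True)
class TrialEffect:
    """A hazard ratio reported by one trial for one ordered comparison."""

    trial_id: str
    comparison: tuple[str, str]  # (arm_a, arm_b): HR of arm_a vs arm_b
    endpoint: str  # "PFS" or "OS"
    hr: float
    ci_low: float | None = None
    ci_high: float | None = None

    def __post_init__(self):
        if not self.hr > 0:
            raise ValueError("hazard ratio must be > 0")
        if (self.ci_low is None) != (self.ci_high is None):
            raise ValueError("provide both CI bounds or neither")
        if self.ci_low is not None:
            if not (0 < self.ci_low <= self.hr <= self.ci_high):
                raise ValueError("require 0 < ci_low <= hr <= ci_high")

    @property
    def anchor(self) -> str:
        return self.comparison[1]


@dataclass(frozen=True)
class ComparativeEffect:
    """An indirect hazard ratio between two strategies, with uncertainty."""

    endpoint: str
    hr: float
    ci_low: float
    ci_high: float
    method: str  # "bucher" or "bayesian"

    def __post_init__(self):
        if not (0 < self.ci_low < self.hr < self.ci_high):
            raise ValueError("require 0 < ci_low < hr < ci_high")

    @property
    def se_log(self) -> float:
        return float(np.log(self.ci_high / self.ci_low) / (2 * Z975))


def se_from_ci(effect: TrialEffect) -> float:
    """Standard error of the log-HR from a symmetric-on-log 95% interval:
    ``(ln ci_high - ln ci_low) / (2 * 1.959964)``."""
    if effect.ci_low is None:
        raise MissingIntervalError(
            f"{effect.trial_id}: no confidence interval; supply an SE directly"
        )
    if effect.ci_low == effect.ci_high:
        raise MissingIntervalError(
            f"{effect.trial_id}: degenerate interval (ci_low == ci_high)"
        )
    return float(np.log(effect.ci_high / effect.ci_low) / (2 * Z975))


def _check_anchored(a: TrialEffect, b: TrialEffect) -> None:
    if a.endpoint != b.endpoint:
        raise ValueError(
            f"endpoint mismatch: {a.endpoint!r} vs {b.endpoint!r}"
        )
    if a.anchor != b.anchor:
        raise ValueError(
            f"anchor mismatch: {a.anchor!r} vs {b.anchor!r}; both effects "
            "must be expressed against the common comparator"
        )


def bucher_indirect(
    a_vs_anchor: TrialEffect, b_vs_anchor: TrialEffect
) -> ComparativeEffect:
    """Closed-form anchored indirect comparison (Bucher)."""
    _check_anchored(a_vs_anchor, b_vs_anchor)
    log_hr = np.log(a_vs_anchor.hr) - np.log(b_vs_anchor.hr)
    se = np.hypot(se_from_ci(a_vs_anchor), se_from_ci(b_vs_anchor))
    return ComparativeEffect(
        endpoint=a_vs_anchor.endpoint,
        hr=float(np.exp(log_hr)),
        ci_low=float(np.exp(log_hr - Z975 * se)),
        ci_high=float(np.exp(log_hr + Z975 * se)),
        method="bucher",
    )


def bucher_point(a_vs_anchor_hr: float, b_vs_anchor_hr: float) -> float:
    """Point estimate only, for effects reported without intervals."""
    return a_vs_anchor_hr / b_vs_anchor_hr


def bayesian_indirect(
    a_vs_anchor: TrialEffect,
    b_vs_anchor: TrialEffect,
    n_draws: int = 20_000,
    seed: int = 0,
) -> ComparativeEffect:
    """Fixed-effect Bayesian indirect comparison on the log-HR scale.

    Each trial contributes a normal likelihood for its log-HR against the
    anchor; with a vague normal prior on each treatment effect the posterior
    of the contrast is conjugate-normal, and is sampled directly. Summarised
    by the posterior median and central 95% interval. Deterministic for a
    given seed.

    Emits a warning for ``n_draws`` under 1,000 (the summaries become too
    noisy to be a meaningful cross-check of the closed form).
    """
    import warnings

    _check_anchored(a_vs_anchor, b_vs_anchor)
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if n_draws < 1000:
        warnings.warn(
            "fewer than 1,000 posterior draws; summaries will be noisy",
            stacklevel=2,
        )
    se_a = se_from_ci(a_vs_anchor)
    se_b = se_from_ci(b_vs_anchor)
    rng = np.random.default_rng(seed)
    # vague-prior limit: posterior d_X ~ N(log hr_X, se_X^2) independently
    d_a = rng.normal(np.log(a_vs_anchor.hr), se_a, size=n_draws)
    d_b = rng.normal(np.log(b_vs_anchor.hr), se_b, size=n_draws)
    contrast = np.exp(d_a - d_b)
    lo, med, hi = np.quantile(contrast, [0.025, 0.5, 0.975])
    return ComparativeEffect(
        endpoint=a_vs_anchor.endpoint,
        hr=float(med),
        ci_low=float(lo),
        ci_high=float(hi),
        method="bayesian",
    )
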