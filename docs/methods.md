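# Methods

This note documents the model implemented in `psmcea`: its structure,
assumptions, calibration, numerical choices, and the limits of what its
tests demonstrate.

## Model structure

A three-state partitioned survival model (PSM) for first-line advanced
hepatocellular carcinoma. State occupancy is derived directly from the two
endpoint survivor functions — no transition probabilities are estimated:

* progression-free share at time *t*: `S_PFS(t)`
* dead share: `1 − S_OS(t)`
* post-progression share: `S_OS(t) − S_PFS(t)`

A fitted PFS curve can cross above the OS curve in the far tail (the two
are fitted independently). The engine caps the progression-free share at
the alive share so the three states always partition the cohort exactly
(conservation holds to 1e-12 by construction), and flags any excess above
0.05 in the run log.

**Cycle accounting.** The cycle is 3 weeks (21 days; 17.38 cycles/year).
Cycle *k* (k = 1…H) represents the interval `(t_{k−1}, t_k]`; occupancy is
measured at the cycle end and every flow at cycle *k* is discounted by
`(1+r)^(−k)`, with `r = (1+annual)^(3/52) − 1` (5%/yr → 0.28%/cycle). There
is no half-cycle correction by default, matching common practice for this
genre of three-week-cycle oncology model; a flag switches the accrual basis
to the interval mean (trapezoid). The end-of-cycle convention makes totals
slight under-estimates of the continuous-time integrals; the engine's
brute-force test oracle shares the convention, and the half-cycle flag
brackets it from the other side.

**Horizon.** "Lifetime" is operationalised as 522 cycles (30 years).
Because the log-normal OS tail is heavy, roughly 0.5% of the synthetic
cohort is still alive at that point; the horizon-convergence property
(totals move < 0.1% under further extension) therefore holds once alive
occupancy is below 0.1%, which the tests verify at the horizon where that
condition is met rather than at the default.

## Cost and utility accounting

All costs in 2021 USD (1 USD = 6.47 RMB, metadata only). Per cycle:

* **Drug + administration** accrue on progression-free occupancy while the
  cycle index is within the treatment cap. The combination arm (sintilimab
  200 mg + bevacizumab biosimilar 15 mg/kg IV every 3 weeks) is capped at
  35 cycles (the 2-year stopping rule); oral lenvatinib (12 mg/day) is
  uncapped until progression. Whole-vial wastage is assumed for IV drugs
  and whole tablets per day for oral dosing; body weight defaults to 65 kg
  (config-exposed). The IV arm incurs the full administration bundle
  (diagnosis + injection + nursing + bed), the oral arm diagnosis only.
* **Follow-up** (the full six-item panel) accrues on all alive occupancy.
* **Subsequent treatment** is read as a per-cycle cost on post-progression
  occupancy (its magnitude sits alongside the other per-cycle quantities in
  the input table).
* **Adverse events** (grade ≥ 3, incidence ≥ 5%) enter as per-cycle
  probabilities — cumulative first-year incidence divided by 17.38 — applied
  to progression-free occupancy during the first year only, with a
  fractional weight (0.38) on the 18th cycle so the window is exactly one
  year. Each event costs its management price once and carries one cycle of
  utility decrement.
* **End-of-life cost** attaches to the increment of the dead state each
  cycle, discounted at that cycle.

QALY accrual per cycle is `(u_PFS·PFS + u_PP·PP − AE decrement) × 21/365`
with u_PFS = 0.745 and u_PP = 0.678; life-years accrue on alive occupancy.
Both are discounted like costs, so the reported LY totals are discounted
life-years.

## Survival inputs

**Fitting.** Right-censored maximum likelihood,
`Σ [event·log f(t) + (1−event)·log S(t)]`, over six families: exponential,
gamma, Weibull, Gompertz, log-normal, log-logistic. Log-normal and
log-logistic are parameterised as location/scale on log-time; Gompertz as
hazard `b·exp(a·t)` with the shape `a` allowed negative — in which case the
survivor function plateaus at `exp(−b/|a|)` and the distribution is
improper. Such fits are excluded from model selection whenever the plateau
exceeds a configurable floor (default 0.05), since a curve that never
reaches zero cannot support lifetime extrapolation. Selection minimises
AIC, with BIC and then a fixed family order breaking ties; the full
(AIC, BIC) table per family is exported.

Numerics: positive parameters are optimised on the log scale; starts are
method-of-moments values plus ×/÷2 scale perturbations (and both hazard
slopes for Gompertz); Nelder–Mead with 1e-8 function tolerance, best start
kept. The exponential rate uses its closed form `events / Σ time`. The
Weibull and log-normal paths are cross-checked against lifelines'
independent fitters in the test suite.

**HR adjustment.** The comparator arm shares the reference arm's fitted
curve shape through `S_comp(t) = S_ref(t)^(1/HR)`, where HR is the
intervention-vs-comparator hazard ratio (PFS 0.856, 95% CI 0.798–0.910; OS
0.618, 0.546–0.708). This is proportional hazards applied to the cumulative
hazard. The log-normal family is not closed under this transform — the
comparator curve is no longer log-normal — which is the standard, accepted
caveat of HR adjustment on a best-fitting AFT curve.

**Indirect comparison.** The head-to-head HRs come from an anchored
comparison through the shared sorafenib arm: on the log scale,
`log HR(A vs B) = log HR(A vs anchor) − log HR(B vs anchor)`, variances
adding (Bucher). A Bayesian fixed-effect counterpart with vague priors is
provided as a cross-check; on a two-trial star network its posterior is
conjugate-normal and must agree with the closed form up to Monte Carlo
error (tested). The closed-form PFS point estimate from the trial HRs,
0.56/0.66 ≈ 0.848, sits within 1% of the 0.856 used as the pipeline input;
the pipeline deliberately takes the published indirect HRs as config inputs
rather than regenerating them, because the trial-level standard errors
behind the published synthesis are not available. The OS comparison can
only be exercised with user-supplied inputs for the same reason.

**Curve reconstruction.** For digitized published curves, pseudo-IPD is
rebuilt interval by interval in the style of the standard published
reconstruction scheme, specialised to a risk table aligned with the
survival grid: the event count in each interval follows from the survival
drop applied to the incoming risk set, censorings absorb the remaining
decline of the risk count, events are spread evenly across the interval and
censorings placed at its end. Because censorings come last, the
product-limit ratio telescopes to `1 − d/n` regardless of event spacing, so
the reconstruction is exact on the grid up to integer rounding; the
round-trip tolerance (sup-distance of the two KM curves) is 0.02 at n = 500
on a half-month grid.

## Synthetic cohorts

The trial IPD behind the published model is not deposited, so the
`synthetic` module emulates it: latent event times from a named family,
entry uniform over an accrual window, administrative censoring at a fixed
cutoff (`censor time = followup − entry`). Draw order (event times, then
entry times) is fixed, making cohorts bit-stable per seed.

Default calibration (declared assumptions, shipped in the config):

| endpoint | family | median | log-time sd | basis |
|---|---|---|---|---|
| PFS | log-normal | 4.6 mo | 1.1 | median matches the trial's printed 4.6 months; sd assumed |
| OS | log-normal | 16 mo | 1.2 | median not reached in the trial (control 10.4 mo); both values assumed |

380 patients (the trial's experimental-arm size), 12-month accrual,
30-month cutoff. These choices are trial-realistic but **synthetic**: the
published fitted parameters are not available, so the package's absolute
per-arm totals are not expected to reproduce the published table. What the
passing tests do show is that the machinery is correct (conservation,
oracle agreement, parameter recovery, selection consistency, arithmetic on
the published totals); what they cannot show is agreement of extrapolated
absolute costs/QALYs with the unpublished curves. The generator also omits
features of real trial data — no dropout censoring (administrative only),
no covariate structure, no cure fraction, independent PFS/OS draws rather
than a joint progression–death process.

## Sensitivity analyses

**One-way DSA** re-runs the full model at each parameter's bounds (95% CI
where reported, else ±20%; the per-cycle discount range 0.00–0.44% as
printed) and ranks by ICER-interval width. Bounds producing non-positive
QALY gains are labelled (dominant/dominated) rather than forced into a
ratio.

**PSA** (5,000 iterations default) samples probabilities and utilities from
beta, costs from gamma — both moment-matched with mean at base and
sd = (high − low)/(2·1.96) — and HRs from log-normal with log-sd from the
CI. Negative utility decrements sample their magnitude and restore the
sign; infeasible beta moment matching falls back to a clipped normal draw
with a warning. Baseline survival-curve parameter uncertainty is *not*
sampled: curve uncertainty enters through the HR parameters only, mirroring
the published distribution list; the fitted curves stay fixed across
draws. CEAC(λ) is the fraction of draws with positive incremental net
monetary benefit `λ·ΔQ − ΔC`; the crossover WTP is the first grid value
(grid 0–50,000 by 500) with CEAC ≥ 0.5.

## Scenario

Real-world dosing reduces bevacizumab biosimilar from 15 to 7.5 mg/kg with
efficacy assumed unchanged: only the intervention arm's drug-cost line
moves (10 → 5 vials per cycle at 65 kg); QALYs and life-years are identical
to base by construction, which the pipeline asserts exactly.

## Known limitations

* Absolute extrapolated totals hinge on the synthetic OS calibration
  (declared, not published data).
* Proportional hazards between arms is an assumption carried from the
  indirect comparison; no population adjustment is attempted.
* Subsequent-treatment cost is interpreted per cycle in the
  post-progression state; the source table is ambiguous on this point.
* The Bayesian indirect comparison is the conjugate fixed-effect special
  case (exact for a two-trial star network); it is a cross-check, not a
  general NMA engine.
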