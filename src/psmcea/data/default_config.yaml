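# Packaged model inputs for the first-line advanced-HCC comparison:
# sintilimab + bevacizumab biosimilar vs. lenvatinib, Chinese health-system
# perspective, 2021 USD. Every uncertain input carries its base value, the
# deterministic-sensitivity range (95% CI where reported, otherwise +/-20%)
# and the probabilistic sampling family.
#
# The patient-level survival data behind the published model are not publicly
# deposited. The `survival.synthetic` block below is a SYNTHETIC calibration:
# the PFS median matches the trial's printed 4.6 months, but the log-time
# standard deviations and the OS median are declared modelling assumptions,
# not published values.

metadata:
  currency: 2021 USD
  usd_to_rmb: 6.47
  intervention: sintilimab_bevacizumab
  comparator: lenvatinib

settings:
  cycle_length_weeks: 3
  horizon_cycles: 522          # 30 years of 3-week cycles ("lifetime")
  annual_discount_rate: 0.05   # -> 0.28% per cycle, compound convention
  body_weight_kg: 65.0
  ae_window_years: 1.0
  half_cycle_correction: false
  wtp_thresholds: [12516.0, 25031.0, 37547.0]   # 1x, 2x, 3x GDP per capita
  wtp_grid_max: 50000.0
  wtp_grid_step: 500.0
  gompertz_plateau_floor: 0.05

survival:
  source: synthetic            # synthetic | ipd | digitized
  synthetic:
    n_patients: 380
    accrual_months: 12.0
    followup_months: 30.0
    seed: 20210618
    pfs: {family: log-normal, median_months: 4.6, sigma: 1.1}
    os: {family: log-normal, median_months: 16.0, sigma: 1.2}
  ipd:
    pfs: null                  # CSV path with header time,event (months, 0/1)
    os: null
  digitized:
    pfs: {curve: null, risk: null}
    os: {curve: null, risk: null}

# Indirect-comparison hazard ratios, intervention vs. comparator.
hazard_ratios:
  pfs: {value: 0.856, low: 0.798, high: 0.910, psa: lognormal}
  os: {value: 0.618, low: 0.546, high: 0.708, psa: lognormal}

# Anchored trial effects available to the NMA operations (the common
# comparator arm is sorafenib). Intervals are not printed for these in the
# source tables; the indirect-comparison CIs above are the pipeline inputs.
trial_effects:
  - {trial_id: ORIENT-32, arm_a: sintilimab_bevacizumab, arm_b: sorafenib, endpoint: PFS, hr: 0.56}
  - {trial_id: REFLECT, arm_a: lenvatinib, arm_b: sorafenib, endpoint: PFS, hr: 0.66}
  - {trial_id: REFLECT, arm_a: lenvatinib, arm_b: sorafenib, endpoint: OS, hr: 0.92}

drug_prices:                   # per vial / tablet
  sintilimab: {unit_mg: 100, value: 166.92, low: 133.54, high: 166.92, psa: gamma}
  bevacizumab_biosimilar: {unit_mg: 100, value: 177.13, low: 123.99, high: 177.13, psa: gamma}
  lenvatinib: {unit_mg: 4, value: 16.69, low: 11.68, high: 16.69, psa: gamma}

regimens:
  sintilimab_bevacizumab:
    components:
      - {drug: sintilimab, kind: flat_iv, dose_mg: 200}
      - {drug: bevacizumab_biosimilar, kind: weight_iv, mg_per_kg: 15}
    treatment_cap_cycles: 35   # 2-year treatment cap
    admin_items: [diagnosis, intravenous_injection, nursing, bed]
  lenvatinib:
    components:
      - {drug: lenvatinib, kind: oral_daily, mg_per_day: 12}
    treatment_cap_cycles: null # oral therapy until progression
    admin_items: [diagnosis]

costs:
  subsequent_per_cycle:        # post-progression treatment, per cycle in PP
    sintilimab_bevacizumab: {value: 442.29, low: 353.83, high: 530.74, psa: gamma}
    lenvatinib: {value: 631.81, low: 505.45, high: 758.17, psa: gamma}
  end_of_life: {value: 2132.67, low: 888.10, high: 6108.44, psa: gamma}
  followup_items:              # one panel per cycle while alive
    computer_tomography: {value: 90.43, low: 64.91, high: 146.83, psa: gamma}
    blood_biochemistry: {value: 24.27, low: 13.76, high: 38.02, psa: gamma}
    blood_routine: {value: 1.58, low: 0.77, high: 2.94, psa: gamma}
    urine_routine: {value: 0.67, low: 0.15, high: 1.39, psa: gamma}
    myocardial_enzyme: {value: 5.13, low: 3.09, high: 7.73, psa: gamma}
    alpha_fetoprotein: {value: 3.18, low: 2.16, high: 4.64, psa: gamma}
  admin_items:                 # per administration cycle
    diagnosis: {value: 5.13, low: 3.09, high: 7.73, psa: gamma}
    intravenous_injection: {value: 1.73, low: 0.46, high: 4.64, psa: gamma}
    nursing: {value: 1.27, low: 0.77, high: 1.85, psa: gamma}
    bed: {value: 2.05, low: 1.64, high: 2.47, psa: gamma}
  ae_event:                    # management cost per event
    hypertension: {value: 3.42, low: 2.73, high: 4.10, psa: gamma}
    proteinuria: {value: 22.10, low: 17.68, high: 26.52, psa: gamma}
    platelet_count_decreased: {value: 176.55, low: 141.24, high: 211.86, psa: gamma}
    elevated_bilirubin: {value: 77.28, low: 61.82, high: 92.74, psa: gamma}
    elevated_ast: {value: 77.28, low: 61.82, high: 92.74, psa: gamma}

# Grade >=3 treatment-related events with incidence >= 5%, expressed as
# per-cycle probabilities (annual incidence spread over 17.38 cycles/year,
# events assumed confined to the first year on treatment).
adverse_events:
  sintilimab_bevacizumab:
    hypertension: {value: 0.0072, low: 0.0058, high: 0.0087, psa: beta}
    platelet_count_decreased: {value: 0.0033, low: 0.0027, high: 0.0040, psa: beta}
  lenvatinib:
    hypertension: {value: 0.0132, low: 0.0106, high: 0.0158, psa: beta}
    proteinuria: {value: 0.0035, low: 0.0028, high: 0.0041, psa: beta}
    platelet_count_decreased: {value: 0.0029, low: 0.0023, high: 0.0035, psa: beta}
    elevated_bilirubin: {value: 0.0040, low: 0.0032, high: 0.0048, psa: beta}
    elevated_ast: {value: 0.0029, low: 0.0023, high: 0.0035, psa: beta}

utilities:
  pfs: {value: 0.745, low: 0.730, high: 0.760, psa: beta}
  pp: {value: 0.678, low: 0.655, high: 0.701, psa: beta}

disutilities:                  # one-cycle utility decrement per AE event
  hypertension: {value: -0.12, low: -0.14, high: -0.10, psa: beta}
  proteinuria: {value: -0.12, low: -0.14, high: -0.10, psa: beta}
  platelet_count_decreased: {value: 0.0, low: 0.0, high: 0.0, psa: fixed}
  elevated_bilirubin: {value: 0.0, low: 0.0, high: 0.0, psa: fixed}
  elevated_ast: {value: 0.0, low: 0.0, high: 0.0, psa: fixed}

discount:
  # value null -> derive the per-cycle rate from the annual rate (0.28%);
  # a number here (as set by the sensitivity analyses) overrides it
  per_cycle: {value: null, low: 0.0, high: 0.0044, psa: beta}

scenario:
  bevacizumab_mg_per_kg: 7.5   # real-world reduced dose; efficacy unchanged

psa:
  n_iterations: 5000
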