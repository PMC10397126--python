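# Model input parameters for the German lipid-lowering cost-effectiveness
# model: treatment-effect hazard ratios per drug and prevention setting,
# health-state utilities, and costs (EUR, inflation-adjusted to 2021).
#
# Variation entries are 95% confidence intervals (`ci`) for hazard ratios
# and utilities, and ±25% bands (`variation_pct`) for costs and the annual
# risk-increase factors.  `distribution` names the PSA sampling family.
#
# Fibrate hazard ratios are synthetic stand-ins of realistic magnitude for
# a fenofibrate-on-statin trial population; no published per-event values
# are transcribed here.
schema_version: 1
baseline_probabilities_file: baseline_probabilities_synthetic.yaml

settings:
  time_horizon: 20            # cycles of one year
  discount_rate: 0.03         # applied to both costs and utilities
  discount_rate_bounds: [0.00, 0.10]
  start_age: 63
  cvd_risk_growth: 1.14       # cardiovascular event rates grow 14%/year
  noncvd_risk_growth: 1.10    # non-cardiovascular mortality grows 10%/year
  psa_iterations: 1000

utilities:
  alive_without_cvd:
    age_65_70: {value: 0.65, ci: [0.64, 0.67], distribution: beta}
    age_70_plus: {value: 0.63, ci: [0.62, 0.65], distribution: beta}
  alive_with_cvd:
    age_65_70: {value: 0.57, ci: [0.56, 0.59], distribution: beta}
    age_70_plus: {value: 0.55, ci: [0.54, 0.57], distribution: beta}
  event_decrements:             # one-cycle disutility of acute events
    nonfatal_mi: {value: 0.04, ci: [0.02, 0.05], distribution: gamma}
    nonfatal_stroke: {value: 0.12, ci: [0.09, 0.16], distribution: gamma}
    unstable_angina_hosp: {value: 0.09, ci: [0.06, 0.13], distribution: gamma}
    coronary_revasc: {value: 0.01, ci: [0.01, 0.03], distribution: gamma}

costs_eur:
  annual_state:
    alive_without_cvd: {value: 4522, variation_pct: 25, distribution: gamma}
    alive_with_cvd: {value: 8008, variation_pct: 25, distribution: gamma}
  one_off_event:
    nonfatal_mi: {value: 8588, variation_pct: 25, distribution: gamma}
    nonfatal_stroke: {value: 10441, variation_pct: 25, distribution: gamma}
    unstable_angina_hosp: {value: 4791, variation_pct: 25, distribution: gamma}
    coronary_revasc: {value: 9901, variation_pct: 25, distribution: gamma}
  one_off_death:                # hospital/home weighted (71% / 29%)
    cvd_death: {value: 11842, variation_pct: 25, distribution: gamma}
    noncvd_death: {value: 3924, variation_pct: 25, distribution: gamma}
  annual_statin_cost_eur_per_year: 131.62

drugs:
  icosapent_ethyl:
    trial: REDUCE-IT
    median_followup_years: 4.9
    annual_cost_eur_per_year: 2400.0
    hazard_ratios:              # [point, ci_low, ci_high], Normal distribution
      primary:
        nonfatal_mi: [0.78, 0.67, 0.90]
        cvd_death: [0.90, 0.77, 1.04]
        noncvd_death: [1.14, 0.97, 1.31]
        nonfatal_stroke: [0.81, 0.69, 0.93]
        unstable_angina_hosp: [0.76, 0.64, 0.87]
        coronary_revasc: [0.76, 0.64, 0.87]
      secondary:
        nonfatal_mi: [0.68, 0.58, 0.79]
        cvd_death: [0.79, 0.67, 0.91]
        noncvd_death: [1.01, 0.85, 1.16]
        nonfatal_stroke: [0.71, 0.60, 0.82]
        unstable_angina_hosp: [0.67, 0.57, 0.77]
        coronary_revasc: [0.66, 0.56, 0.75]
  evolocumab:
    trial: FOURIER
    median_followup_years: 2.2
    annual_cost_eur_per_year: 5879.54
    hazard_ratios:
      secondary:
        nonfatal_mi: [0.72, 0.64, 0.81]
        cvd_death: [1.05, 0.88, 1.25]
        noncvd_death: [1.04, 0.91, 1.19]
        nonfatal_stroke: [0.91, 0.78, 1.07]
        unstable_angina_hosp: [0.99, 0.82, 1.18]
        coronary_revasc: [0.78, 0.71, 0.86]
  alirocumab:
    trial: ODYSSEY
    median_followup_years: 2.8
    annual_cost_eur_per_year: 7508.88
    hazard_ratios:
      secondary:
        nonfatal_mi: [0.86, 0.77, 0.96]
        cvd_death: [0.88, 0.74, 1.05]
        noncvd_death: [0.78, 0.66, 0.94]
        nonfatal_stroke: [0.73, 0.57, 0.93]
        unstable_angina_hosp: [0.61, 0.41, 0.92]
        coronary_revasc: [0.88, 0.79, 0.97]
  ezetimibe:
    trial: IMPROVE-IT
    median_followup_years: 6.0
    annual_cost_eur_per_year: 156.48
    hazard_ratios:
      secondary:
        nonfatal_mi: [0.87, 0.80, 0.95]
        cvd_death: [1.00, 0.89, 1.13]
        noncvd_death: [0.98, 0.90, 1.06]
        nonfatal_stroke: [0.86, 0.73, 1.00]
        unstable_angina_hosp: [1.06, 0.85, 1.33]
        coronary_revasc: [0.96, 0.90, 1.02]
  fibrate:
    trial: ACCORD
    median_followup_years: 4.7
    annual_cost_eur_per_year: 130.44
    hazard_ratios:              # synthetic stand-ins (see header note)
      primary:
        nonfatal_mi: [0.85, 0.70, 1.03]
        cvd_death: [0.93, 0.77, 1.12]
        noncvd_death: [0.99, 0.85, 1.15]
        nonfatal_stroke: [0.95, 0.76, 1.19]
        unstable_angina_hosp: [0.85, 0.68, 1.06]
        coronary_revasc: [0.89, 0.78, 1.02]
      secondary:
        nonfatal_mi: [0.82, 0.69, 0.98]
        cvd_death: [0.88, 0.74, 1.05]
        noncvd_death: [0.98, 0.86, 1.12]
        nonfatal_stroke: [0.90, 0.73, 1.11]
        unstable_angina_hosp: [0.83, 0.67, 1.02]
        coronary_revasc: [0.87, 0.77, 0.98]
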