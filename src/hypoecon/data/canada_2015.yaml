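# Default parameter bundle — Canada, 2015 CAN$, public payer perspective.
#
# Incidence-rate inputs, probabilities and utilities are identical to the
# U.S. bundle (event rates and QALYs are country-invariant in this model);
# only unit costs, drug acquisition costs and the willingness-to-pay
# threshold differ. Unit costs and per-event disutilities are SYNTHETIC
# calibration-derived defaults (see the note in us_2015.yaml and
# docs/methods.md) and should be overridden with provincial fee-schedule
# values for substantive costing work.
schema_version: hypoecon-parameters-1
country: Canada
currency: 2015 CAN$

cohorts:
  65-79:
    label: "65-79"
    diabetes_duration: 15.6
    hba1c: 7.1
    bmi: 31.1
    gfr: 61.0
  80plus:
    label: 80plus
    diabetes_duration: 17.8
    hba1c: 7.0
    bmi: 28.2
    gfr: 45.0

strategies:
  metformin:
    name: metformin
    base_rate: 1.0
    daily_smbg_tests: 0.94
    daily_injections: 0.0
    annual_drug_cost: 39.70
  sulfonylurea:
    name: sulfonylurea
    base_rate: 3.0
    daily_smbg_tests: 1.16
    daily_injections: 0.0
    annual_drug_cost: 208.84
  dpp4:
    name: dpp4
    base_rate: 1.0
    daily_smbg_tests: 0.94
    daily_injections: 0.0
    annual_drug_cost: 959.16
  tzd:
    name: tzd
    base_rate: 1.0
    daily_smbg_tests: 0.94
    daily_injections: 0.0
    annual_drug_cost: 566.16
  glp1:
    name: glp1
    base_rate: 1.3
    daily_smbg_tests: 0.94
    daily_injections: 1.0
    annual_drug_cost: 2592.26
  basal_insulin:
    name: basal_insulin
    base_rate: 6.3
    daily_smbg_tests: 2.08
    daily_injections: 1.0
    annual_drug_cost: 1102.82

risk_constants:
  duration_base: 1.037
  duration_cap: 20.0
  duration_offset: 9.0
  a1c_base: 0.82
  a1c_ref: 7.0
  bmi_base: 0.95
  bmi_floor: 21.0
  bmi_cap: 35.0
  bmi_ref: 33.0
  gfr_scale: 22700.0
  gfr_exponent: -0.86655
  gfr_floor: 15.0
  gfr_ref: 60.0
  gfr_legacy_divisor: false

severity:
  p_mild: 0.95
  p_moderate: 0.04
  p_severe: 0.01

resource_use:
  p_hcp_contact_any_event: 0.14
  p_assay_per_contact: 1.0
  n_extra_smbg_after_event: 3.9
  p_glucagon_moderate: 0.02
  severe_branch:
    gp: 0.26
    np: 0.13
    outpatient: 0.20
    er_only: 0.17
    hospitalization: 0.24
  p_glucagon_severe: 0.25
  p_ambulance_severe_transport: 1.00
  p_death_given_hospitalization: 0.20

unit_costs:
  # Synthetic, calibration-derived stand-ins for provincial fee schedules.
  country: Canada
  currency: 2015 CAN$
  gp_visit: 77.20
  np_visit: 55.00
  outpatient_visit: 110.00
  er_visit: 450.00
  hospitalization: 28170.00
  ambulance: 240.00
  glucagon_kit: 120.00
  blood_glucose_assay: 4.50
  smbg_strip: 0.36
  smbg_lancet: 0.04
  needle: 0.12
  home_monitor_annual: 12.00

utilities:
  u_base: 0.844
  disutility_per_event:
    # Synthetic, calibration-derived per-event QALY decrements.
    mild_daytime: 0.00700
    mild_nocturnal: 0.01313
    moderate_severe_daytime: 0.01320
    moderate_severe_nocturnal: 0.01770
  p_daytime_mild: 0.75
  p_daytime_modsev: 0.60
  fatal_event_year_fraction_lost: 0.5

settings:
  wtp_threshold: 53891.0   # 2014 per-capita GDP converted to CAN$ at 1.0720
  exchange_rate_us_to_can: 1.0720
  time_horizon: 1.0
  discount_rate: 0.0
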