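# Default parameter bundle — United States, 2015 US$, Medicare payer perspective.
#
# Cohort profiles, medication base rates, severity split, resource-use
# probabilities, utilities and the willingness-to-pay threshold are the
# published base-case inputs. Unit costs and per-event disutilities are
# SYNTHETIC defaults: the originals live in supplementary fee-schedule
# tables that are not redistributed here, so these values were calibrated
# so that the model reproduces the published per-person annual costs and
# QALYs (see docs/methods.md). Override them with payer fee-schedule
# values for any substantive costing work.
schema_version: hypoecon-parameters-1
country: US
currency: 2015 US$

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
    annual_drug_cost: 181.20
  sulfonylurea:
    name: sulfonylurea
    base_rate: 3.0
    daily_smbg_tests: 1.16
    daily_injections: 0.0
    annual_drug_cost: 226.10
  dpp4:
    name: dpp4
    base_rate: 1.0
    daily_smbg_tests: 0.94
    daily_injections: 0.0
    annual_drug_cost: 2055.20
  tzd:
    name: tzd
    base_rate: 1.0
    daily_smbg_tests: 0.94
    daily_injections: 0.0
    annual_drug_cost: 744.20
  glp1:
    name: glp1
    base_rate: 1.3
    daily_smbg_tests: 0.94
    daily_injections: 1.0
    annual_drug_cost: 1994.70
  basal_insulin:
    name: basal_insulin
    base_rate: 6.3
    daily_smbg_tests: 2.08
    daily_injections: 1.0
    annual_drug_cost: 531.20

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
  # Synthetic, calibration-derived stand-ins for the 2015 CMS fee schedule.
  country: US
  currency: 2015 US$
  gp_visit: 73.93
  np_visit: 62.84
  outpatient_visit: 140.00
  er_visit: 622.00
  hospitalization: 21872.00
  ambulance: 429.00
  glucagon_kit: 185.00
  blood_glucose_assay: 5.48
  smbg_strip: 0.32
  smbg_lancet: 0.08
  needle: 0.15
  home_monitor_annual: 15.00

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
  wtp_threshold: 54630.0   # 2014 per-capita GDP, US$
  exchange_rate_us_to_can: 1.0720
  time_horizon: 1.0
  discount_rate: 0.0
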