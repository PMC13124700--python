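# Default simulation: a 50,000-version synthetic quarterly extract whose
# drug exposure rates, association strengths, demographic mix, missingness
# and latency structure emulate the studied quinolone-pemphigoid reporting
# cohort. relative_risk = 1 would encode the null for a drug.
n_reports: 50000
drugs:
- name: OFLOXACIN
  synonyms:
  - Floxin
  - Tarivid
  - Ofloxacine
  exposure_prob: 0.03
  approval_date: 19901228
  relative_risk: 2.75
  relative_risk_by_sex: null
- name: CIPROFLOXACIN
  synonyms:
  - Cipro
  - Cipro XR
  - Ciproxin
  exposure_prob: 0.03
  approval_date: 19871022
  relative_risk: 2.31
  relative_risk_by_sex: null
- name: LEVOFLOXACIN
  synonyms:
  - Levaquin
  - Cravit
  exposure_prob: 0.025
  approval_date: 19961220
  relative_risk: 2.53
  relative_risk_by_sex: null
- name: MOXIFLOXACIN
  synonyms:
  - Avelox
  exposure_prob: 0.01
  approval_date: 19991210
  relative_risk: 1.0
  relative_risk_by_sex: null
- name: NORFLOXACIN
  synonyms:
  - Noroxin
  exposure_prob: 0.002
  approval_date: 19861031
  relative_risk: 25.14
  relative_risk_by_sex: null
event_term: Pemphigoid
event_base_rate: 0.01
duplicate_fraction: 0.1
missingness:
  sex: 0.131
  age: 0.175
  weight: 0.727
  occp_cod: 0.06
  outc_cod: 0.093
  event_dt: 0.25
  start_dt: 0.25
demographics:
  sex:
    F: 0.642
    M: 0.358
  age_band:
    <18: 0.013
    18-44: 0.179
    45-64: 0.225
    '>=65': 0.583
  weight_band:
    <80: 0.7
    '>=80': 0.3
  occupation:
    CN: 0.041
    MD: 0.413
    OT: 0.43
    PH: 0.116
  region:
    Others: 0.929
    Europe: 0.049
    North America: 0.016
    Asia: 0.006
  outcome:
    DE: 0.006
    HO: 0.741
    OT: 0.253
latency_model:
  family: lognormal
  median_days: 14.0
  sigma: 0.8
  value: null
year_range:
- 2004
- 2024
partial_event_dt_fraction: 0.02
seed: 0
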