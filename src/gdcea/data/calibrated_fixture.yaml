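states:
- state_without_complications
- state_with_multiple_complications
- necessary_tracheostomy
- necessary_enteral_feeding
- epilepsy
- interstitial_lung_disease
- major_bleeding
- death
adjacency:
  extra_edges: []
transitions:
  mono:
  - from: state_without_complications
    to: death
    p: 0.013906273386670033
  - from: state_without_complications
    to: state_with_multiple_complications
    p: 0.0050414940846882205
  - from: state_with_multiple_complications
    to: death
    p: 0.3936049795499326
  - from: state_without_complications
    to: necessary_tracheostomy
    p: 0.0050414940846882205
  - from: necessary_tracheostomy
    to: death
    p: 0.3936049795499326
  - from: state_without_complications
    to: necessary_enteral_feeding
    p: 0.0050414940846882205
  - from: necessary_enteral_feeding
    to: death
    p: 0.3936049795499326
  - from: state_without_complications
    to: epilepsy
    p: 0.0050414940846882205
  - from: epilepsy
    to: death
    p: 0.3936049795499326
  - from: state_without_complications
    to: interstitial_lung_disease
    p: 0.0050414940846882205
  - from: interstitial_lung_disease
    to: death
    p: 0.3936049795499326
  - from: state_without_complications
    to: major_bleeding
    p: 0.0050414940846882205
  - from: major_bleeding
    to: death
    p: 0.3936049795499326
  combo:
  - from: state_without_complications
    to: death
    p: 1.5005316811776755e-05
  - from: state_without_complications
    to: state_with_multiple_complications
    p: 0.006227705800505733
  - from: state_with_multiple_complications
    to: death
    p: 0.08774464884924749
  - from: state_without_complications
    to: necessary_tracheostomy
    p: 0.006227705800505733
  - from: necessary_tracheostomy
    to: death
    p: 0.08774464884924749
  - from: state_without_complications
    to: necessary_enteral_feeding
    p: 0.006227705800505733
  - from: necessary_enteral_feeding
    to: death
    p: 0.08774464884924749
  - from: state_without_complications
    to: epilepsy
    p: 0.006227705800505733
  - from: epilepsy
    to: death
    p: 0.08774464884924749
  - from: state_without_complications
    to: interstitial_lung_disease
    p: 0.006227705800505733
  - from: interstitial_lung_disease
    to: death
    p: 0.08774464884924749
  - from: state_without_complications
    to: major_bleeding
    p: 0.006227705800505733
  - from: major_bleeding
    to: death
    p: 0.08774464884924749
utilities:
  state_without_complications: 0.86
  state_with_multiple_complications: 0.44
  necessary_tracheostomy: 0.68
  necessary_enteral_feeding: 0.5
  epilepsy: 0.55
  interstitial_lung_disease: 0.55
  major_bleeding: 0.52
  death: 0.0
drugs:
  patient_weight_kg: 20.0
  imiglucerase:
    pack_size: 400.0
    pack_price: 21870.0
    dose_per_admin_per_kg: 2.5
    admins_per_week: 3.0
  ambroxol:
    pack_size: 600.0
    pack_price: 5.25
    daily_dose_per_kg: 25.0
  cost_multipliers:
    mono: 0.7002840776231465
    combo: 0.5764061604096037
economics:
  discount_rate: 0.05
  horizon_years: 6.0
  cycle_length_months: 1
  gdp_per_capita: 89358.0
  wtp_multipliers:
  - 1.0
  - 2.0
  - 3.0
psa:
  n_draws: 1000
  seed: 0
  se_fraction: 0.1
  sample_costs: true
  sample_utilities: true
  sample_transitions: true
  wtp_points: 21
owsa:
  perturbation_fraction: 0.1
  parameters:
  - imiglucerase_pack_price
  - ambroxol_pack_price
  - utility.state_without_complications
  - utility.state_with_multiple_complications
  - utility.necessary_tracheostomy
  - utility.necessary_enteral_feeding
  - utility.epilepsy
  - utility.interstitial_lung_disease
  - utility.major_bleeding
  - discount_rate
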