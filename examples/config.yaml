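# Full default configuration: code lists, price table, analysis
# constants (codes:) and synthetic-registry settings (simulation:).
codes:
  severity_map:
    mild:
    - F32.0
    - F32.8
    - F32.9
    - F33.0
    - F33.4
    - F33.8
    - F33.9
    moderate:
    - F32.1
    - F33.1
    severe:
    - F32.2
    - F32.3
    - F33.2
    - F33.3
  mdd_codes:
  - F32.0
  - F32.1
  - F32.2
  - F32.3
  - F32.8
  - F32.9
  - F33.0
  - F33.1
  - F33.2
  - F33.3
  - F33.4
  - F33.8
  - F33.9
  exclusion_codes:
    bipolar:
      icd10:
      - F30
      - F31
      icd8:
      - '296.19'
      - '296.39'
      - '296.89'
      - '296.99'
      - '298.19'
    other_affective:
      icd10:
      - F38
      - F39
      icd8: []
    persistent_mood:
      icd10:
      - F34
      icd8: []
    schizophrenia:
      icd10:
      - F20
      - F21
      - F22
      - F23
      - F24
      - F25
      - F28
      - F29
      icd8:
      - 295.x9
      - 297.x9
      - 298.29-298.99
      - '299.04'
      - '299.05'
      - '299.09'
    dementia:
      icd10:
      - F00
      - F01
      - F02
      - F03
      - G30
      - R54.9
      icd8:
      - 290.x
  antidepressant_class_prefixes:
    SSRI:
    - N06AB
    SNRI:
    - N06AX
    TCA:
    - N06AA
    MAOI:
    - N06AF
    - N06AG
  ect_codes:
  - BRTB1
  - BRXA1
  medicine_cost_groups:
    antidepressant:
    - N06A
    other_psychiatric:
    - N05A
    - N05B
  fixed_price_table:
    psychiatric:hospitalization:acute: 5000.0
    psychiatric:hospitalization:elective: 4500.0
    psychiatric:ed:na: 300.0
    psychiatric:outpatient:na: 250.0
    psychiatric:home_visit:na: 150.0
    somatic:hospitalization:acute: 3500.0
    somatic:hospitalization:elective: 3000.0
    somatic:ed:na: 250.0
    somatic:outpatient:na: 200.0
    primary:gp:na: 20.0
    primary:private_psychiatrist:na: 100.0
    primary:private_psychologist:na: 80.0
    primary:other_specialist:na: 60.0
  dkk_per_eur: 7.47
  window_days: 365
  activity_window_days: 90
  min_days_between_shifts: 0
  re_initiation_counts: false
  ect_always_shift: false
  study_years:
  - 1996
  - 2015
  age_group_edges:
  - 18
  - 25
  - 45
  - 65
  - 85
  age_group_labels:
  - 18-24
  - 25-44
  - 45-64
  - 65-84
  - 85+
  year_group_edges:
  - 1996
  - 2001
  - 2006
  - 2011
  year_group_labels:
  - 1996-2000
  - 2001-2005
  - 2006-2010
  - 2011-2015
  n_controls: 2
  allow_partial_match: true
  cost_mode: recorded
  include_index_day_in_post: false
  adjust_part1: false
  cluster_by_set: false
simulation:
  n_persons: 2000
  seed: 1
  sex_split: 0.62
  age_distribution:
    18-24: 0.12
    25-44: 0.33
    45-64: 0.28
    65-84: 0.22
    85+: 0.05
  severity_distribution:
    mild: 0.55
    moderate: 0.32
    severe: 0.13
  p_resistant: 0.158
  switch_hazard:
  - 0.35
  - 0.06
  redemption_interval_days: 30.0
  n_redemptions: 12
  p_ect_severe: 0.2
  hru_base_rates:
    psych_hospitalization_acute: 0.1
    psych_hospitalization_elective: 0.03
    psych_ed: 0.1
    psych_outpatient: 4.0
    psych_home_visit: 0.5
    private_psychiatrist: 0.3
    private_psychologist: 0.15
    somatic_hospitalization_acute: 0.35
    somatic_hospitalization_elective: 0.1
    somatic_ed: 0.35
    somatic_outpatient: 3.0
    gp: 7.5
    other_specialist: 1.8
  hru_multiplier:
    psych_hospitalization_acute: 2.4
    psych_hospitalization_elective: 2.5
    psych_ed: 1.9
    psych_outpatient: 1.6
    psych_home_visit: 2.3
    private_psychiatrist: 2.3
    private_psychologist: 1.3
    somatic_hospitalization_acute: 1.0
    somatic_hospitalization_elective: 1.0
    somatic_ed: 1.0
    somatic_outpatient: 1.0
    gp: 1.2
    other_specialist: 1.05
  hru_dispersion: 1.0
  bed_days_mean: 7.0
  cost_noise_sigma: 0.0
  rx_cost_mean: 30.0
  any_use_probs: null
  p_death: 0.02
  p_emigrate: 0.01
  p_exclusion_dx: 0.01
  p_comorbidity_dx: 0.25
  mode: realistic
  shift_offsets:
  - 60
  - 120
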