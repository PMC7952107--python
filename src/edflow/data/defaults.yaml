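pathway:
  specs:
    nurse_screening:
      family: gamma
      params:
      - 0.567
      - 4.9
    vitals:
      family: gamma
      params:
      - 1.58
      - 1.51
      shift: 1.0
    transfer_to_room:
      family: triangular
      params:
      - 5.0
      - 10.0
      - 12.0
    attending_eval:
      family: beta
      params:
      - 0.726
      - 1.08
      shift: 2.0
      scale_mult: 28.0
    resident_eval:
      family: beta
      params:
      - 1.11
      - 1.04
      shift: 2.0
      scale_mult: 28.0
    attending_resident_review:
      family: weibull
      params:
      - 6.4
      - 1.27
      shift: -0.001
    attending_reassessment:
      family: exponential
      params:
      - 3.88
      shift: -0.001
    testing_treatment_esi4:
      family: gamma
      params:
      - 136.0
      - 0.874
      shift: 5.0
    testing_treatment_esi5:
      family: weibull
      params:
      - 45.1
      - 0.701
      shift: 5.0
    nurse_discharge:
      family: triangular
      params:
      - 5.0
      - 10.0
      - 15.0
    bed_cleaning:
      family: lognormal
      params:
      - 17.4
      - 16.2
      shift: 2.0
  p_test_esi4: 0.225
  p_test_esi5: 0.119
resources:
  n_rooms: 12
  n_nurses: 2
  n_providers: 2
  n_residents: 2
  resident_fraction: 1.0
profile:
  hourly_rates:
  - 5.162167158223421
  - 4.269783879111095
  - 3.4303181578112723
  - 2.7003400910289637
  - 2.130315168735021
  - 1.7621648162398786
  - 1.63
  - 1.7621648162398786
  - 2.130315168735021
  - 2.7003400910289637
  - 3.4303181578112723
  - 4.269783879111095
  - 5.162167158223421
  - 6.048102046837448
  - 6.869080656159397
  - 7.571125371900313
  - 8.108207481775477
  - 8.445175994095528
  - 8.56
  - 8.445175994095528
  - 8.108207481775477
  - 7.571125371900314
  - 6.8690806561594
  - 6.048102046837448
  esi4_fraction: 0.7970730839375473
pathway_variant: vitals_before_room
meta:
  description: Calibrated low-acuity pediatric ED model defaults
  calibration: resource counts and trainee first-touch routing selected by grid search
    against the published current-testing and benchmark-testing LOS/wait surface (5
    reps x 1 year)
  units: minutes; arrival rates patients/hour
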