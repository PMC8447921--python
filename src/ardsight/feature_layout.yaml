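# Machine-readable row layout of the 49 x 32 feature matrix.
n_rows: 49
n_steps: 32
constant_rows:
  0: age_zscored
  1: male
  2: female
  3: antibiotics_before_prediction
  4: supplemental_o2_before_prediction
  5: heart_failure_history
time_varying:
  # each feature occupies two rows: mask_row (0/1) then value_row (z-scored)
  order:
    - SysBP
    - DiasBP
    - HR
    - Temp
    - RespRate
    - SpO2
    - creatinine
    - BUN
    - bilirubin
    - glucose
    - INR
    - WBC
    - RBC
    - platelets
    - neutrophil_pct
    - lymphocyte_pct
    - monocyte_pct
    - hematocrit
    - lactate
    - AST
    - ALT
  first_row: 6
time_delta_row: 48  # z-scored minutes since the previous kept step
padding: left  # all-zero columns occupy the oldest positions
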