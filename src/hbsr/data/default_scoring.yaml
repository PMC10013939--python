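smoking_grades:
  daily: high
  occasional: moderate
  ex_smoker: moderate
  never: low
bmi_grades:
  ge30: high
  b25_29_9: moderate
  lt25: low
exercise_grades:
  ge4_per_week: low
  w2_3_per_week: low
  once_per_week: moderate
  m2_3_per_month: moderate
  rare_or_none: high
adverse_salting:
- before_tasting
veg_days_threshold: 6
adverse_alcohol_freq:
- ge2_per_week
- once_per_week
alcohol_unit_limits:
  female: 8.0
  male: 16.0
alcohol_strict_inequality: true
high_band_cutoff: 6
missing_policy: require_complete
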