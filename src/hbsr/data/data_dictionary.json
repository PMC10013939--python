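{
  "format": "CSV, UTF-8, comma-delimited, header row; blank cells are missing values",
  "columns": {
    "id": "opaque unique identifier (string)",
    "group": [
      "patient",
      "control"
    ],
    "age": "integer years, 18-54 inclusive",
    "sex": [
      "male",
      "female"
    ],
    "education": [
      "basic",
      "secondary",
      "higher"
    ],
    "marital": [
      "married_cohabiting",
      "single",
      "divorced_widowed"
    ],
    "smoking": [
      "daily",
      "occasional",
      "ex_smoker",
      "never"
    ],
    "bmi": "kg/m^2, optional; may instead be derived from height_cm and weight_kg",
    "height_cm": "optional, used with weight_kg when bmi is absent",
    "weight_kg": "optional, used with height_cm when bmi is absent",
    "exercise": [
      "ge4_per_week",
      "w2_3_per_week",
      "once_per_week",
      "m2_3_per_month",
      "rare_or_none"
    ],
    "veg_days": "integer 0-7 days/week; binary tokens ge6_days/lt6_days map to 6/0",
    "salting": [
      "before_tasting",
      "when_needed",
      "never"
    ],
    "alcohol_freq": [
      "ge2_per_week",
      "once_per_week",
      "m2_3_per_month",
      "few_per_year",
      "none"
    ],
    "alcohol_units_7d": "non-negative standard drink units in the last 7 days"
  }
}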