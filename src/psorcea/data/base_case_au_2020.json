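{
  "currency": "AUD (2020)",
  "drugs": {
    "adalimumab": {
      "cost_per_dispense": 1132,
      "dosing": {"loading_dose_weeks": [0, 1], "steady_interval_weeks": 2},
      "dispensing": {"induction_weeks": [0, 4, 8], "maintenance_interval_weeks": 4, "maintenance_start_week": 12},
      "p_induction": 0.695, "p_induction_ci": [0.66, 0.726],
      "p_maintenance": 0.671, "p_maintenance_ci": [0.529, 0.787]
    },
    "etanercept": {
      "cost_per_dispense": 1026,
      "dosing": {"loading_dose_weeks": [0], "steady_interval_weeks": 1},
      "dispensing": {"induction_weeks": [0, 4, 8], "maintenance_interval_weeks": 4, "maintenance_start_week": 12},
      "p_induction": 0.401, "p_induction_ci": [0.354, 0.451],
      "p_maintenance": 0.555, "p_maintenance_ci": [0.501, 0.609]
    },
    "guselkumab": {
      "cost_per_dispense": 3771,
      "dosing": {"loading_dose_weeks": [0, 4], "steady_interval_weeks": 8},
      "dispensing": {"induction_weeks": [0, 4], "maintenance_interval_weeks": 8, "maintenance_start_week": 12},
      "p_induction": 0.868, "p_induction_ci": [0.838, 0.894],
      "p_maintenance": 0.882, "p_maintenance_ci": [0.846, 0.911]
    },
    "ixekizumab": {
      "cost_per_dispense": 3396,
      "dosing": {"loading_dose_weeks": [0, 2, 4, 6, 8, 10, 12], "steady_interval_weeks": 4},
      "dispensing": {"induction_weeks": [0, 2, 4, 6, 8, 10], "maintenance_interval_weeks": 12, "maintenance_start_week": 12},
      "p_induction": 0.888, "p_induction_ci": [0.865, 0.909],
      "p_maintenance": 0.85, "p_maintenance_ci": [0.792, 0.894]
    },
    "risankizumab": {
      "cost_per_dispense": 5375,
      "dosing": {"loading_dose_weeks": [0, 4], "steady_interval_weeks": 12},
      "dispensing": {"induction_weeks": [0, 4], "maintenance_interval_weeks": 12, "maintenance_start_week": 12},
      "p_induction": 0.892, "p_induction_ci": [0.869, 0.913],
      "p_maintenance": 0.901, "p_maintenance_ci": [0.863, 0.929]
    },
    "secukinumab": {
      "cost_per_dispense": 1440,
      "dosing": {"loading_dose_weeks": [0, 1, 2, 3, 4], "steady_interval_weeks": 4},
      "dispensing": {"induction_weeks": [0, 1, 2, 3, 4, 8], "maintenance_interval_weeks": 4, "maintenance_start_week": 12},
      "p_induction": 0.831, "p_induction_ci": [0.802, 0.857],
      "p_maintenance": 0.886, "p_maintenance_ci": [0.806, 0.936]
    },
    "tildrakizumab": {
      "cost_per_dispense": 3246,
      "dosing": {"loading_dose_weeks": [0, 4], "steady_interval_weeks": 12},
      "dispensing": {"induction_weeks": [0, 4], "maintenance_interval_weeks": 12, "maintenance_start_week": 12},
      "p_induction": 0.629, "p_induction_ci": [0.573, 0.684],
      "p_maintenance": 0.878, "p_maintenance_ci": [0.843, 0.914]
    },
    "ustekinumab": {
      "cost_per_dispense": 3910,
      "dosing": {"loading_dose_weeks": [0, 4], "steady_interval_weeks": 12},
      "dispensing": {"induction_weeks": [0, 4], "maintenance_interval_weeks": 12, "maintenance_start_week": 12},
      "p_induction": 0.697, "p_induction_ci": [0.663, 0.731],
      "p_maintenance": 0.725, "p_maintenance_ci": [0.659, 0.782]
    }
  },
  "monitoring": {
    "visit_induction": 113,
    "visit_maintenance": 75,
    "investigations_induction": 738,
    "investigations_maintenance": 80
  },
  "bsc": {
    "cyclosporine_induction": 2360,
    "cyclosporine_maintenance": 5644,
    "foam_induction": 128,
    "foam_maintenance": 256
  },
  "utilities": {
    "u_uncontrolled": 0.64,
    "u_uncontrolled_sd": 0.49,
    "u_controlled": 0.89,
    "u_controlled_sd": 0.11
  },
  "timeline": {
    "cycle_weeks": 12,
    "horizon_weeks": 96,
    "maintenance_review_interval_weeks": 24,
    "weeks_per_year": 52.0,
    "annual_discount_rate": 0.0
  },
  "sequencing_rule": "base",
  "notes": [
    "Drug costs are 2020 AUD per PBS dispense, net of the AUD41.00 patient co-payment.",
    "Ustekinumab priced at the single 45 mg dispense suitable for an 85 kg patient.",
    "Dispense calendars reflect PBS pack sizes: adalimumab 2 x 40 mg and etanercept 4 x 50 mg per pack (4-weekly supply), ixekizumab single pens during induction then a 3-pen pack per 12 weeks, secukinumab 2 x 150 mg pens = one 300 mg dose."
  ]
}
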