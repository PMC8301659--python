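{
  "description": "Two-arm comparisons for the six remdesivir COVID-19 trial publications, typed in from the summary statistics those publications print. Event-count payloads are the published per-arm counts; ratio payloads are the published effect estimates with 95% CIs. Solidarity no-ventilation counts are derived from the publication's totals minus its ventilated-at-entry deaths (301-98=203 of 2743-254=2489; 303-71=232 of 2708-233=2475).",
  "comparisons": [
    {
      "trial_id": "ACTT-1-preliminary",
      "outcome": "time_to_recovery",
      "subgroup": "",
      "outcome_kind": "ratio_ci",
      "direction": "greater_is_benefit",
      "payload": {"ratio": 1.32, "ci_lower": 1.12, "ci_upper": 1.55, "level": 0.95, "n1": 538, "n2": 521},
      "notes": "recovery rate ratio, remdesivir vs placebo"
    },
    {
      "trial_id": "ACTT-1-preliminary",
      "outcome": "mortality_day14",
      "subgroup": "",
      "outcome_kind": "binary_counts",
      "direction": "lower_is_benefit",
      "payload": {"n1": 538, "y1": 32, "n2": 521, "y2": 54},
      "notes": "deaths by day 14"
    },
    {
      "trial_id": "Wang",
      "outcome": "clinical_improvement_day28",
      "subgroup": "",
      "outcome_kind": "binary_counts",
      "direction": "greater_is_benefit",
      "payload": {"n1": 158, "y1": 103, "n2": 79, "y2": 45},
      "notes": "patients clinically improved by day 28"
    },
    {
      "trial_id": "Wang",
      "outcome": "mortality_day28",
      "subgroup": "",
      "outcome_kind": "binary_counts",
      "direction": "lower_is_benefit",
      "payload": {"n1": 158, "y1": 22, "n2": 78, "y2": 10},
      "notes": "28-day mortality (one placebo withdrawal excluded)"
    },
    {
      "trial_id": "Wang",
      "outcome": "time_to_improvement",
      "subgroup": "early_treatment",
      "outcome_kind": "ratio_ci",
      "direction": "greater_is_benefit",
      "payload": {"ratio": 1.52, "ci_lower": 0.95, "ci_upper": 2.43, "level": 0.95, "n1": 71, "n2": 47},
      "notes": "hazard ratio for clinical improvement, symptoms <10 days at treatment start"
    },
    {
      "trial_id": "Wang",
      "outcome": "mortality_day28",
      "subgroup": "early_treatment",
      "outcome_kind": "binary_counts",
      "direction": "lower_is_benefit",
      "payload": {"n1": 71, "y1": 8, "n2": 47, "y2": 7},
      "notes": "28-day mortality, symptoms <10 days at treatment start"
    },
    {
      "trial_id": "GS-US-540-5773",
      "outcome": "clinical_improvement_day14",
      "subgroup": "",
      "outcome_kind": "binary_counts",
      "direction": "greater_is_benefit",
      "payload": {"n1": 200, "y1": 129, "n2": 197, "y2": 107},
      "notes": "improvement of >=2 points on the 7-point ordinal scale at day 14; 5-day vs 10-day remdesivir"
    },
    {
      "trial_id": "GS-US-540-5773",
      "outcome": "mortality_day14",
      "subgroup": "",
      "outcome_kind": "binary_counts",
      "direction": "lower_is_benefit",
      "payload": {"n1": 200, "y1": 16, "n2": 197, "y2": 21},
      "notes": "deaths by day 14; 5-day vs 10-day remdesivir"
    },
    {
      "trial_id": "ACTT-1-final",
      "outcome": "time_to_recovery",
      "subgroup": "",
      "outcome_kind": "ratio_ci",
      "direction": "greater_is_benefit",
      "payload": {"ratio": 1.29, "ci_lower": 1.12, "ci_upper": 1.49, "level": 0.95, "n1": 541, "n2": 521},
      "notes": "recovery rate ratio, remdesivir vs placebo"
    },
    {
      "trial_id": "ACTT-1-final",
      "outcome": "mortality_day15",
      "subgroup": "",
      "outcome_kind": "binary_counts",
      "direction": "lower_is_benefit",
      "payload": {"n1": 541, "y1": 35, "n2": 521, "y2": 61},
      "notes": "deaths by day 15"
    },
    {
      "trial_id": "ACTT-1-final",
      "outcome": "mortality_day29",
      "subgroup": "",
      "outcome_kind": "binary_counts",
      "direction": "lower_is_benefit",
      "payload": {"n1": 541, "y1": 59, "n2": 521, "y2": 77},
      "notes": "deaths by day 29"
    },
    {
      "trial_id": "GS-US-540-5774",
      "outcome": "clinical_status_day11",
      "subgroup": "5day_vs_soc",
      "outcome_kind": "ratio_ci",
      "direction": "greater_is_benefit",
      "payload": {"ratio": 1.65, "ci_lower": 1.09, "ci_upper": 2.48, "level": 0.95, "n1": 199, "n2": 200},
      "notes": "proportional-odds ratio for better clinical status, 5-day remdesivir vs standard of care"
    },
    {
      "trial_id": "GS-US-540-5774",
      "outcome": "clinical_status_day11",
      "subgroup": "10day_vs_soc",
      "outcome_kind": "ratio_ci",
      "direction": "greater_is_benefit",
      "payload": {"ratio": 1.31, "ci_lower": 0.88, "ci_upper": 1.95, "level": 0.95, "n1": 197, "n2": 200},
      "notes": "proportional-odds ratio for better clinical status, 10-day remdesivir vs standard of care"
    },
    {
      "trial_id": "Solidarity",
      "outcome": "inhospital_mortality",
      "subgroup": "",
      "outcome_kind": "binary_counts",
      "direction": "lower_is_benefit",
      "payload": {"n1": 2743, "y1": 301, "n2": 2708, "y2": 303},
      "notes": "in-hospital deaths, remdesivir vs standard of care"
    },
    {
      "trial_id": "Solidarity",
      "outcome": "inhospital_mortality",
      "subgroup": "no_ventilation",
      "outcome_kind": "binary_counts",
      "direction": "lower_is_benefit",
      "payload": {"n1": 2489, "y1": 203, "n2": 2475, "y2": 232},
      "notes": "in-hospital deaths among patients not ventilated at entry (totals minus ventilated-at-entry deaths)"
    }
  ]
}
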