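{
  "schema": "deprisk-riskmodel-1",
  "outcome_label": "incident_mdd",
  "provenance": "external",
  "penalty": null,
  "intercept": -8.231075,
  "coefficients": {
    "sex_female=1": 0.85,
    "nonwhite=1": 0.69,
    "trauma=1": 0.45,
    "trauma=2": 0.8,
    "school_disengaged=1": 0.25,
    "loneliness=1": 0.9,
    "fights=1": 0.7,
    "ran_away=1": 1.3,
    "substance_ever=1": 0.15,
    "caregiver1_q=2": 0.4,
    "caregiver1_q=3": 0.9,
    "caregiver1_q=4": 0.9,
    "caregiver1_q=5": 1.45,
    "caregiver2_q=2": 0.2,
    "caregiver2_q=3": 0.55,
    "caregiver2_q=4": 0.4,
    "caregiver2_q=5": 0.6,
    "family_conflict_q=2": 0.5,
    "family_conflict_q=3": 0.8,
    "family_conflict_q=4": 1.2,
    "family_conflict_q=5": 1.3
  },
  "interactions": {}
}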