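# Example study configuration. Every key is optional; omitted keys fall back
# to the default study definition (see vocburden.codesets.StudyConfig).
# Codes may be written with or without dots.

scd_codes: ["282.41", "282.42", "282.60", "282.61", "282.62", "282.63",
            "282.64", "282.65", "282.66", "282.67", "282.68", "282.69"]
voc_episode_codes: ["282.42", "282.62", "282.64", "282.69"]
voc_primary_reason_codes: ["282.41", "282.42", "282.60", "282.61", "282.62",
                           "282.63", "282.64", "282.65", "282.66", "282.67",
                           "282.68", "282.69"]
trial_exclusion_codes: ["V70.7"]

# ILLUSTRATIVE complication mapping — supply an authoritative list for real
# studies. match_mode defaults to prefix for categories.
complication_categories:
  - label: infectious and parasitic diseases
    codes: ["038", "041", "079", "112", "590"]
  - label: fever
    codes: ["780.6"]
  - label: pulmonary disorders
    codes: ["480", "486", "517.3", "415.11", "518.81"]
  - label: cerebrovascular conditions
    codes: ["430", "431", "433", "434", "435", "436", "437", "438"]
  - label: thrombosis/DVT
    codes: ["453"]
  - label: aseptic (avascular) bone necrosis
    codes: ["733.4"]

study_start: 2009-01-01
study_end: 2013-12-31
identification_window: [2009-07-01, 2012-12-31]
baseline_days: 183
followup_min_days: 365
episode_gap_days: 3
setting_hierarchy: [inpatient, ER, outpatient, office, other]
min_age: 18
rng_seed: 0
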