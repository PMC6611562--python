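# Example simulation parameters. Every key is optional; omitted keys fall
# back to vocburden.synthetic_data.SimParams defaults (which describe a
# "clean" population with no eligibility noise).

n_patients: 500
voc_rate_mean: 3.31            # episodes per person-year
voc_rate_dispersion: 0.45      # gamma shape of patient-level rate mixing
setting_probs:                 # proportional to first-year per-patient means
  inpatient: 0.37857142857142856
  ER: 0.32142857142857145
  outpatient: 0.18214285714285713
  office: 0.08571428571428572
  other: 0.03214285714285714
p_complicated: 0.297
p_complication_primary: 0.5
category_probs:
  infectious and parasitic diseases: 0.30
  fever: 0.22
  pulmonary disorders: 0.18
  cerebrovascular conditions: 0.12
  thrombosis/DVT: 0.10
  aseptic (avascular) bone necrosis: 0.08
episode_duration_days: {dist: lognormal, mu: 0.9, sigma: 0.7, cap: 30}
claims_per_episode: {dist: poisson_plus_one, lam: 0.8}
inpatient_los_days: {dist: lognormal, mu: 1.4, sigma: 0.8, cap: 60}

# eligibility noise
p_trial_code: 0.02
p_dual_eligible: 0.03
p_enrollment_gap: 0.05
p_under_age: 0.02

# baseline utilization / comorbidity
baseline_er_mean: 2.3
baseline_er_dispersion: 0.3
baseline_ip_mean: 0.45
baseline_ip_dispersion: 0.3
p_baseline_comorbidity: 0.3

seed: 0
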