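# vocburden

Claims-based construction and descriptive analysis of vaso-occlusive crisis
(VOC) episodes in sickle cell disease (SCD), built as a reusable, tested
pipeline over administrative-claims-style tables:

1. **codesets** — ICD-9-CM code sets, date windows, thresholds, and the
   place-of-service hierarchy as validated, file-overridable configuration.
2. **synthetic_data** — a Medicaid-like claims generator (gamma-Poisson VOC
   counts, multi-claim episodes, injected eligibility violations) with full
   ground truth, so every downstream stage has a recoverable target.
3. **cohort** — index-date identification, continuous-enrollment checks,
   the exclusion cascade, Deyo-adapted Charlson index, baseline ER/inpatient
   utilization.
4. **episodes** — the core algorithm: VOC-coded claims merged into episodes
   across a configurable day gap (default 3; a strictly larger gap splits),
   hierarchical setting assignment (inpatient > ER > outpatient > office >
   other), and complicated/uncomplicated classification from concurrent
   complication-category diagnoses.
5. **utilization** — first-year SCD-related ER visits and hospitalizations,
   primary-reason attribution from the primary discharge diagnosis (ER
   visits leading to admission within the gap window fold into the stay),
   length-of-stay summaries (mean/SD/median/IQR).
6. **report** — machine-readable (JSON) and human-readable (Markdown)
   descriptive summaries with deterministic formatting.

The bundled complication-category code mapping is **illustrative only**;
supply an authoritative list via the config file for real studies.

## Command-line usage

```bash
# full chain: simulate -> select-cohort -> episodes -> visits -> report
vocburden run-all --out out/ --seed 17

# or step by step, with explicit configuration
vocburden simulate --params examples/params.yaml --config examples/study.yaml \
    --out out/ --seed 17
vocburden select-cohort --config examples/study.yaml --in out/ --out out/
vocburden episodes --config examples/study.yaml --cohort out/cohort.csv \
    --claims out/claims.csv --out out/
vocburden visits --cohort out/cohort.csv --claims out/claims.csv --out out/
vocburden report --in out/ --out out/report.json out/report.md
```

Both YAML files are fully optional; omitted keys fall back to the default
study definition (identification window 2009-07-01..2012-12-31, 183-day
baseline, 365-day minimum follow-up, 3-day episode gap, VOC episode codes
282.42/282.62/282.64/282.69). See `examples/study.yaml` and
`examples/params.yaml` for the documented schemas. Runs with the same seed
produce byte-identical outputs.

Table schemas (CSV, day-resolution dates):

- `patients.csv`: patient_id, birth_date, sex, race, region
- `enrollment.csv`: patient_id, span_start, span_end, medical, pharmacy,
  dual_eligible
- `claims.csv`: claim_id, patient_id, service_start, service_end,
  place_of_service, claim_type, dx1..dxK (dx1 = primary diagnosis)

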