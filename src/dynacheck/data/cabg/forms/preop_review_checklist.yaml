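form:
  id: preop_review_checklist
  meta:
    title: Pre-operative review
    author: dynacheck
    version: '1.0'
    created: '2024-01-15'
  problems:
  - id: preop_risk
    description: Pre-operative review
    algorithms:
    - renal_alert
    - diabetes_screen
    items:
    - id: hb_reviewed
      text: 'Hemoglobin reviewed: {hemoglobin} g/dL'
      supplementary:
      - kind: patient_data
        payload: hemoglobin
    - id: meds_reconciled
      text: Medication reconciliation completed
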