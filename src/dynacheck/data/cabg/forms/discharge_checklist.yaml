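form:
  id: discharge_checklist
  meta:
    title: Discharge review
    author: dynacheck
    version: '1.0'
    created: '2024-01-15'
  problems:
  - id: discharge
    description: Discharge review
    items:
    - id: followup_booked
      text: Follow-up appointment booked
    - id: rehab_referral
      text: Cardiac rehabilitation referral made
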