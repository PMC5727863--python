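form:
  id: time_out_checklist
  meta:
    title: Surgical time-out
    author: dynacheck
    version: '1.0'
    created: '2024-01-15'
  problems:
  - id: time_out
    description: Surgical time-out
    items:
    - id: correct_patient
      text: Correct patient, site and procedure confirmed
      priority: high
    - id: antibiotics_given
      text: Prophylactic antibiotics given within 60 min
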