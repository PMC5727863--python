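form:
  id: admission_checklist
  meta:
    title: Ward admission
    author: dynacheck
    version: '1.0'
    created: '2024-01-15'
  problems:
  - id: admission
    description: Ward admission
    algorithms:
    - crossmatch_check
    items:
    - id: identity_verified
      text: Patient identity verified against wristband
    - id: consent_present
      text: Signed informed consent in chart
    - id: crossmatch_item
      text: Blood samples for cross-typing has been taken
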