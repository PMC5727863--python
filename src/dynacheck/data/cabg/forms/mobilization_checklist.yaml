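form:
  id: mobilization_checklist
  meta:
    title: Mobilization
    author: dynacheck
    version: '1.0'
    created: '2024-01-15'
  problems:
  - id: mobilization
    description: Mobilization
    items:
    - id: pain_controlled
      text: Pain adequately controlled before mobilizing
    - id: sternal_precautions
      text: Sternal precautions explained
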