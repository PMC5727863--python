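form:
  id: icu_round_checklist
  meta:
    title: ICU daily round
    author: dynacheck
    version: '1.0'
    created: '2024-01-15'
  problems:
  - id: icu_round
    description: ICU daily round
    items:
    - id: sedation_reviewed
      text: Sedation level reviewed
    - id: feeding_plan
      text: Feeding plan documented
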