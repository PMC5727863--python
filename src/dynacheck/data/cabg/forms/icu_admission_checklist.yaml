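form:
  id: icu_admission_checklist
  meta:
    title: ICU admission
    author: dynacheck
    version: '1.0'
    created: '2024-01-15'
  problems:
  - id: icu_admission
    description: ICU admission
    items:
    - id: ventilator_settings
      text: Ventilator settings confirmed
    - id: lines_checked
      text: Lines and drains checked and labelled
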