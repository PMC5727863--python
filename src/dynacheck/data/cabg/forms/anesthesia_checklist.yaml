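form:
  id: anesthesia_checklist
  meta:
    title: Anesthesia induction
    author: dynacheck
    version: '1.0'
    created: '2024-01-15'
  problems:
  - id: induction
    description: Anesthesia induction
    items:
    - id: airway_assessed
      text: Airway assessment documented
    - id: emergency_drugs
      text: Emergency drugs drawn up and labelled
      options: null
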