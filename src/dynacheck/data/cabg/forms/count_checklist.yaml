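form:
  id: count_checklist
  meta:
    title: Closing count
    author: dynacheck
    version: '1.0'
    created: '2024-01-15'
  problems:
  - id: count
    description: Closing count
    items:
    - id: sponge_count
      text: Sponge and instrument counts correct
      priority: high
    - id: specimen_labelled
      text: Specimens labelled and signed off
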