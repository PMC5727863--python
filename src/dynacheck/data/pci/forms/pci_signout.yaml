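form:
  id: pci_signout
  meta:
    title: Cath-lab sign-out
    author: dynacheck
    version: '1.0'
    created: '2024-01-15'
  problems:
  - id: signout
    description: Cath-lab sign-out
    items:
    - id: contrast_dose_noted
      text: Total contrast dose documented
    - id: complications_noted
      text: Complications (if any) documented
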