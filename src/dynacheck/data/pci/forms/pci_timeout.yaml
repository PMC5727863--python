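form:
  id: pci_timeout
  meta:
    title: Cath-lab time-out
    author: dynacheck
    version: '1.0'
    created: '2024-01-15'
  problems:
  - id: timeout
    description: Cath-lab time-out
    items:
    - id: correct_patient
      text: Correct patient and planned lesion confirmed
      priority: high
    - id: access_site_marked
      text: Access site marked
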