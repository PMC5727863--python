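form:
  id: pci_preop
  meta:
    title: PCI pre-operative checklist
    author: dynacheck
    version: '1.0'
    created: '2024-03-01'
  problems:
  - id: cardiac_function
    description: Cardiac function
    algorithms:
    - lvef_alert
    items:
    - id: lvef_documented
      text: 'LVEF documented: {lvef}%'
      supplementary:
      - kind: patient_data
        payload: lvef
  - id: renal_risk
    description: Renal risk
    algorithms:
    - renal_alert
    items:
    - id: hydration_plan
      text: Peri-procedural hydration plan in place
  - id: medication
    description: Medication
    algorithms:
    - antiplatelet_check
    items:
    - id: antiplatelet_item
      text: Dual antiplatelet therapy given
    - id: allergy_item
      text: Contrast allergy assessed
      priority: high
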