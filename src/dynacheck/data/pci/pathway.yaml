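pathway:
  id: pci_periop
  meta:
    title: PCI peri-operative pathway
    author: dynacheck
    version: '1.0'
    created: '2024-03-01'
  roles:
  - id: cardiologist
    name: Interventional cardiologist
  - id: cath_lab_nurse
    name: Cath-lab nurse
  - id: ward_nurse
    name: Ward nurse
  nodes:
  - id: start
    kind: start
  - id: end
    kind: end
  - id: admit_patient
    kind: task
    name: Admit patient
    roles:
    - ward_nurse
  - id: preop_checkup
    kind: task
    name: Pre-operative checkup
    roles:
    - cardiologist
    guards:
    - trigger: on_entry
      form: pci_preop
  - id: perform_pci
    kind: task
    name: Perform percutaneous coronary intervention
    roles:
    - cardiologist
    guards:
    - trigger: on_entry
      form: pci_timeout
      guards:
      - trigger: on_exit
        form: pci_signout
  - id: ecg_monitoring
    kind: task
    name: Continuous ECG monitoring
    roles:
    - cath_lab_nurse
  - id: puncture_site_check
    kind: task
    name: Check puncture site
    roles:
    - cath_lab_nurse
  - id: discharge
    kind: task
    name: Discharge with instructions
    roles:
    - ward_nurse
  - id: postop_observation
    kind: ad_hoc
    tasks:
    - ecg_monitoring
    - puncture_site_check
    name: Post-procedure observation
  edges:
  - id: e_start_admit_patient
    from: start
    to: admit_patient
  - id: e_admit_patient_preop_checkup
    from: admit_patient
    to: preop_checkup
  - id: e_preop_checkup_perform_pci
    from: preop_checkup
    to: perform_pci
  - id: e_perform_pci_postop_observation
    from: perform_pci
    to: postop_observation
  - id: e_postop_observation_discharge
    from: postop_observation
    to: discharge
  - id: e_discharge_end
    from: discharge
    to: end
  start: start
  end: end
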