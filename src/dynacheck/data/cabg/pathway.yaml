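pathway:
  id: cabg_periop
  meta:
    title: CABG peri-operative pathway
    author: dynacheck
    version: '1.0'
    created: '2024-01-15'
  roles:
  - id: ward_nurse
    name: Ward nurse
  - id: cardiologist
    name: Cardiologist
  - id: anesthesiologist
    name: Anesthesiologist
  - id: cardiac_surgeon
    name: Cardiac surgeon
  - id: or_nurse
    name: Operating-room nurse
  - id: perfusionist
    name: Perfusionist
  - id: icu_nurse
    name: ICU nurse
  - id: icu_physician
    name: ICU physician
  - id: physiotherapist
    name: Physiotherapist
  nodes:
  - id: start
    kind: start
  - id: end
    kind: end
  - id: admit_patient
    kind: task
    name: Admit patient to ward
    roles:
    - ward_nurse
    guards:
    - trigger: on_entry
      form: admission_checklist
  - id: preop_assessment
    kind: task
    name: Pre-operative cardiology assessment
    roles:
    - cardiologist
    guards:
    - trigger: on_entry
      form: preop_review_checklist
  - id: anesthesia_evaluation
    kind: task
    name: Anesthesia evaluation
    roles:
    - anesthesiologist
  - id: preop_briefing
    kind: task
    name: Surgical team briefing
    roles:
    - cardiac_surgeon
  - id: prepare_operating_room
    kind: task
    name: Prepare operating room
    roles:
    - or_nurse
  - id: prime_bypass_circuit
    kind: task
    name: Prime cardiopulmonary bypass circuit
    roles:
    - perfusionist
    guards:
    - trigger: on_entry
      form: bypass_checklist
  - id: prepare_patient
    kind: task
    name: Prepare patient for transfer to OR
    roles:
    - ward_nurse
  - id: time_out_verification
    kind: task
    name: Time-out verification
    roles:
    - cardiac_surgeon
    guards:
    - trigger: on_entry
      form: time_out_checklist
      blocking: true
  - id: induce_anesthesia
    kind: task
    name: Induce anesthesia
    roles:
    - anesthesiologist
    guards:
    - trigger: on_entry
      form: anesthesia_checklist
  - id: perform_grafting
    kind: task
    name: Perform coronary grafting
    roles:
    - cardiac_surgeon
  - id: wean_from_bypass
    kind: task
    name: Wean from cardiopulmonary bypass
    roles:
    - perfusionist
  - id: close_and_count
    kind: task
    name: Close wound and count instruments
    roles:
    - or_nurse
    guards:
    - trigger: on_exit
      form: count_checklist
  - id: transfer_to_icu
    kind: task
    name: Transfer patient to ICU
    roles:
    - anesthesiologist
  - id: icu_admission_check
    kind: task
    name: ICU admission check
    roles:
    - icu_nurse
    guards:
    - trigger: on_entry
      form: icu_admission_checklist
  - id: postop_monitoring
    kind: task
    name: Post-operative monitoring round
    roles:
    - icu_physician
    guards:
    - trigger: on_entry
      form: icu_round_checklist
  - id: manage_complication
    kind: task
    name: Manage post-operative complication
    roles:
    - icu_physician
  - id: start_physiotherapy
    kind: task
    name: Start mobilization program
    roles:
    - physiotherapist
    guards:
    - trigger: on_entry
      form: mobilization_checklist
  - id: ward_transfer
    kind: task
    name: Transfer back to ward
    roles:
    - ward_nurse
    guards:
    - trigger:
        kind: overdue
        after: 240
      form: admission_checklist
  - id: discharge_review
    kind: task
    name: Discharge review
    roles:
    - cardiologist
    guards:
    - trigger: on_entry
      form: discharge_checklist
  - id: prep_split
    kind: parallel_split
  - id: prep_join
    kind: parallel_join
  - id: complication_split
    kind: exclusive_split
    conditions:
    - edge: e_complication_split_manage_complication
      when: complication == true
    default_edge: e_complication_split_complication_merge
  - id: complication_merge
    kind: exclusive_merge
  edges:
  - id: e_start_admit_patient
    from: start
    to: admit_patient
  - id: e_admit_patient_preop_assessment
    from: admit_patient
    to: preop_assessment
  - id: e_preop_assessment_anesthesia_evaluation
    from: preop_assessment
    to: anesthesia_evaluation
  - id: e_anesthesia_evaluation_preop_briefing
    from: anesthesia_evaluation
    to: preop_briefing
  - id: e_preop_briefing_prep_split
    from: preop_briefing
    to: prep_split
  - id: e_prep_split_prepare_operating_room
    from: prep_split
    to: prepare_operating_room
  - id: e_prepare_operating_room_prep_join
    from: prepare_operating_room
    to: prep_join
  - id: e_prep_split_prime_bypass_circuit
    from: prep_split
    to: prime_bypass_circuit
  - id: e_prime_bypass_circuit_prep_join
    from: prime_bypass_circuit
    to: prep_join
  - id: e_prep_split_prepare_patient
    from: prep_split
    to: prepare_patient
  - id: e_prepare_patient_prep_join
    from: prepare_patient
    to: prep_join
  - id: e_prep_join_time_out_verification
    from: prep_join
    to: time_out_verification
  - id: e_time_out_verification_induce_anesthesia
    from: time_out_verification
    to: induce_anesthesia
  - id: e_induce_anesthesia_perform_grafting
    from: induce_anesthesia
    to: perform_grafting
  - id: e_perform_grafting_wean_from_bypass
    from: perform_grafting
    to: wean_from_bypass
  - id: e_wean_from_bypass_close_and_count
    from: wean_from_bypass
    to: close_and_count
  - id: e_close_and_count_transfer_to_icu
    from: close_and_count
    to: transfer_to_icu
  - id: e_transfer_to_icu_icu_admission_check
    from: transfer_to_icu
    to: icu_admission_check
  - id: e_icu_admission_check_postop_monitoring
    from: icu_admission_check
    to: postop_monitoring
  - id: e_postop_monitoring_complication_split
    from: postop_monitoring
    to: complication_split
  - id: e_complication_split_manage_complication
    from: complication_split
    to: manage_complication
  - id: e_complication_split_complication_merge
    from: complication_split
    to: complication_merge
  - id: e_manage_complication_complication_merge
    from: manage_complication
    to: complication_merge
  - id: e_complication_merge_start_physiotherapy
    from: complication_merge
    to: start_physiotherapy
  - id: e_start_physiotherapy_ward_transfer
    from: start_physiotherapy
    to: ward_transfer
  - id: e_ward_transfer_discharge_review
    from: ward_transfer
    to: discharge_review
  - id: e_discharge_review_end
    from: discharge_review
    to: end
  start: start
  end: end
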