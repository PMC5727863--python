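<?xml version='1.0' encoding='UTF-8'?>
<definitions xmlns="http://www.omg.org/spec/BPMN/20100524/MODEL" xmlns:dc="urn:dynacheck:bpmn-ext:1.0" targetNamespace="urn:dynacheck:bpmn-ext:1.0" id="defs_pci_periop">
  <process id="pci_periop" name="PCI peri-operative pathway">
    <extensionElements>
      <dc:meta title="PCI peri-operative pathway" author="dynacheck" version="1.0" created="2024-03-01"/>
    </extensionElements>
    <laneSet id="lanes_pci_periop">
      <lane id="lane_cardiologist" name="Interventional cardiologist">
        <flowNodeRef>perform_pci</flowNodeRef>
        <flowNodeRef>preop_checkup</flowNodeRef>
      </lane>
      <lane id="lane_cath_lab_nurse" name="Cath-lab nurse">
        <flowNodeRef>ecg_monitoring</flowNodeRef>
        <flowNodeRef>puncture_site_check</flowNodeRef>
      </lane>
      <lane id="lane_ward_nurse" name="Ward nurse">
        <flowNodeRef>admit_patient</flowNodeRef>
        <flowNodeRef>discharge</flowNodeRef>
      </lane>
    </laneSet>
    <startEvent id="start"/>
    <endEvent id="end"/>
    <userTask id="admit_patient" name="Admit patient">
      <potentialOwner>
        <resourceRef>ward_nurse</resourceRef>
      </potentialOwner>
    </userTask>
    <userTask id="preop_checkup" name="Pre-operative checkup">
      <extensionElements>
        <dc:guard trigger="on_entry" form="pci_preop"/>
      </extensionElements>
      <potentialOwner>
        <resourceRef>cardiologist</resourceRef>
      </potentialOwner>
    </userTask>
    <userTask id="perform_pci" name="Perform percutaneous coronary intervention">
      <extensionElements>
        <dc:guard trigger="on_entry" form="pci_timeout">
          <dc:guard trigger="on_exit" form="pci_signout"/>
        </dc:guard>
      </extensionElements>
      <potentialOwner>
        <resourceRef>cardiologist</resourceRef>
      </potentialOwner>
    </userTask>
    <userTask id="discharge" name="Discharge with instructions">
      <potentialOwner>
        <resourceRef>ward_nurse</resourceRef>
      </potentialOwner>
    </userTask>
    <adHocSubProcess id="postop_observation" name="Post-procedure observation">
      <extensionElements>
        <dc:mandatory>ecg_monitoring puncture_site_check</dc:mandatory>
      </extensionElements>
      <userTask id="ecg_monitoring" name="Continuous ECG monitoring">
        <potentialOwner>
          <resourceRef>cath_lab_nurse</resourceRef>
        </potentialOwner>
      </userTask>
      <userTask id="puncture_site_check" name="Check puncture site">
        <potentialOwner>
          <resourceRef>cath_lab_nurse</resourceRef>
        </potentialOwner>
      </userTask>
    </adHocSubProcess>
    <sequenceFlow id="e_start_admit_patient" sourceRef="start" targetRef="admit_patient"/>
    <sequenceFlow id="e_admit_patient_preop_checkup" sourceRef="admit_patient" targetRef="preop_checkup"/>
    <sequenceFlow id="e_preop_checkup_perform_pci" sourceRef="preop_checkup" targetRef="perform_pci"/>
    <sequenceFlow id="e_perform_pci_postop_observation" sourceRef="perform_pci" targetRef="postop_observation"/>
    <sequenceFlow id="e_postop_observation_discharge" sourceRef="postop_observation" targetRef="discharge"/>
    <sequenceFlow id="e_discharge_end" sourceRef="discharge" targetRef="end"/>
  </process>
</definitions>
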