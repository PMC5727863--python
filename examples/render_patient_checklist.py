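"""Instantiate the bundled PCI pre-operative checklist for one patient.

The patient's LVEF of 36% is below the 50% alert threshold, so the rule
engine adds a red-highlighted, high-priority alert item binding the actual
value; the documented antiplatelet therapy pre-checks its item (shown as
``[x]``, the system's own tick).
"""

from dynacheck import PatientContext, instantiate_checklist, pci_fixture, render_instance

model = pci_fixture()
patient = PatientContext(
    patient_id="pat_042",
    values={"lvef": 36, "antiplatelet_given": True, "renal_insufficiency": False},
)
instance = instantiate_checklist(model.form_map()["pci_preop"], patient, model)
print(render_instance(instance, "text"))
print(f"{len(instance.rule_added_items())} item(s) were added by clinical rules;")
print("lines starting with '!' flag abnormalities, a trailing 'M' marks high priority.")
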