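# dynacheck

Executable models of **dynamic clinical safety checklists** — checklists
that are *process-oriented* (delivered at the right workflow step to the
right clinical role) and *patient-context-aware* (items generated,
highlighted, or pre-checked by clinical rules evaluated against the
patient's record).

Paper surgical checklists demonstrably reduce avoidable errors, but static
forms impose workload and ignore the patient in front of the clinician.
`dynacheck` is for health-informatics engineers and researchers who want to
model such checklists *declaratively* — as data, reviewable by clinicians —
and execute them with a generic engine instead of hard-coding them into an
EMR. A model is three documents plus a field catalogue:

* a **clinical pathway**: a directed graph of clinical tasks assigned to
  roles, composed with the four care-flow patterns — sequential, parallel,
  conditional (exclusive/inclusive) and ad-hoc — with **safety guards**
  (checklist activities) bound to tasks and fired by triggers (task entry,
  task exit, overdue);
* **checklist forms**: containers of target clinical problems, each a list
  of checkable items with answer options, priority and supplementary
  material;
* **situation–action rules** in a `WHEN condition THEN action` DSL, with
  nesting (a rule may invoke another rule) and five effect kinds:
  `add_item`, `highlight … red`, `pre_check`, `set_priority`,
  `attach_material`.

Rule conditions are evaluated in **Kleene three-valued logic**: a
comparison touching a missing field is `unknown`, and `unknown` never fires
a rule — a safety checklist must not assert findings from absent data.
Pathways interchange as a **BPMN 2.0 subset** (userTask, sequenceFlow,
parallel/exclusive/inclusive gateways, ad-hoc subprocess, lanes); concepts
BPMN lacks (triggers, guard bindings) travel in `extensionElements` under
the package's own namespace.

## Worked example

Two complete models ship with the package: a CABG peri-operative pathway
(19 clinical tasks, 9 roles) and a PCI pathway with a pre-operative
checklist. For a patient whose left-ventricular ejection fraction is 36%
— below the 50% alert threshold — the rule engine adds a red-flagged,
high-priority alert binding the actual value:

```python
from dynacheck import (PatientContext, instantiate_checklist,
                       pci_fixture, render_instance)

model = pci_fixture()
patient = PatientContext("pat_042", {"lvef": 36, "antiplatelet_given": True,
                                     "renal_insufficiency": False})
instance = instantiate_checklist(model.form_map()["pci_preop"], patient, model)
print(render_instance(instance, "text"))
```

prints

```
Checklist pci_preop for patient pat_042
instance pci_preop.pat_042 at t=0min
========================================
-- Cardiac function
 [ ] LVEF documented: 36%
      (patient_data: lvef)
![ ] LVEF 36: evaluate cardiac function before intervention M
-- Renal risk
 [ ] Peri-procedural hydration plan in place
-- Medication
 [x] Dual antiplatelet therapy given
 [ ] Contrast allergy assessed M
```

A leading `!` marks a red-highlighted abnormality, a trailing `M` marks
high priority, and `[x]` is a system pre-check (the documented antiplatelet
therapy), which a human may override with a logged answer. The same
instance renders as self-contained HTML or as schema-conformant XML that
round-trips byte-identically.

The `examples/` directory has one short script per capability: rendering a
patient checklist, stepping a case through the workflow engine, authoring
rules in the DSL, BPMN round-tripping, and running a synthetic cohort.

A thin CLI wraps the same library:

```bash
dynacheck run --model pci --patient '{"lvef":36}' --format text
dynacheck validate path/to/bundle
dynacheck import-bpmn model.bpmn --strict --out pathway.yaml
dynacheck simulate --model cabg --n 50 --seed 7
```

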