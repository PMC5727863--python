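"""Step a CABG case through the workflow engine by hand.

Entering a guarded task activates its safety checklist (addressed to the
guard's roles); completing tasks routes tokens through the parallel
preparation block, so all three preparation tasks become workable at once.
"""

from dynacheck import (
    PatientContext,
    cabg_fixture,
    complete_task,
    enabled_tasks,
    enter_task,
    start_case,
)

model = cabg_fixture()
state = start_case(model, patient_id="pat_7", case_id="demo",
                   ctx=PatientContext("pat_7", {"complication": False}))

state, guards = enter_task(state, "admit_patient")
print(f"entering 'admit_patient' activated {len(guards)} checklist guard(s): "
      f"{[g.guard.form_id for g in guards]}")

for task_id in ("admit_patient", "preop_assessment", "anesthesia_evaluation",
                "preop_briefing"):
    state, _ = complete_task(state, task_id)

now_enabled = sorted(t for t, _ in enabled_tasks(state))
print(f"after the briefing, the parallel preparation block enables: {now_enabled}")
print("each can be completed in any interleaving; the join waits for all three.")
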