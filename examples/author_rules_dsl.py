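"""Author situation–action rules in the WHEN/THEN DSL and fire them.

The second rule is *nested*: its action invokes the first, so the emitted
effect carries the full invocation chain as provenance. A missing field
evaluates to `unknown`, which never fires a rule — the trace shows the
difference between `false` and `unknown`.
"""

from dynacheck import PatientContext, fire_rules, parse_rule_dsl
from dynacheck.rules import EvaluationTrace

rules = parse_rule_dsl("""\
RULE renal_alert
WHEN renal_insufficiency == true
THEN add_item "Renal insufficiency noticed" AND highlight renal_alert_item red

RULE elderly_renal_screen
WHEN age >= 75
THEN invoke_rule renal_alert
""")

ctx = PatientContext("pat_3", {"age": 81, "renal_insufficiency": True})
trace = EvaluationTrace()
effects = fire_rules(rules, ctx, trace=trace)
for eff in effects:
    print(f"{eff.action.kind:<10} via {' -> '.join(eff.provenance)}")
print("\nevaluation trace (rule, outcome, effects emitted):")
print(trace.as_text())

sparse = PatientContext("pat_4", {"age": 81})  # renal status unknown
print("\nwith renal status missing, effects:",
      len(fire_rules(rules, sparse)), "(unknown suppresses firing)")
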