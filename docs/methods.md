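# Methods

This note documents the semantics `dynacheck` implements, the choices made
where the design was genuinely open, and what the bundled models and
synthetic cohorts do and do not show about real hospital data.

## The meta-model

A model is a cross-linked quadruple: a **pathway** (the process layer), a
set of **checklist forms** (the content layer), a set of **situation–action
rules** (the decision layer), and a **field catalogue** declaring every
patient-context field with its type (`number`, `boolean`, `text`, `date`).

Identifiers are case-sensitive strings matching `[A-Za-z0-9_.-]+` — safe as
XML ids and file names. Validation is a pure function returning a report of
`(code, subject, message)` entries; a model executes only with an empty
error list, and a model that validates never raises reference errors at run
time (resolution is atomic over all cross-references, including nested
guard bindings).

A **safety guard** is modelled as a binding on its host task — trigger +
form + guard roles — rather than as a free graph node. When its trigger
fires, the binding becomes a runtime activity in its own right; because a
binding can carry sub-bindings, protection nests (a checklist activity can
itself be guarded). Triggers are task entry, task exit, and overdue; the
overdue horizon is in minutes of logical case time and must be positive.

## Expressions and rules

Conditions are threshold and boolean tests only: field references, typed
literals, the six comparisons, `AND`/`OR`/`NOT`, and `EXISTS field`. There
is deliberately no arithmetic — every condition the engine targets is a
threshold or boolean test; arithmetic is a documented extension point, not
a missing feature. One grammar serves the rule DSL, the native bundle
format and BPMN `conditionExpression` bodies (read as this dialect, not as
XPath/FEEL), so branch and rule semantics are identical everywhere.

Evaluation is Kleene's strong three-valued logic. A comparison (or bare
boolean field) touching a missing field yields `unknown`; `EXISTS` alone is
always two-valued. Both `false` and `unknown` suppress rule firing — the
engine never asserts a patient-specific finding from absent data — but the
two outcomes are distinguished in the evaluation trace so clinical logic
remains auditable.

Nested rules evaluate eagerly, depth-first, in the caller's context; there
is no fact chaining between rules (the nesting requirement is about
decomposition, not forward inference, and this is the simplest sound
semantics). Effect order is rule declaration order, then action order,
depth-first through invocations; provenance records the invocation chain
outermost-first. Invocation cycles are a hard error at evaluation time and
a static lint at validation time — guideline decomposition is hierarchical,
hence acyclic. When two rules touch the same item (e.g. conflicting
priorities), effects apply last-writer-wins in effect order; provenance
keeps both.

Only the clinical-rule realization of the abstract "clinical algorithm"
concept is implemented; heuristic and Bayesian-network algorithms are
documented extension points, not code.

## The token game

Execution is a token game on the pathway graph: tokens live on edges, and a
task is enabled when a token sits on an incoming edge. Gateways fire
eagerly and invisibly between user actions:

* **parallel** — split copies its token to every outgoing edge; join waits
  for one token per incoming edge, so the marking at a join never exceeds
  its fan-in (validation requires split fan-out = join fan-in).
* **exclusive** — conditions are evaluated in declared order against the
  case's patient context; the first `TRUE` branch wins; a default edge is
  mandatory and `unknown` falls through toward it (consistent with the rule
  engine's missing-data stance). Exactly one outgoing edge activates.
* **inclusive** — every `TRUE` branch activates, else the default; the
  split records, per firing, how many branches its matching join must wait
  for. The join is located structurally (the split's nearest gateway
  post-dominator), which is also what validation enforces: split/join pairs
  must nest properly, making join semantics decidable locally.
* **ad-hoc** — entering the block enables all member tasks at once; the
  block completes when every *mandatory* member has completed, at which
  point unfinished optional members are skipped.

Operations are pure: each returns a fresh state sharing the immutable
model. Time is logical — an injected minute clock, never wall-clock — so
overdue triggers are exactly testable; they fire exactly once per task
enablement. Guard activations are addressed to roles; any owner holding the
role may claim one, and tasks are never duplicated per owner. Whether an
open guard blocks its host task's completion is configurable per binding
(`blocking`), defaulting to non-blocking, since the trigger contract alone
does not decide it. The event log is append-only and replayable: re-applying
the command events (case start, task entry/completion, clock advances,
guard entry/completion) reproduces the final state exactly, with derived
events (guard activations, skips, case completion) re-derived rather than
replayed.

`legal_completion_orders` explores the full reachable state space by
completing any enabled task at each step; it is capped at 7 tasks (the
enumeration is factorial) and exists chiefly as an oracle surface: for
structured pathways its output equals the set of linear extensions of the
task precedence order, which the test suite recomputes independently by
permutation filtering.

## Checklist instantiation and rendering

Instantiation merges a form's static items with rule effects in firing
order. Rule-added items append at the end of their target problem's block,
preserving form order otherwise (alerts appear within their section; no
stronger ordering is defined). Highlighting is an explicit rule action, not
automatic range checking — red marks are driven by authored clinical rules,
never by a built-in reference-range table. `{field}` slots bind context
values; a missing field renders as an em dash and suppresses any pre-check
of that item (the system cannot vouch for a claim it could not read).
Items without options are guidance-only (per item, for emergency-style
use): they take no answer and can never be pre-checked — statically
validated and enforced at run time. A human may override an auto-checked
item only by answering it, and the override is logged; silent un-checking
is not provided.

Renderers share one semantic model. Text is 80-column plain (`!` prefix =
red highlight, `[x]` = auto-checked, trailing `M` = high priority). HTML is
self-contained with semantic classes (`item--auto`, `item--red`,
`item--priority`) and a minimal inline stylesheet — content and
presentation stay separable. XML conforms to the shipped
`schemas/checklist-instance.xsd` and round-trips byte-identically. Visual
layout beyond these two semantic flags (red highlight, priority mark) is
out of scope, as is reordering items by priority: items are flagged, never
reordered.

## Interchange formats

The native bundle is a directory of YAML documents plus `.rules` files; the
normative key lists live in the shipped `schemas/bundle-v1.yaml`, and the
loader rejects unknown keys with a pointer path. Saving and reloading a
model is a semantic identity (property-tested on the fixtures and on
randomly generated structured pathways).

The BPMN mapping covers: process ↔ pathway, userTask ↔ clinical task,
sequenceFlow ↔ edge (with `conditionExpression` for conditional branches),
parallel/exclusive/inclusive gateways by kind and degree, adHocSubProcess ↔
ad-hoc block, lanes/potentialOwner ↔ roles. `startEvent`/`endEvent` are
admitted as the process anchors. Strict import rejects anything else with
`UNSUPPORTED_ELEMENT`; lenient import skips with a warning. Guard bindings
and ad-hoc mandatory sets have no BPMN counterpart and travel in
`extensionElements` under `urn:dynacheck:bpmn-ext:1.0`; this encoding is an
original design and is **not** interoperable with vendor on-entry/on-exit
extensions (BizAgi, jBPM). Export∘import is graph-isomorphic on the mapped subset. Not
covered: BPMN events beyond start/end, message flows, other subprocess
types, CMMN.

## Bundled models and synthetic cohorts

The CABG model has 19 clinical tasks and 9 roles (the modelled care
process's counts); its task and role wording, lane layout, the three-way
parallel preparation block, the exclusive complication branch and the
one-form-per-lane checklist set are this package's own authorship. The PCI
model carries the pre-operative checklist whose alert rule fires iff
`lvef < 50` (adding a red, high-priority item binding the value), a renal
rule adding the item "Renal insufficiency noticed", and a medication
pre-check rule; the worked-example patient has LVEF 36. The number of forms
per model is a package choice, not a claim about any hospital's checklist
set.

`generate_patients` draws seeded records per a `CohortProfile`: numeric
fields uniform or (clipped) normal, booleans Bernoulli, with per-field
missingness. The bundled PCI profile uses LVEF ~ N(55, 12) clipped to
[10, 80] with 5% missing, 15% renal insufficiency, 90% documented
antiplatelet therapy — plausible for an elective PCI population. Cohorts
emulate marginal prevalences and missingness only: fields are independent,
there is no measurement error, no temporal structure, and no informative
missingness. Passing tests therefore demonstrate engine correctness under
realistic marginals, not clinical validity of content or robustness to
correlated real-world records. Clinical completeness of the CABG/PCI
content, EMR connectivity and multi-user operation are non-goals.

## Numerical and procedural choices

* Determinism: every stochastic component (cohort draws, the simulation's
  actor-choice policy) consumes a single integer seed through one
  `numpy.random.Generator` stream per concern; identical invocations are
  byte-identical.
* The LVEF threshold check in `scripts/acceptance.py` sweeps all integers
  1..100 (exhaustive, so no tolerance applies); the sweep order is shuffled
  under the seed to demonstrate order-independence.
* Property-test sizes: order-oracle comparison covers every deduplicated
  single-entry/single-exit fragment of both fixtures with ≤ 7 tasks;
  round-trip fuzzing uses 200 random structured pathways; robustness uses
  1000 seeded runs per fixture. These sizes give exhaustive coverage of the
  fixtures' structure and stable statistics while keeping the default suite
  in seconds.
* Degenerate inputs: an empty rule file is a parse error (a rule file must
  contain rules); an empty cohort (`n=0`) is valid; a checklist instance
  must contain at least one item.
* Potential-owner lists are runtime configuration, not part of the
  persisted model; the simulator synthesizes one owner per role when none
  are supplied.

## Known limitations

Composed/group roles jointly executing one task are not supported (each
activation is claimed by one owner). There is no persistence/resume across
processes, no UI beyond the three renderers, no versioned model migration,
and no multi-pathway orchestration. The inclusive-join synchronization is
count-based per split firing, which is exact for properly nested pathways
(the only kind validation admits) but would under-specify arbitrary
unstructured graphs.
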