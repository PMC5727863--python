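"""Domain types for dynamic clinical safety checklists, plus model validation.

The type system covers three concept groups:

* **process** — roles, clinical tasks, gateways, ad-hoc blocks, triggers and
  safety-guard bindings, organised into a :class:`Pathway` graph;
* **context / rules** — the patient-data catalogue and situation–action rules
  (see :mod:`dynacheck.context` and :mod:`dynacheck.rules`);
* **checklist content** — :class:`ChecklistForm` containers of target clinical
  problems and checkable items.

A safety guard is modelled as a *binding* on its host task (trigger + form +
roles) rather than a free node; when activated it becomes a runtime task in
its own right and may itself carry guards, so protection nests.

Validation never raises for content problems: :func:`validate_pathway` and
:func:`validate_form` return a :class:`ValidationReport` listing every
violated invariant, and a model is executable iff the report has no errors.
"""

from __future__ import annotations

import datetime as _dt
import re
from dataclasses import dataclass, field
from typing import Iterable, Union

import networkx as nx

from .context import ContextSchema
from .errors import DanglingRefError
from .expressions import Expression, type_errors

ID_RE = re.compile(r"^[A-Za-z0-9_.-]+$")
SLOT_RE = re.compile(r"\{([A-Za-z_][A-Za-z0-9_.]*)\}")

TRIGGER_KINDS = ("on_entry", "on_exit", "overdue")
GATEWAY_KINDS = (
    "parallel_split",
    "parallel_join",
    "exclusive_split",
    "exclusive_merge",
    "inclusive_split",
    "inclusive_join",
)
_SPLIT_OF = {
    "parallel_join": "parallel_split",
    "exclusive_merge": "exclusive_split",
    "inclusive_join": "inclusive_split",
}
DEFAULT_OPTIONS = ("yes", "no", "not_applicable")


def valid_id(s: object) -> bool:
    return isinstance(s, str) and bool(ID_RE.match(s))


@dataclass(frozen=True)
class MetaInfo:
    """Maintenance metadata of a pathway or checklist form."""

    title: str = ""
    author: str = ""
    version: str = "1"
    created: _dt.date | None = None


@dataclass(frozen=True)
class Role:
    id: str
    name: str


@dataclass(frozen=True)
class PotentialOwner:
    """A person eligible to perform tasks, via one or more roles.

    Owner lists are runtime configuration, not part of the persisted model.
    """

    id: str
    name: str
    role_ids: frozenset[str]
    contact: str = ""


@dataclass(frozen=True)
class Trigger:
    """When a safety guard activates: task entry, task exit, or overdue.

    ``overdue_after`` is in minutes of logical case time and is required
    (and must be positive) exactly when ``kind == "overdue"``.
    """

    kind: str
    overdue_after: int | None = None

    def __post_init__(self):
        if self.kind not in TRIGGER_KINDS:
            raise ValueError(f"unknown trigger kind {self.kind!r}")
        if self.kind == "overdue":
            if self.overdue_after is None or self.overdue_after <= 0:
                raise ValueError("overdue trigger requires overdue_after > 0 minutes")
        elif self.overdue_after is not None:
            raise ValueError("overdue_after only applies to overdue triggers")


@dataclass(frozen=True)
class SafetyGuardBinding:
    """Attach a checklist (form) to a host task, activated by a trigger.

    ``guard_role_ids`` defaults to the host task's roles when empty.
    ``blocking`` marks guards whose completion gates the host task's
    completion (off by default). A guard activation is itself a clinical
    task instance, so ``guards`` lets protection nest: sub-guards fire on
    entry/exit of the guard activity itself.
    """

    trigger: Trigger
    form_id: str
    guard_role_ids: frozenset[str] = frozenset()
    blocking: bool = False
    guards: tuple["SafetyGuardBinding", ...] = ()


@dataclass(frozen=True)
class ClinicalTask:
    """An atomic clinical activity assigned to one or more roles."""

    id: str
    name: str
    role_ids: frozenset[str]
    guards: tuple[SafetyGuardBinding, ...] = ()


@dataclass(frozen=True)
class GatewayNode:
    """Routing node realizing parallel / exclusive / inclusive care flow.

    For exclusive and inclusive splits, ``branch_conditions`` is an ordered
    list of ``(edge_id, Expression)``; conditions are evaluated against the
    case's patient context at the moment the split fires. A ``default_edge_id``
    is mandatory for those splits; an ``unknown`` condition never selects a
    branch (it falls through toward the default).
    """

    id: str
    kind: str
    branch_conditions: tuple[tuple[str, Expression], ...] = ()
    default_edge_id: str | None = None

    def __post_init__(self):
        if self.kind not in GATEWAY_KINDS:
            raise ValueError(f"unknown gateway kind {self.kind!r}")


@dataclass(frozen=True)
class AdHocBlock:
    """A batch of member tasks executed in no predefined order.

    The block completes once every task in ``mandatory_task_ids`` has
    completed; remaining members are then skipped. Member tasks live in the
    pathway's node collection but are connected through the block, not by
    ordinary edges.
    """

    id: str
    task_ids: frozenset[str]
    mandatory_task_ids: frozenset[str]
    name: str = ""


@dataclass(frozen=True)
class EventNode:
    """Start or end anchor of a pathway."""

    id: str
    kind: str  # "start" | "end"


PathwayNode = Union[ClinicalTask, GatewayNode, AdHocBlock, EventNode]


@dataclass(frozen=True)
class Edge:
    id: str
    source_id: str
    target_id: str


@dataclass(frozen=True)
class Pathway:
    """Directed graph of clinical tasks, gateways and ad-hoc blocks."""

    id: str
    nodes: tuple[PathwayNode, ...]
    edges: tuple[Edge, ...]
    start_node_id: str
    end_node_id: str
    roles: tuple[Role, ...] = ()
    meta: MetaInfo = MetaInfo()

    def node_map(self) -> dict[str, PathwayNode]:
        return {n.id: n for n in self.nodes}

    def edge_map(self) -> dict[str, Edge]:
        return {e.id: e for e in self.edges}

    def role_map(self) -> dict[str, Role]:
        return {r.id: r for r in self.roles}

    def tasks(self) -> list[ClinicalTask]:
        return [n for n in self.nodes if isinstance(n, ClinicalTask)]

    def adhoc_member_ids(self) -> set[str]:
        out: set[str] = set()
        for n in self.nodes:
            if isinstance(n, AdHocBlock):
                out |= n.task_ids
        return out

    def out_edges(self, node_id: str) -> list[Edge]:
        return [e for e in self.edges if e.source_id == node_id]

    def in_edges(self, node_id: str) -> list[Edge]:
        return [e for e in self.edges if e.target_id == node_id]

    def flow_graph(self) -> nx.DiGraph:
        """Control-flow digraph; ad-hoc membership shown as block<->member arcs."""
        g = nx.DiGraph()
        for n in self.nodes:
            g.add_node(n.id)
        for e in self.edges:
            g.add_edge(e.source_id, e.target_id, edge_id=e.id)
        for n in self.nodes:
            if isinstance(n, AdHocBlock):
                for t in n.task_ids:
                    g.add_edge(n.id, t, membership=True)
                    g.add_edge(t, n.id, membership=True)
        return g


# ---------------------------------------------------------------------------
# Checklist content


@dataclass(frozen=True)
class SupplementaryMaterial:
    """Auxiliary info attached to an item: a patient-data field or literature."""

    kind: str  # "patient_data" | "literature"
    payload: str

    def __post_init__(self):
        if self.kind not in ("patient_data", "literature"):
            raise ValueError(f"unknown supplementary kind {self.kind!r}")


@dataclass(frozen=True)
class CheckableItem:
    """One entry of a checklist form.

    ``description`` is a template whose ``{field}`` slots bind patient-context
    values at instantiation. Items without ``options`` are guidance-only:
    they are read, never ticked, and can never be pre-checked. ``source`` is
    ``"static"`` for form-authored items or ``"rule:<id>"`` for rule-added
    ones.
    """

    id: str
    description: str
    options: tuple[str, ...] | None = DEFAULT_OPTIONS
    priority: str = "normal"  # "normal" | "high"
    supplementary: tuple[SupplementaryMaterial, ...] = ()
    source: str = "static"
    pre_checked: bool = False

    def __post_init__(self):
        if self.priority not in ("normal", "high"):
            raise ValueError(f"bad priority {self.priority!r}")

    @property
    def guidance_only(self) -> bool:
        return self.options is None

    def binding_slots(self) -> list[str]:
        return SLOT_RE.findall(self.description)


@dataclass(frozen=True)
class TargetClinicalProblem:
    """The clinical concern a group of checkable items addresses."""

    id: str
    description: str
    static_items: tuple[CheckableItem, ...] = ()
    algorithm_ids: tuple[str, ...] = ()


@dataclass(frozen=True)
class ChecklistForm:
    """Static container of target problems and their checkable items."""

    id: str
    problems: tuple[TargetClinicalProblem, ...]
    meta: MetaInfo = MetaInfo()

    def items(self) -> list[CheckableItem]:
        return [i for p in self.problems for i in p.static_items]


# ---------------------------------------------------------------------------
# Validation


@dataclass
class ValidationReport:
    """Errors and warnings from model validation.

    Each entry is ``(code, subject_id, message)``. A model is loadable for
    execution iff ``errors`` is empty.
    """

    errors: list[tuple[str, str, str]] = field(default_factory=list)
    warnings: list[tuple[str, str, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def error(self, code: str, subject: str, message: str) -> None:
        self.errors.append((code, subject, message))

    def warn(self, code: str, subject: str, message: str) -> None:
        self.warnings.append((code, subject, message))

    def codes(self) -> list[str]:
        return [c for c, _, _ in self.errors]

    def extend(self, other: "ValidationReport") -> None:
        self.errors.extend(other.errors)
        self.warnings.extend(other.warnings)

    def __str__(self) -> str:
        lines = [f"ERROR {c} [{s}] {m}" for c, s, m in self.errors]
        lines += [f"WARN  {c} [{s}] {m}" for c, s, m in self.warnings]
        return "\n".join(lines) or "OK"


def validate_pathway(pathway: Pathway) -> ValidationReport:
    """Check every structural invariant of a pathway graph.

    Violations are report entries, never exceptions. Validation is pure and
    idempotent. Checks: id syntax and uniqueness, a single start/end pair,
    edge endpoint resolution, reachability (start reaches everything,
    everything reaches end — ad-hoc members count as reached through their
    block), role resolution, gateway condition wiring and structured
    split/join nesting, trigger sanity, ad-hoc membership.
    """
    rep = ValidationReport()
    nodes = list(pathway.nodes)
    ids_seen: set[str] = set()
    for n in nodes:
        if not valid_id(n.id):
            rep.error("BAD_ID", str(n.id), "node id must match [A-Za-z0-9_.-]+")
        if n.id in ids_seen:
            rep.error("DUPLICATE_ID", n.id, "node id not unique")
        ids_seen.add(n.id)

    if not pathway.meta.version:
        rep.error("EMPTY_VERSION", pathway.id, "meta.version must be non-empty")

    role_ids = set()
    for r in pathway.roles:
        if r.id in role_ids:
            rep.error("DUPLICATE_ID", r.id, "role id not unique")
        role_ids.add(r.id)
        if not r.name:
            rep.error("EMPTY_NAME", r.id, "role name must be non-empty")

    node_map = {n.id: n for n in nodes}
    starts = [n for n in nodes if isinstance(n, EventNode) and n.kind == "start"]
    ends = [n for n in nodes if isinstance(n, EventNode) and n.kind == "end"]
    if len(starts) != 1 or pathway.start_node_id not in {s.id for s in starts}:
        rep.error("BAD_START", pathway.id, "pathway must have exactly one start node")
    if len(ends) != 1 or pathway.end_node_id not in {e.id for e in ends}:
        rep.error("BAD_END", pathway.id, "pathway must have exactly one end node")

    edge_ids: set[str] = set()
    for e in pathway.edges:
        if e.id in edge_ids:
            rep.error("DUPLICATE_ID", e.id, "edge id not unique")
        edge_ids.add(e.id)
        for endpoint in (e.source_id, e.target_id):
            if endpoint not in node_map:
                rep.error("MISSING_NODE", e.id, f"edge references missing node {endpoint!r}")

    def _check_task(task: ClinicalTask) -> None:
        if not task.role_ids:
            rep.error("NO_ROLE", task.id, "clinical task needs at least one role")
        for rid in sorted(task.role_ids):
            if rid not in role_ids:
                rep.error("UNRESOLVED_ROLE", task.id, f"role {rid!r} not declared")
        for g in task.guards:
            for rid in sorted(g.guard_role_ids):
                if rid not in role_ids:
                    rep.error("UNRESOLVED_ROLE", task.id, f"guard role {rid!r} not declared")

    for n in nodes:
        if isinstance(n, ClinicalTask):
            _check_task(n)
        elif isinstance(n, AdHocBlock):
            if not n.task_ids:
                rep.error("EMPTY_ADHOC", n.id, "ad-hoc block has no member tasks")
            if not n.mandatory_task_ids <= n.task_ids:
                rep.error("BAD_ADHOC_MANDATORY", n.id, "mandatory tasks must be members")
            for t in sorted(n.task_ids):
                member = node_map.get(t)
                if not isinstance(member, ClinicalTask):
                    rep.error("MISSING_NODE", n.id, f"ad-hoc member {t!r} is not a clinical task")
        elif isinstance(n, GatewayNode):
            if n.kind in ("exclusive_split", "inclusive_split"):
                if n.default_edge_id is None:
                    rep.error("NO_DEFAULT_EDGE", n.id, f"{n.kind} requires a default edge")
                elif n.default_edge_id not in edge_ids:
                    rep.error("MISSING_EDGE", n.id, f"default edge {n.default_edge_id!r} missing")
                for eid, _expr in n.branch_conditions:
                    if eid not in edge_ids:
                        rep.error("MISSING_EDGE", n.id, f"condition edge {eid!r} missing")
                    else:
                        edge = pathway.edge_map()[eid]
                        if edge.source_id != n.id:
                            rep.error("MISSING_EDGE", n.id, f"condition edge {eid!r} is not outgoing")
            elif n.branch_conditions:
                rep.error("BAD_GATEWAY", n.id, f"{n.kind} carries branch conditions")

    # Reachability over the flow graph (ad-hoc membership arcs included).
    if rep.ok:
        g = pathway.flow_graph()
        reachable = nx.descendants(g, pathway.start_node_id) | {pathway.start_node_id}
        for n in nodes:
            if n.id not in reachable:
                rep.error("UNREACHABLE_NODE", n.id, "not reachable from start")
        rg = g.reverse()
        co_reachable = nx.descendants(rg, pathway.end_node_id) | {pathway.end_node_id}
        for n in nodes:
            if n.id not in co_reachable:
                rep.error("NO_PATH_TO_END", n.id, "end not reachable from node")

    if rep.ok:
        _check_structured_gateways(pathway, rep)
    return rep


def _check_structured_gateways(pathway: Pathway, rep: ValidationReport) -> None:
    """Require split/join pairs to nest properly.

    Each split's immediate post-dominator must be a join of the matching
    kind, and for parallel pairs the join's in-degree must equal the split's
    out-degree — this makes join token semantics decidable locally.
    """
    g = pathway.flow_graph()
    # membership arcs create trivial cycles; drop them for dominance analysis
    h = nx.DiGraph()
    h.add_nodes_from(g.nodes)
    h.add_edges_from(
        (u, v) for u, v, d in g.edges(data=True) if not d.get("membership")
    )
    try:
        ipostdom = nx.immediate_dominators(h.reverse(copy=False), pathway.end_node_id)
    except nx.NetworkXError:  # pragma: no cover - end unreachable caught earlier
        return
    node_map = pathway.node_map()
    member_ids = pathway.adhoc_member_ids()
    splits = [
        n for n in pathway.nodes
        if isinstance(n, GatewayNode) and n.kind.endswith("_split")
    ]
    for s in splits:
        join_kind = {v: k for k, v in _SPLIT_OF.items()}[s.kind]
        # walk the post-dominator chain to the first gateway node
        cur = ipostdom.get(s.id)
        while cur is not None and not isinstance(node_map.get(cur), GatewayNode):
            nxt = ipostdom.get(cur)
            cur = None if nxt == cur else nxt
        join = node_map.get(cur) if cur else None
        if not (isinstance(join, GatewayNode) and join.kind == join_kind):
            rep.error(
                "UNSTRUCTURED_GATEWAYS", s.id,
                f"{s.kind} has no matching {join_kind} post-dominating it",
            )
            continue
        if s.kind == "parallel_split":
            out_deg = len(pathway.out_edges(s.id))
            in_deg = len([e for e in pathway.in_edges(join.id) if e.source_id not in member_ids])
            if out_deg != in_deg:
                rep.error(
                    "UNSTRUCTURED_GATEWAYS", s.id,
                    f"parallel split fan-out {out_deg} != join fan-in {in_deg}",
                )


def validate_form(form: ChecklistForm, schema: ContextSchema) -> ValidationReport:
    """Check a checklist form against the patient-context field catalogue."""
    rep = ValidationReport()
    if not valid_id(form.id):
        rep.error("BAD_ID", str(form.id), "form id must match [A-Za-z0-9_.-]+")
    if not form.meta.version:
        rep.error("EMPTY_VERSION", form.id, "meta.version must be non-empty")
    if not form.problems:
        rep.error("EMPTY_FORM", form.id, "form needs at least one target problem")
    item_ids: set[str] = set()
    for p in form.problems:
        if not valid_id(p.id):
            rep.error("BAD_ID", str(p.id), "problem id must match [A-Za-z0-9_.-]+")
        for item in p.static_items:
            if item.id in item_ids:
                rep.error("DUPLICATE_ID", item.id, "item id not unique within form")
            item_ids.add(item.id)
            for slot in item.binding_slots():
                if slot not in schema:
                    rep.error("UNKNOWN_FIELD", item.id, f"binding slot {{{slot}}} not in catalogue")
            for mat in item.supplementary:
                if mat.kind == "patient_data" and mat.payload not in schema:
                    rep.error("UNKNOWN_FIELD", item.id, f"supplementary field {mat.payload!r} not in catalogue")
            if item.guidance_only and item.pre_checked:
                rep.error("GUIDANCE_PRECHECK", item.id, "guidance-only items cannot be pre-checked")
    return rep


# ---------------------------------------------------------------------------
# Whole-model resolution


@dataclass(frozen=True)
class Model:
    """A fully cross-linked bundle: pathway + forms + rules + field catalogue."""

    pathway: Pathway
    forms: tuple[ChecklistForm, ...]
    rules: tuple["Rule", ...]  # noqa: F821 - see dynacheck.rules
    schema: ContextSchema

    def form_map(self) -> dict[str, ChecklistForm]:
        return {f.id: f for f in self.forms}

    def rule_map(self) -> dict[str, "Rule"]:  # noqa: F821
        return {r.id: r for r in self.rules}


def resolve_model(
    pathway: Pathway | None,
    forms: Iterable[ChecklistForm] = (),
    rules: Iterable["Rule"] = (),  # noqa: F821
    schema: ContextSchema | None = None,
) -> Model:
    """Cross-link a parsed bundle into a :class:`Model`.

    Fails atomically with :class:`DanglingRefError` on the first set of
    dangling references; on success every id reference is guaranteed to
    resolve, so execution never sees a missing link.
    """
    dangling: list[str] = []
    if pathway is None:
        raise DanglingRefError("bundle has no pathway (start node unresolvable)", ref="start")
    forms = tuple(forms)
    rules = tuple(rules)
    schema = schema or ContextSchema()
    form_ids = {f.id for f in forms}
    rule_ids = {r.id for r in rules}

    def check_guard(g: SafetyGuardBinding, owner: str) -> None:
        if g.form_id not in form_ids:
            dangling.append(f"task {owner}: guard form {g.form_id!r}")
        for sub in g.guards:
            check_guard(sub, owner)

    for task in pathway.tasks():
        for g in task.guards:
            check_guard(g, task.id)
    problem_ids = {p.id for f in forms for p in f.problems}
    for f in forms:
        for p in f.problems:
            for aid in p.algorithm_ids:
                if aid not in rule_ids:
                    dangling.append(f"form {f.id}/{p.id}: algorithm {aid!r}")
    for r in rules:
        for action in r.actions:
            if action.kind == "invoke_rule" and action.rule_id not in rule_ids:
                dangling.append(f"rule {r.id}: invoked rule {action.rule_id!r}")
        if r.problem_id is not None and r.problem_id not in problem_ids:
            dangling.append(f"rule {r.id}: problem {r.problem_id!r}")

    if dangling:
        raise DanglingRefError(
            "dangling references: " + "; ".join(sorted(dangling)), refs=sorted(dangling)
        )
    return Model(pathway=pathway, forms=forms, rules=rules, schema=schema)


def validate_model(model: Model) -> ValidationReport:
    """Validate an already-resolved model end to end.

    Combines pathway and form validation with rule lints: expression typing
    against the field catalogue and static rule-invocation acyclicity.
    """
    from .rules import static_rule_cycle  # local import to avoid a cycle

    rep = validate_pathway(model.pathway)
    for f in model.forms:
        rep.extend(validate_form(f, model.schema))
    for r in model.rules:
        for problem in type_errors(r.condition, model.schema):
            rep.error("TYPE_ERROR", r.id, problem)
    cycle = static_rule_cycle(model.rules)
    if cycle:
        rep.error("RULE_CYCLE", cycle[0], "rule invocation cycle: " + " -> ".join(cycle))
    return rep
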