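"""Situation–action rules: WHEN condition THEN actions, possibly nested.

A rule's actions fire iff its condition evaluates to ``TRUE`` under the
patient context — ``FALSE`` and ``UNKNOWN`` both suppress firing, but are
distinguished in the evaluation trace so clinical logic stays auditable.

Nesting follows the guideline/sub-guideline idiom: an ``invoke_rule`` action
evaluates the target rule eagerly in the *caller's* context (no fact
chaining), depth-first, and the effect's provenance records the invocation
chain outermost-first. Invocation cycles are a hard error at evaluation time
and a static lint at validation time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .context import ContextSchema, PatientContext
from .errors import RuleCycleError
from .expressions import Expression, TruthValue, eval_expression
from .model import CheckableItem, SupplementaryMaterial

ACTION_KINDS = (
    "add_item",
    "highlight",
    "pre_check",
    "set_priority",
    "attach_material",
    "invoke_rule",
)


@dataclass(frozen=True)
class Action:
    """One action of a rule; the payload shape depends on ``kind``.

    add_item: ``item`` (a CheckableItem template).
    highlight: ``item_id`` + ``color`` (only "red" is defined).
    pre_check: ``item_id``.
    set_priority: ``item_id`` + ``level`` ("normal" | "high").
    attach_material: ``item_id`` + ``material``.
    invoke_rule: ``rule_id``.
    """

    kind: str
    item: CheckableItem | None = None
    item_id: str | None = None
    color: str | None = None
    level: str | None = None
    material: SupplementaryMaterial | None = None
    rule_id: str | None = None

    def __post_init__(self):
        if self.kind not in ACTION_KINDS:
            raise ValueError(f"unknown action kind {self.kind!r}")
        need = {
            "add_item": self.item is not None,
            "highlight": self.item_id is not None and self.color == "red",
            "pre_check": self.item_id is not None,
            "set_priority": self.item_id is not None and self.level in ("normal", "high"),
            "attach_material": self.item_id is not None and self.material is not None,
            "invoke_rule": self.rule_id is not None,
        }[self.kind]
        if not need:
            raise ValueError(f"payload shape does not match action kind {self.kind!r}")


@dataclass(frozen=True)
class Rule:
    """WHEN ``condition`` THEN ``actions`` for one optional target problem."""

    id: str
    condition: Expression
    actions: tuple[Action, ...]
    problem_id: str | None = None

    def __post_init__(self):
        if not self.actions:
            raise ValueError(f"rule {self.id!r} has no actions")


@dataclass(frozen=True)
class RuleEffect:
    """A fired action with its resolved payload and rule provenance.

    ``provenance`` lists rule ids outermost-first through nested
    invocations; it is non-empty and acyclic by construction.
    """

    action: Action
    provenance: tuple[str, ...]

    def to_dict(self) -> dict:
        a = self.action
        d: dict = {"kind": a.kind, "provenance": list(self.provenance)}
        if a.item is not None:
            d["item"] = {
                "id": a.item.id,
                "description": a.item.description,
                "options": list(a.item.options) if a.item.options else None,
                "priority": a.item.priority,
                "source": a.item.source,
            }
        for key in ("item_id", "color", "level", "rule_id"):
            v = getattr(a, key)
            if v is not None:
                d[key] = v
        if a.material is not None:
            d["material"] = {"kind": a.material.kind, "payload": a.material.payload}
        return d


@dataclass(frozen=True)
class TraceRecord:
    """One rule evaluation: outcome plus the number of effects it emitted."""

    rule_id: str
    truth: TruthValue
    effects_emitted: int
    depth: int

    def as_line(self) -> str:
        return f"{self.rule_id}\t{self.truth.value}\t{self.effects_emitted}\tdepth={self.depth}"


@dataclass
class EvaluationTrace:
    records: list[TraceRecord] = field(default_factory=list)

    def as_text(self) -> str:
        return "\n".join(r.as_line() for r in self.records)


def static_rule_cycle(rules: Sequence[Rule]) -> list[str] | None:
    """Return a rule-id cycle in the invocation graph, or None if acyclic."""
    graph = {
        r.id: [a.rule_id for a in r.actions if a.kind == "invoke_rule"]
        for r in rules
    }
    WHITE, GRAY, BLACK = 0, 1, 2
    color = {rid: WHITE for rid in graph}
    stack: list[str] = []

    def visit(rid: str) -> list[str] | None:
        color[rid] = GRAY
        stack.append(rid)
        for nxt in graph.get(rid, ()):
            if nxt not in graph:
                continue  # dangling target; resolve_model reports it
            if color[nxt] == GRAY:
                return stack[stack.index(nxt):] + [nxt]
            if color[nxt] == WHITE:
                found = visit(nxt)
                if found:
                    return found
        color[rid] = BLACK
        stack.pop()
        return None

    for rid in graph:
        if color[rid] == WHITE:
            found = visit(rid)
            if found:
                return found
    return None


def fire_rules(
    rules: Sequence[Rule],
    ctx: PatientContext,
    *,
    all_rules: Iterable[Rule] | None = None,
    schema: ContextSchema | None = None,
    trace: EvaluationTrace | None = None,
) -> list[RuleEffect]:
    """Evaluate ``rules`` in declaration order and collect fired effects.

    ``all_rules`` is the lookup universe for ``invoke_rule`` targets and
    defaults to ``rules`` itself. Effect order is rule declaration order,
    then action order, depth-first through invocations. Raises
    :class:`RuleCycleError` if an invocation chain revisits a rule id.
    """
    universe = {r.id: r for r in (all_rules if all_rules is not None else rules)}
    for r in rules:
        universe.setdefault(r.id, r)
    effects: list[RuleEffect] = []

    def evaluate(rule: Rule, chain: tuple[str, ...]) -> int:
        if rule.id in chain:
            raise RuleCycleError(
                "rule invocation cycle: " + " -> ".join(chain + (rule.id,)),
                chain=list(chain + (rule.id,)),
            )
        chain = chain + (rule.id,)
        truth = eval_expression(rule.condition, ctx, schema)
        emitted = 0
        if truth is TruthValue.TRUE:
            for action in rule.actions:
                if action.kind == "invoke_rule":
                    target = universe.get(action.rule_id)
                    if target is None:
                        raise RuleCycleError(  # pragma: no cover - resolve_model guards
                            f"invoked rule {action.rule_id!r} not found",
                        )
                    emitted += evaluate(target, chain)
                else:
                    resolved = action
                    if action.kind == "add_item" and not action.item.source.startswith("rule:"):
                        resolved = Action(
                            kind="add_item",
                            item=CheckableItem(
                                id=action.item.id,
                                description=action.item.description,
                                options=action.item.options,
                                priority=action.item.priority,
                                supplementary=action.item.supplementary,
                                source=f"rule:{rule.id}",
                                pre_checked=action.item.pre_checked,
                            ),
                        )
                    effects.append(RuleEffect(action=resolved, provenance=chain))
                    emitted += 1
        if trace is not None:
            trace.records.append(
                TraceRecord(rule.id, truth, emitted, depth=len(chain) - 1)
            )
        return emitted

    for rule in rules:
        evaluate(rule, ())
    return effects


def effects_as_json(effects: Sequence[RuleEffect]) -> str:
    """Canonical serialization of an effect list (determinism checks)."""
    return json.dumps([e.to_dict() for e in effects], sort_keys=True)
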