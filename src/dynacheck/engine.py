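"""Token-based execution of pathway cases.

The engine plays a token game over the pathway graph. Tokens live on edges;
a clinical task is *enabled* when a token sits on one of its incoming edges
(or its ad-hoc block is active), *active* once a user enters it, and
*completed* when finished — completion consumes the enabling token and
produces one on each outgoing edge. Gateways fire eagerly and silently:

* parallel split copies its token to every outgoing edge; its join waits for
  one token per incoming edge;
* exclusive split routes to the first branch whose condition is TRUE under
  the case's patient context (``unknown`` never selects; the mandatory
  default edge catches the rest); its merge passes tokens through;
* inclusive split activates every TRUE branch, else the default, and tells
  its matching join how many branches to wait for (recorded per firing);
* an ad-hoc block enables all member tasks at once and completes — skipping
  unfinished optional members — when every mandatory member has completed.

Time is logical: :func:`advance_clock` moves an injected minute counter and
fires overdue guards exactly once per enablement. All state transitions are
pure (each operation returns a fresh state) and append to an event log whose
replay reproduces the final state bit-for-bit.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .context import PatientContext
from .errors import (
    DynacheckError,
    InvalidModelError,
    NotEnabledError,
    RoleMismatchError,
    TooLargeError,
)
from .expressions import TruthValue, eval_expression
from .model import (
    AdHocBlock,
    ClinicalTask,
    GatewayNode,
    Model,
    Pathway,
    PotentialOwner,
    SafetyGuardBinding,
    validate_model,
)

TASK_STATES = ("dormant", "enabled", "active", "completed", "skipped")


class DeadlockError(DynacheckError):
    code = "DEADLOCK"


class GuardPendingError(DynacheckError):
    code = "GUARD_PENDING"


@dataclass(frozen=True)
class Event:
    """One append-only log record: (time, kind, node, actor)."""

    time: int
    kind: str
    node_id: str
    actor_id: str = ""

    def as_line(self) -> str:
        return f"time={self.time}\tkind={self.kind}\tnode={self.node_id}\tactor={self.actor_id}"


@dataclass(frozen=True)
class GuardActivation:
    """A safety-guard activity instance addressed to its guard roles."""

    instance_id: str
    guard: SafetyGuardBinding
    host_task_id: str
    role_ids: frozenset[str]
    activated_at: int
    state: str = "open"  # "open" | "active" | "done"


@dataclass
class WorkflowState:
    """Complete runtime state of one pathway case.

    Treat as immutable from the outside: engine operations return fresh
    copies (the shared :class:`Model` is never copied).
    """

    model: Model
    case_id: str
    patient_id: str
    ctx: PatientContext
    task_states: dict[str, str] = field(default_factory=dict)
    tokens: Counter = field(default_factory=Counter)
    pending_guards: list[GuardActivation] = field(default_factory=list)
    clock: int = 0
    log: list[Event] = field(default_factory=list)
    enabled_since: dict[str, int] = field(default_factory=dict)
    overdue_fired: set[tuple[str, int]] = field(default_factory=set)
    active_adhoc: set[str] = field(default_factory=set)
    inclusive_waits: dict[str, list[int]] = field(default_factory=dict)
    guard_seq: int = 0
    complete: bool = False

    def clone(self) -> "WorkflowState":
        return WorkflowState(
            model=self.model,
            case_id=self.case_id,
            patient_id=self.patient_id,
            ctx=self.ctx,
            task_states=dict(self.task_states),
            tokens=Counter(self.tokens),
            pending_guards=list(self.pending_guards),
            clock=self.clock,
            log=list(self.log),
            enabled_since=dict(self.enabled_since),
            overdue_fired=set(self.overdue_fired),
            active_adhoc=set(self.active_adhoc),
            inclusive_waits={k: list(v) for k, v in self.inclusive_waits.items()},
            guard_seq=self.guard_seq,
            complete=self.complete,
        )

    # -- queries ------------------------------------------------------------

    def state_of(self, node_id: str) -> str:
        return self.task_states.get(node_id, "dormant")

    def open_guards(self) -> list[GuardActivation]:
        return [g for g in self.pending_guards if g.state != "done"]

    def log_text(self) -> str:
        return "\n".join(e.as_line() for e in self.log)


# ---------------------------------------------------------------------------
# internal helpers


def _pathway(state: WorkflowState) -> Pathway:
    return state.model.pathway


def _mark_enabled(state: WorkflowState) -> None:
    """Recompute which tasks are enabled from the token marking."""
    pw = _pathway(state)
    members = pw.adhoc_member_ids()
    for task in pw.tasks():
        cur = state.state_of(task.id)
        if cur in ("active", "completed", "skipped"):
            continue
        if task.id in members:
            in_active_block = any(
                task.id in n.task_ids
                for n in pw.nodes
                if isinstance(n, AdHocBlock) and n.id in state.active_adhoc
            )
            enabled = in_active_block
        else:
            enabled = any(state.tokens[e.id] > 0 for e in pw.in_edges(task.id))
        new = "enabled" if enabled else "dormant"
        if new != cur:
            state.task_states[task.id] = new
            if new == "enabled":
                state.enabled_since[task.id] = state.clock


def _route_tokens(state: WorkflowState) -> None:
    """Fire every gateway / block entry / end arrival until quiescent."""
    pw = _pathway(state)
    node_map = pw.node_map()
    changed = True
    while changed:
        changed = False
        for node in pw.nodes:
            if isinstance(node, GatewayNode):
                if _fire_gateway(state, node):
                    changed = True
            elif isinstance(node, AdHocBlock):
                if node.id not in state.active_adhoc:
                    for e in pw.in_edges(node.id):
                        if state.tokens[e.id] > 0:
                            state.tokens[e.id] -= 1
                            state.active_adhoc.add(node.id)
                            state.log.append(
                                Event(state.clock, "ADHOC_ENTERED", node.id)
                            )
                            changed = True
                            break
        # arrival at the end event closes the case
        end_id = pw.end_node_id
        for e in pw.in_edges(end_id):
            if state.tokens[e.id] > 0:
                state.tokens[e.id] -= 1
                if not state.complete:
                    state.complete = True
                    state.log.append(Event(state.clock, "CASE_COMPLETED", end_id))
                changed = True
    _mark_enabled(state)


def _fire_gateway(state: WorkflowState, node: GatewayNode) -> bool:
    pw = _pathway(state)
    ins = pw.in_edges(node.id)
    outs = pw.out_edges(node.id)
    if node.kind == "parallel_split":
        for e in ins:
            if state.tokens[e.id] > 0:
                state.tokens[e.id] -= 1
                for o in outs:
                    state.tokens[o.id] += 1
                return True
        return False
    if node.kind == "parallel_join":
        if ins and all(state.tokens[e.id] > 0 for e in ins):
            for e in ins:
                state.tokens[e.id] -= 1
            for o in outs:
                state.tokens[o.id] += 1
            return True
        return False
    if node.kind in ("exclusive_split", "inclusive_split"):
        for e in ins:
            if state.tokens[e.id] > 0:
                state.tokens[e.id] -= 1
                chosen: list[str] = []
                for edge_id, expr in node.branch_conditions:
                    tv = eval_expression(expr, state.ctx, state.model.schema)
                    if tv is TruthValue.TRUE:
                        chosen.append(edge_id)
                        if node.kind == "exclusive_split":
                            break
                if not chosen:
                    chosen = [node.default_edge_id]
                for c in chosen:
                    state.tokens[c] += 1
                if node.kind == "inclusive_split":
                    join_id = _matching_join(pw, node)
                    if join_id is not None:
                        state.inclusive_waits.setdefault(join_id, []).append(len(chosen))
                return True
        return False
    if node.kind == "exclusive_merge":
        for e in ins:
            if state.tokens[e.id] > 0:
                state.tokens[e.id] -= 1
                for o in outs:
                    state.tokens[o.id] += 1
                return True
        return False
    if node.kind == "inclusive_join":
        waits = state.inclusive_waits.get(node.id, [])
        if not waits:
            return False
        expected = waits[0]
        have = sum(state.tokens[e.id] for e in ins)
        if have >= expected:
            # consume exactly `expected` tokens across the incoming edges
            left = expected
            for e in ins:
                take = min(left, state.tokens[e.id])
                state.tokens[e.id] -= take
                left -= take
            waits.pop(0)
            for o in outs:
                state.tokens[o.id] += 1
            return True
        return False
    return False


def _matching_join(pw: Pathway, split: GatewayNode) -> str | None:
    """First gateway post-dominating a split (its structured partner)."""
    import networkx as nx

    h = nx.DiGraph()
    h.add_nodes_from(n.id for n in pw.nodes)
    h.add_edges_from((e.source_id, e.target_id) for e in pw.edges)
    ipd = nx.immediate_dominators(h.reverse(copy=False), pw.end_node_id)
    node_map = pw.node_map()
    cur = ipd.get(split.id)
    seen = set()
    while cur is not None and cur not in seen:
        seen.add(cur)
        if isinstance(node_map.get(cur), GatewayNode):
            return cur
        nxt = ipd.get(cur)
        cur = None if nxt == cur else nxt
    return None


def _activate_guards(
    state: WorkflowState,
    host_task_id: str,
    bindings: Iterable[SafetyGuardBinding],
    kind: str,
    host_role_ids: frozenset[str],
) -> list[GuardActivation]:
    fired: list[GuardActivation] = []
    for b in bindings:
        if b.trigger.kind != kind:
            continue
        state.guard_seq += 1
        act = GuardActivation(
            instance_id=f"{state.case_id}.g{state.guard_seq}",
            guard=b,
            host_task_id=host_task_id,
            role_ids=b.guard_role_ids or host_role_ids,
            activated_at=state.clock,
        )
        state.pending_guards.append(act)
        state.log.append(Event(state.clock, "GUARD_ACTIVATED", host_task_id))
        fired.append(act)
    return fired


def _find_activation(state: WorkflowState, instance_id: str) -> int:
    for i, g in enumerate(state.pending_guards):
        if g.instance_id == instance_id:
            return i
    raise NotEnabledError(f"no guard activation {instance_id!r}")


# ---------------------------------------------------------------------------
# public operations


def start_case(
    model: Model,
    patient_id: str,
    case_id: str,
    ctx: PatientContext | None = None,
) -> WorkflowState:
    """Open a case: validate, place the initial token, enable first tasks."""
    report = validate_model(model)
    if not report.ok:
        raise InvalidModelError(f"model fails validation:\n{report}", report=report)
    ctx = ctx or PatientContext(patient_id=patient_id)
    state = WorkflowState(model=model, case_id=case_id, patient_id=patient_id, ctx=ctx)
    for e in model.pathway.out_edges(model.pathway.start_node_id):
        state.tokens[e.id] += 1
    state.log.append(Event(0, "CASE_STARTED", model.pathway.start_node_id))
    _route_tokens(state)
    return state


def enabled_tasks(state: WorkflowState) -> set[tuple[str, frozenset[str]]]:
    """Pure query: currently workable tasks with their role assignments."""
    pw = _pathway(state)
    out = set()
    for task in pw.tasks():
        if state.state_of(task.id) in ("enabled", "active"):
            out.add((task.id, task.role_ids))
    return out


def _check_actor(task: ClinicalTask, actor: PotentialOwner | None) -> None:
    if actor is None:
        return
    if not (actor.role_ids & task.role_ids):
        raise RoleMismatchError(
            f"actor {actor.id!r} holds {sorted(actor.role_ids)}, "
            f"task {task.id!r} needs one of {sorted(task.role_ids)}"
        )


def enter_task(
    state: WorkflowState, task_id: str, actor: PotentialOwner | None = None
) -> tuple[WorkflowState, list[GuardActivation]]:
    """Mark a task active; on-entry guards produce activations."""
    st = state.clone()
    pw = _pathway(st)
    task = pw.node_map().get(task_id)
    if not isinstance(task, ClinicalTask):
        raise NotEnabledError(f"{task_id!r} is not a clinical task")
    if st.state_of(task_id) != "enabled":
        raise NotEnabledError(f"task {task_id!r} is not enabled")
    _check_actor(task, actor)
    st.task_states[task_id] = "active"
    st.log.append(Event(st.clock, "TASK_ENTERED", task_id, actor.id if actor else ""))
    fired = _activate_guards(st, task_id, task.guards, "on_entry", task.role_ids)
    return st, fired


def complete_task(
    state: WorkflowState, task_id: str, actor: PotentialOwner | None = None
) -> tuple[WorkflowState, list[GuardActivation]]:
    """Finish a task: route tokens downstream, fire on-exit guards.

    Allowed from ``enabled`` or ``active``. Blocking guards bound to the
    task must be done first.
    """
    st = state.clone()
    pw = _pathway(st)
    task = pw.node_map().get(task_id)
    if not isinstance(task, ClinicalTask):
        raise NotEnabledError(f"{task_id!r} is not a clinical task")
    if st.state_of(task_id) not in ("enabled", "active"):
        raise NotEnabledError(f"task {task_id!r} is not enabled or active")
    _check_actor(task, actor)
    for g in st.pending_guards:
        if g.host_task_id == task_id and g.guard.blocking and g.state != "done":
            raise GuardPendingError(
                f"blocking guard {g.instance_id!r} on task {task_id!r} is still open"
            )
    members = pw.adhoc_member_ids()
    if task_id not in members:
        for e in pw.in_edges(task_id):
            if st.tokens[e.id] > 0:
                st.tokens[e.id] -= 1
                break
    st.task_states[task_id] = "completed"
    st.enabled_since.pop(task_id, None)
    st.log.append(Event(st.clock, "TASK_COMPLETED", task_id, actor.id if actor else ""))
    fired = _activate_guards(st, task_id, task.guards, "on_exit", task.role_ids)
    if task_id in members:
        _settle_adhoc(st, task_id)
    else:
        for e in pw.out_edges(task_id):
            st.tokens[e.id] += 1
    _route_tokens(st)
    return st, fired


def _settle_adhoc(state: WorkflowState, member_id: str) -> None:
    pw = _pathway(state)
    for block in pw.nodes:
        if not isinstance(block, AdHocBlock) or block.id not in state.active_adhoc:
            continue
        if member_id not in block.task_ids:
            continue
        done = all(
            state.state_of(t) == "completed" for t in block.mandatory_task_ids
        )
        if done:
            for t in sorted(block.task_ids):
                if state.state_of(t) not in ("completed",):
                    state.task_states[t] = "skipped"
                    state.enabled_since.pop(t, None)
                    state.log.append(Event(state.clock, "TASK_SKIPPED", t))
            state.active_adhoc.discard(block.id)
            state.log.append(Event(state.clock, "ADHOC_COMPLETED", block.id))
            for e in pw.out_edges(block.id):
                state.tokens[e.id] += 1


def advance_clock(
    state: WorkflowState, minutes: int
) -> tuple[WorkflowState, list[GuardActivation]]:
    """Advance logical time; overdue guards fire exactly once per enablement."""
    if minutes <= 0:
        raise ValueError("minutes must be positive")
    st = state.clone()
    st.clock += minutes
    st.log.append(Event(st.clock, "CLOCK_ADVANCED", ""))
    fired: list[GuardActivation] = []
    pw = _pathway(st)
    for task in pw.tasks():
        if st.state_of(task.id) not in ("enabled", "active"):
            continue
        since = st.enabled_since.get(task.id)
        if since is None:
            continue
        for idx, b in enumerate(task.guards):
            if b.trigger.kind != "overdue":
                continue
            key = (task.id, idx)
            if key in st.overdue_fired:
                continue
            if st.clock - since > b.trigger.overdue_after:
                st.overdue_fired.add(key)
                fired.extend(
                    _activate_guards(st, task.id, [b], "overdue", task.role_ids)
                )
    return st, fired


# -- guard activations as runtime tasks -------------------------------------


def enter_guard(
    state: WorkflowState, instance_id: str, actor: PotentialOwner | None = None
) -> tuple[WorkflowState, list[GuardActivation]]:
    """Enter a guard activation; its own on-entry sub-guards activate."""
    st = state.clone()
    i = _find_activation(st, instance_id)
    act = st.pending_guards[i]
    if act.state != "open":
        raise NotEnabledError(f"guard activation {instance_id!r} is not open")
    if actor is not None and not (actor.role_ids & act.role_ids):
        raise RoleMismatchError(f"actor {actor.id!r} lacks guard roles {sorted(act.role_ids)}")
    st.pending_guards[i] = replace(act, state="active")
    st.log.append(Event(st.clock, "GUARD_ENTERED", act.host_task_id, actor.id if actor else ""))
    fired = _activate_guards(st, act.host_task_id, act.guard.guards, "on_entry", act.role_ids)
    return st, fired


def complete_guard(
    state: WorkflowState, instance_id: str, actor: PotentialOwner | None = None
) -> tuple[WorkflowState, list[GuardActivation]]:
    """Complete a guard activation; on-exit sub-guards activate."""
    st = state.clone()
    i = _find_activation(st, instance_id)
    act = st.pending_guards[i]
    if act.state == "done":
        raise NotEnabledError(f"guard activation {instance_id!r} already done")
    st.pending_guards[i] = replace(act, state="done")
    st.log.append(Event(st.clock, "GUARD_COMPLETED", act.host_task_id, actor.id if actor else ""))
    fired = _activate_guards(st, act.host_task_id, act.guard.guards, "on_exit", act.role_ids)
    return st, fired


# ---------------------------------------------------------------------------
# enumeration oracle support and simulation


def legal_completion_orders(
    model: Model,
    ctx: PatientContext | None = None,
    max_tasks: int = 7,
) -> set[tuple[str, ...]]:
    """Enumerate every task-completion order the token game admits.

    Explores the full state space by repeatedly completing any enabled task.
    Raises :class:`TooLargeError` if the pathway has more than ``max_tasks``
    clinical tasks (the enumeration is factorial).
    """
    n = len(model.pathway.tasks())
    if n > max_tasks:
        raise TooLargeError(f"{n} tasks exceeds enumeration limit {max_tasks}")
    start = start_case(model, patient_id="enum", case_id="enum", ctx=ctx)
    orders: set[tuple[str, ...]] = set()

    def explore(state: WorkflowState, prefix: tuple[str, ...]) -> None:
        if state.complete:
            orders.add(prefix)
            return
        choices = sorted(t for t, _ in enabled_tasks(state))
        if not choices:
            orders.add(prefix)  # deadlock: record partial order (tests reject)
            return
        for t in choices:
            nxt, _ = complete_task(state, t)
            explore(nxt, prefix + (t,))

    explore(start, ())
    return orders


def simulate_case(
    model: Model,
    ctx: PatientContext,
    seed: int,
    case_id: str = "sim",
    owners: Sequence[PotentialOwner] | None = None,
    max_steps: int = 10000,
) -> WorkflowState:
    """Run a case to completion with a seeded random actor-choice policy.

    At each step a uniformly random enabled task is entered and completed by
    a random owner holding one of its roles (a per-role owner is synthesized
    when none is supplied); open guard activations are completed as they
    appear. Raises :class:`DeadlockError` if no progress is possible.
    """
    rng = np.random.default_rng(seed)
    if owners is None:
        owners = [
            PotentialOwner(id=f"owner_{r.id}", name=r.name, role_ids=frozenset({r.id}))
            for r in model.pathway.roles
        ]
    state = start_case(model, patient_id=ctx.patient_id, case_id=case_id, ctx=ctx)
    for _ in range(max_steps):
        if state.complete and not state.open_guards():
            return state
        open_guards = state.open_guards()
        if open_guards:
            g = open_guards[int(rng.integers(len(open_guards)))]
            eligible = [o for o in owners if o.role_ids & g.role_ids] or [None]
            actor = eligible[int(rng.integers(len(eligible)))]
            if g.state == "open":
                state, _ = enter_guard(state, g.instance_id, actor)
            else:
                state, _ = complete_guard(state, g.instance_id, actor)
            continue
        choices = sorted(t for t, _ in enabled_tasks(state))
        if not choices:
            if state.complete:
                return state
            raise DeadlockError(
                f"case {case_id!r}: no enabled tasks and case not complete"
            )
        task_id = choices[int(rng.integers(len(choices)))]
        task = model.pathway.node_map()[task_id]
        eligible = [o for o in owners if o.role_ids & task.role_ids] or [None]
        actor = eligible[int(rng.integers(len(eligible)))]
        if state.state_of(task_id) == "enabled":
            state, _ = enter_task(state, task_id, actor)
            continue  # entry guards (possibly blocking) get handled first
        state, _ = complete_task(state, task_id, actor)
    raise DeadlockError(f"case {case_id!r} did not finish within {max_steps} steps")


def replay_log(model: Model, ctx: PatientContext, log: Sequence[Event]) -> WorkflowState:
    """Re-apply a logged event sequence; reproduces the final state exactly."""
    state: WorkflowState | None = None
    guard_cursor = 0
    for ev in log:
        if ev.kind == "CASE_STARTED":
            state = start_case(model, patient_id=ctx.patient_id, case_id="replay", ctx=ctx)
        elif state is None:
            raise InvalidModelError("log does not begin with CASE_STARTED")
        elif ev.kind == "TASK_ENTERED":
            state, _ = enter_task(state, ev.node_id, _owner_for(model, ev.actor_id))
        elif ev.kind == "TASK_COMPLETED":
            state, _ = complete_task(state, ev.node_id, _owner_for(model, ev.actor_id))
        elif ev.kind == "CLOCK_ADVANCED":
            state, _ = advance_clock(state, ev.time - state.clock)
        elif ev.kind == "GUARD_ENTERED":
            acts = [g for g in state.pending_guards if g.state == "open"]
            state, _ = enter_guard(state, acts[0].instance_id, _owner_for(model, ev.actor_id))
        elif ev.kind == "GUARD_COMPLETED":
            acts = [g for g in state.pending_guards if g.state != "done"]
            state, _ = complete_guard(state, acts[0].instance_id, _owner_for(model, ev.actor_id))
        # GUARD_ACTIVATED / TASK_SKIPPED / ADHOC_* / CASE_COMPLETED are
        # consequences, not commands; the engine re-derives them.
    if state is None:
        raise InvalidModelError("empty event log")
    return state


def _owner_for(model: Model, actor_id: str) -> PotentialOwner | None:
    if not actor_id:
        return None
    # replay logs only need role-compatible stand-ins; synthesize by id
    for r in model.pathway.roles:
        if actor_id == f"owner_{r.id}":
            return PotentialOwner(id=actor_id, name=r.name, role_ids=frozenset({r.id}))
    return PotentialOwner(
        id=actor_id,
        name=actor_id,
        role_ids=frozenset(r.id for r in model.pathway.roles),
    )
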