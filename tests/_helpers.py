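"""Shared test utilities: independent oracles and model fuzzers.

Everything here stays deliberately independent of the engine internals it
checks: the completion-order oracle enumerates permutations against a
reachability partial order, and the pathway fuzzer builds models from the
public dataclasses only.
"""

from __future__ import annotations

from itertools import permutations

import networkx as nx
import numpy as np

from dynacheck.context import ContextSchema, FieldSpec
from dynacheck.model import (
    AdHocBlock,
    ClinicalTask,
    Edge,
    EventNode,
    GatewayNode,
    Model,
    Pathway,
    Role,
    resolve_model,
    validate_model,
)
from dynacheck.expressions import parse_expression


# ---------------------------------------------------------------------------
# pathway isomorphism (BPMN round-trip checks)


def assert_pathway_isomorphic(a: Pathway, b: Pathway) -> None:
    """Same ids, node kinds, roles, guards, edges and branch conditions."""
    assert a.id == b.id
    na, nb = a.node_map(), b.node_map()
    assert set(na) == set(nb), (set(na) ^ set(nb))
    for nid, node in na.items():
        other = nb[nid]
        assert type(node) is type(other), nid
        if isinstance(node, ClinicalTask):
            assert node.role_ids == other.role_ids, nid
            assert _guard_sig(node.guards) == _guard_sig(other.guards), nid
            assert node.name == other.name
        elif isinstance(node, GatewayNode):
            assert node.kind == other.kind, nid
            assert node.default_edge_id == other.default_edge_id, nid
            conds_a = {(e, x.to_text()) for e, x in node.branch_conditions}
            conds_b = {(e, x.to_text()) for e, x in other.branch_conditions}
            assert conds_a == conds_b, nid
        elif isinstance(node, AdHocBlock):
            assert node.task_ids == other.task_ids, nid
            assert node.mandatory_task_ids == other.mandatory_task_ids, nid
    ea = {(e.id, e.source_id, e.target_id) for e in a.edges}
    eb = {(e.id, e.source_id, e.target_id) for e in b.edges}
    assert ea == eb, ea ^ eb
    assert {(r.id, r.name) for r in a.roles} == {(r.id, r.name) for r in b.roles}


def _guard_sig(guards):
    return tuple(
        (g.trigger.kind, g.trigger.overdue_after, g.form_id,
         tuple(sorted(g.guard_role_ids)), g.blocking, _guard_sig(g.guards))
        for g in guards
    )


# ---------------------------------------------------------------------------
# completion-order oracle: linear extensions of the precedence poset


def oracle_completion_orders(pathway: Pathway, ctx_values: dict | None = None):
    """Brute-force enumeration of admissible task-completion orders.

    Builds the set of *active* nodes by walking from the start, taking at an
    exclusive/inclusive split only the branches whose single-field equality
    condition holds under ``ctx_values`` (else the default edge), then
    enumerates all permutations of the active tasks and keeps the linear
    extensions of the reachability partial order. Ad-hoc members sit between
    the block's predecessors and successors with no mutual order.
    """
    ctx_values = ctx_values or {}
    g = nx.DiGraph()
    node_map = pathway.node_map()
    for e in pathway.edges:
        g.add_edge(e.source_id, e.target_id)
    # split adhoc blocks into entry/exit shells with members in between
    for n in pathway.nodes:
        if isinstance(n, AdHocBlock):
            exit_id = n.id + "__exit"
            for succ in list(g.successors(n.id)):
                g.remove_edge(n.id, succ)
                g.add_edge(exit_id, succ)
            for m in n.task_ids:
                g.add_edge(n.id, m)
                g.add_edge(m, exit_id)

    # active-edge walk: conditions are single comparisons `field == true`
    active: set[str] = set()
    frontier = [pathway.start_node_id]
    while frontier:
        cur = frontier.pop()
        if cur in active:
            continue
        active.add(cur)
        node = node_map.get(cur)
        if isinstance(node, GatewayNode) and node.kind in (
            "exclusive_split", "inclusive_split"
        ):
            taken = []
            for eid, expr in node.branch_conditions:
                field = next(iter(expr.fields()))
                if ctx_values.get(field) is True:
                    taken.append(pathway.edge_map()[eid].target_id)
                    if node.kind == "exclusive_split":
                        break
            if not taken:
                taken = [pathway.edge_map()[node.default_edge_id].target_id]
            frontier.extend(taken)
        else:
            frontier.extend(g.successors(cur))

    tasks = sorted(
        n.id for n in pathway.nodes
        if isinstance(n, ClinicalTask) and n.id in active
    )
    reach = {t: nx.descendants(g, t) for t in tasks}
    orders = set()
    for perm in permutations(tasks):
        pos = {t: i for i, t in enumerate(perm)}
        if all(
            pos[a] < pos[b]
            for a in tasks
            for b in tasks
            if a != b and b in reach[a]
        ):
            orders.add(perm)
    return orders


# ---------------------------------------------------------------------------
# SESE fragment extraction (sub-pathways of the fixtures)


def fragment_model(model: Model, entry: str, exit_: str) -> Model | None:
    """Cut the single-entry/single-exit region [entry, exit_] into a model.

    Returns None when the cut is not a well-formed pathway.
    """
    pw = model.pathway
    g = nx.DiGraph()
    for e in pw.edges:
        g.add_edge(e.source_id, e.target_id)
    if entry not in g or exit_ not in g:
        return None
    between = (nx.descendants(g, entry) & nx.ancestors(g, exit_)) | {entry, exit_}
    node_map = pw.node_map()
    members = set()
    for nid in between:
        n = node_map.get(nid)
        if isinstance(n, AdHocBlock):
            members |= n.task_ids
    keep = between | members
    nodes = [n for n in pw.nodes if n.id in keep and not isinstance(n, EventNode)]
    if not nodes:
        return None
    edges = [e for e in pw.edges if e.source_id in keep and e.target_id in keep]
    start = EventNode("frag_start", "start")
    end = EventNode("frag_end", "end")
    edges.append(Edge("frag_in", "frag_start", entry))
    edges.append(Edge("frag_out", exit_, "frag_end"))
    frag = Pathway(
        id=f"frag_{entry}_{exit_}",
        nodes=tuple([start, end] + nodes),
        edges=tuple(edges),
        start_node_id="frag_start",
        end_node_id="frag_end",
        roles=pw.roles,
        meta=pw.meta,
    )
    try:
        frag_model = resolve_model(frag, model.forms, model.rules, model.schema)
    except Exception:
        return None
    if not validate_model(frag_model).ok:
        return None
    return frag_model


# ---------------------------------------------------------------------------
# random structured pathway fuzzer


def random_structured_pathway(rng: np.random.Generator, max_depth: int = 2) -> Model:
    """Generate a small, valid, properly nested pathway for property tests."""
    counter = {"n": 0}
    nodes: list = []
    edges: list[Edge] = []
    role = Role("r", "generic role")

    def fresh(prefix: str) -> str:
        counter["n"] += 1
        return f"{prefix}{counter['n']}"

    def add_edge(src: str, tgt: str) -> str:
        eid = f"e{len(edges)}"
        edges.append(Edge(eid, src, tgt))
        return eid

    def task_node() -> tuple[str, str]:
        tid = fresh("t")
        nodes.append(ClinicalTask(id=tid, name=tid, role_ids=frozenset({"r"})))
        return tid, tid

    def block(depth: int) -> tuple[str, str]:
        """Return (entry_node, exit_node) of a generated region."""
        kind = rng.choice(
            ["task", "seq", "parallel", "exclusive", "inclusive", "adhoc"]
            if depth < max_depth else ["task", "seq", "adhoc"]
        )
        if kind == "task":
            return task_node()
        if kind == "seq":
            first = block(depth + 1)
            second = block(depth + 1)
            add_edge(first[1], second[0])
            return first[0], second[1]
        if kind == "adhoc":
            k = int(rng.integers(2, 4))
            tids = []
            for _ in range(k):
                tid = fresh("t")
                nodes.append(ClinicalTask(id=tid, name=tid, role_ids=frozenset({"r"})))
                tids.append(tid)
            bid = fresh("ah")
            nodes.append(AdHocBlock(
                id=bid, task_ids=frozenset(tids), mandatory_task_ids=frozenset(tids)
            ))
            return bid, bid
        # gateway pair
        split_kind, join_kind = {
            "parallel": ("parallel_split", "parallel_join"),
            "exclusive": ("exclusive_split", "exclusive_merge"),
            "inclusive": ("inclusive_split", "inclusive_join"),
        }[kind]
        sid, jid = fresh("g"), fresh("g")
        nodes.append(GatewayNode(id=jid, kind=join_kind))
        branches = int(rng.integers(2, 4))
        branch_edge_ids = []
        for _ in range(branches):
            entry, exit_ = block(depth + 1)
            eid = add_edge(sid, entry)
            add_edge(exit_, jid)
            branch_edge_ids.append(eid)
        if kind == "parallel":
            nodes.append(GatewayNode(id=sid, kind=split_kind))
        else:
            conds = tuple(
                (eid, parse_expression("flag == true"))
                for eid in branch_edge_ids[:-1]
            )
            nodes.append(GatewayNode(
                id=sid, kind=split_kind,
                branch_conditions=conds,
                default_edge_id=branch_edge_ids[-1],
            ))
        return sid, jid

    entry, exit_ = block(0)
    start, end = EventNode("start", "start"), EventNode("end", "end")
    add_edge("start", entry)
    add_edge(exit_, "end")
    pw = Pathway(
        id="fuzzed",
        nodes=tuple([start, end] + nodes),
        edges=tuple(edges),
        start_node_id="start",
        end_node_id="end",
        roles=(role,),
    )
    schema = ContextSchema.from_specs([FieldSpec("flag", "boolean")])
    return resolve_model(pw, [], [], schema)
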