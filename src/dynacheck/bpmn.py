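"""BPMN 2.0 XML import/export for the supported pathway subset.

Supported elements: ``process``, ``userTask``, ``sequenceFlow`` (with
optional ``conditionExpression``), ``parallelGateway``, ``exclusiveGateway``,
``inclusiveGateway``, ``adHocSubProcess``, ``laneSet``/``lane``,
``potentialOwner``/``resourceRef``, plus ``startEvent``/``endEvent`` as the
process anchors. Gateway split-vs-join direction is decided by degree.
Anything else raises ``UNSUPPORTED_ELEMENT`` in strict mode, or is skipped
with a warning otherwise.

Concepts without a BPMN counterpart — safety-guard bindings with their
triggers, and ad-hoc mandatory-member sets — travel in ``extensionElements``
under this package's own namespace; the encoding is an original design and
is not interoperable with vendor on-entry/on-exit extensions (BizAgi, jBPM).

``conditionExpression`` bodies are read with this package's expression
grammar, not XPath/FEEL — a deliberate dialect restriction that keeps rule
and branch semantics identical.
"""

from __future__ import annotations

from lxml import etree

from .errors import UnsupportedElementError
from .expressions import parse_expression
from .model import (
    AdHocBlock,
    ClinicalTask,
    Edge,
    EventNode,
    GatewayNode,
    MetaInfo,
    Pathway,
    Role,
    SafetyGuardBinding,
    Trigger,
    ValidationReport,
    validate_pathway,
)

BPMN_NS = "http://www.omg.org/spec/BPMN/20100524/MODEL"
EXT_NS = "urn:dynacheck:bpmn-ext:1.0"
NSMAP = {None: BPMN_NS, "dc": EXT_NS}


def _b(tag: str) -> str:
    return f"{{{BPMN_NS}}}{tag}"


def _x(tag: str) -> str:
    return f"{{{EXT_NS}}}{tag}"


# ---------------------------------------------------------------------------
# export


def export_bpmn(pathway: Pathway) -> bytes:
    """Serialize a pathway to BPMN 2.0 XML (UTF-8 bytes)."""
    defs = etree.Element(_b("definitions"), nsmap=NSMAP)
    defs.set("targetNamespace", EXT_NS)
    defs.set("id", f"defs_{pathway.id}")
    proc = etree.SubElement(defs, _b("process"))
    proc.set("id", pathway.id)
    if pathway.meta.title:
        proc.set("name", pathway.meta.title)
    ext = etree.SubElement(proc, _b("extensionElements"))
    meta = etree.SubElement(ext, _x("meta"))
    meta.set("title", pathway.meta.title)
    meta.set("author", pathway.meta.author)
    meta.set("version", pathway.meta.version)
    if pathway.meta.created:
        meta.set("created", pathway.meta.created.isoformat())

    if pathway.roles:
        lane_set = etree.SubElement(proc, _b("laneSet"))
        lane_set.set("id", f"lanes_{pathway.id}")
        task_roles = {
            t.id: t.role_ids for t in pathway.tasks()
        }
        for role in pathway.roles:
            lane = etree.SubElement(lane_set, _b("lane"))
            lane.set("id", f"lane_{role.id}")
            lane.set("name", role.name)
            for tid in sorted(task_roles):
                if role.id in task_roles[tid]:
                    ref = etree.SubElement(lane, _b("flowNodeRef"))
                    ref.text = tid

    member_ids = pathway.adhoc_member_ids()
    node_map = pathway.node_map()

    def emit_task(parent, task: ClinicalTask) -> None:
        el = etree.SubElement(parent, _b("userTask"))
        el.set("id", task.id)
        el.set("name", task.name)
        if task.guards:
            gext = etree.SubElement(el, _b("extensionElements"))
            for g in task.guards:
                _emit_guard(gext, g)
        for rid in sorted(task.role_ids):
            po = etree.SubElement(el, _b("potentialOwner"))
            rr = etree.SubElement(po, _b("resourceRef"))
            rr.text = rid

    for node in pathway.nodes:
        if isinstance(node, EventNode):
            el = etree.SubElement(proc, _b("startEvent" if node.kind == "start" else "endEvent"))
            el.set("id", node.id)
        elif isinstance(node, ClinicalTask):
            if node.id in member_ids:
                continue  # emitted inside its ad-hoc subprocess
            emit_task(proc, node)
        elif isinstance(node, GatewayNode):
            tag = {
                "parallel_split": "parallelGateway",
                "parallel_join": "parallelGateway",
                "exclusive_split": "exclusiveGateway",
                "exclusive_merge": "exclusiveGateway",
                "inclusive_split": "inclusiveGateway",
                "inclusive_join": "inclusiveGateway",
            }[node.kind]
            el = etree.SubElement(proc, _b(tag))
            el.set("id", node.id)
            el.set(
                "gatewayDirection",
                "Diverging" if node.kind.endswith("_split") else "Converging",
            )
            if node.default_edge_id:
                el.set("default", node.default_edge_id)
        elif isinstance(node, AdHocBlock):
            el = etree.SubElement(proc, _b("adHocSubProcess"))
            el.set("id", node.id)
            if node.name:
                el.set("name", node.name)
            aext = etree.SubElement(el, _b("extensionElements"))
            mand = etree.SubElement(aext, _x("mandatory"))
            mand.text = " ".join(sorted(node.mandatory_task_ids))
            for tid in sorted(node.task_ids):
                emit_task(el, node_map[tid])

    conditions: dict[str, str] = {}
    for node in pathway.nodes:
        if isinstance(node, GatewayNode):
            for eid, expr in node.branch_conditions:
                conditions[eid] = expr.to_text()
    for edge in pathway.edges:
        el = etree.SubElement(proc, _b("sequenceFlow"))
        el.set("id", edge.id)
        el.set("sourceRef", edge.source_id)
        el.set("targetRef", edge.target_id)
        if edge.id in conditions:
            ce = etree.SubElement(el, _b("conditionExpression"))
            ce.text = conditions[edge.id]
    return etree.tostring(
        defs, pretty_print=True, xml_declaration=True, encoding="UTF-8"
    )


def _emit_guard(parent, g: SafetyGuardBinding) -> None:
    el = etree.SubElement(parent, _x("guard"))
    el.set("trigger", g.trigger.kind)
    if g.trigger.overdue_after is not None:
        el.set("overdueAfter", str(g.trigger.overdue_after))
    el.set("form", g.form_id)
    if g.guard_role_ids:
        el.set("roles", " ".join(sorted(g.guard_role_ids)))
    if g.blocking:
        el.set("blocking", "true")
    for sub in g.guards:
        _emit_guard(el, sub)


# ---------------------------------------------------------------------------
# import


def _parse_guard(el) -> SafetyGuardBinding:
    kind = el.get("trigger")
    overdue = el.get("overdueAfter")
    trigger = Trigger(kind=kind, overdue_after=int(overdue) if overdue else None)
    roles = frozenset((el.get("roles") or "").split()) - {""}
    return SafetyGuardBinding(
        trigger=trigger,
        form_id=el.get("form"),
        guard_role_ids=roles,
        blocking=el.get("blocking") == "true",
        guards=tuple(_parse_guard(s) for s in el.findall(_x("guard"))),
    )


def import_bpmn(doc: bytes | str, strict: bool = True) -> tuple[Pathway, ValidationReport]:
    """Parse a BPMN subset document into a :class:`Pathway`.

    Returns the pathway together with its structural validation report
    (import warnings for skipped elements included in lenient mode).
    """
    if isinstance(doc, str):
        doc = doc.encode("utf-8")
    root = etree.fromstring(doc)
    if root.tag == _b("definitions"):
        proc = root.find(_b("process"))
    elif root.tag == _b("process"):
        proc = root
    else:
        raise UnsupportedElementError(f"expected a BPMN definitions document, got {root.tag}")
    if proc is None:
        raise UnsupportedElementError("document contains no process element")

    warnings: list[tuple[str, str, str]] = []
    nodes: list = []
    edges: list[Edge] = []
    roles: dict[str, Role] = {}
    lane_membership: dict[str, set[str]] = {}
    meta = MetaInfo()
    adhoc_members: dict[str, set[str]] = {}
    conditional_flows: list[tuple[str, str, str]] = []  # (edge_id, source, text)
    start_id = end_id = None

    def local(tag: str) -> str:
        return etree.QName(tag).localname

    def unsupported(el) -> None:
        name = local(el.tag)
        eid = el.get("id", "?")
        if strict:
            raise UnsupportedElementError(
                f"element <{name}> (id {eid!r}) is outside the supported subset"
            )
        warnings.append(("UNSUPPORTED_ELEMENT", eid, f"skipped <{name}>"))

    def read_task(el, parent_block: str | None = None) -> ClinicalTask:
        tid = el.get("id")
        guards = []
        role_ids: set[str] = set()
        for child in el:
            name = local(child.tag)
            if name == "extensionElements":
                guards = [_parse_guard(g) for g in child.findall(_x("guard"))]
            elif name == "potentialOwner":
                for rr in child.findall(_b("resourceRef")):
                    if rr.text:
                        role_ids.add(rr.text.strip())
            elif name in ("incoming", "outgoing", "documentation"):
                pass
            else:
                unsupported(child)
        if parent_block is not None:
            adhoc_members[parent_block].add(tid)
        return ClinicalTask(
            id=tid, name=el.get("name", tid), role_ids=frozenset(role_ids), guards=tuple(guards)
        )

    for el in proc:
        name = local(el.tag)
        if name == "extensionElements":
            m = el.find(_x("meta"))
            if m is not None:
                import datetime as _dt

                created = m.get("created")
                meta = MetaInfo(
                    title=m.get("title", ""),
                    author=m.get("author", ""),
                    version=m.get("version", "1"),
                    created=_dt.date.fromisoformat(created) if created else None,
                )
        elif name == "laneSet":
            for lane in el.findall(_b("lane")):
                rid = lane.get("id", "")
                rid = rid[5:] if rid.startswith("lane_") else rid
                roles[rid] = Role(id=rid, name=lane.get("name", rid))
                members = {
                    ref.text.strip()
                    for ref in lane.findall(_b("flowNodeRef"))
                    if ref.text
                }
                lane_membership[rid] = members
        elif name == "startEvent":
            start_id = el.get("id")
            nodes.append(EventNode(id=start_id, kind="start"))
        elif name == "endEvent":
            end_id = el.get("id")
            nodes.append(EventNode(id=end_id, kind="end"))
        elif name == "userTask":
            nodes.append(read_task(el))
        elif name in ("parallelGateway", "exclusiveGateway", "inclusiveGateway"):
            nodes.append((el, name))  # degree decided after flows are read
        elif name == "adHocSubProcess":
            bid = el.get("id")
            adhoc_members[bid] = set()
            mandatory: set[str] = set()
            for child in el:
                cname = local(child.tag)
                if cname == "extensionElements":
                    m = child.find(_x("mandatory"))
                    if m is not None and m.text:
                        mandatory = set(m.text.split())
                elif cname == "userTask":
                    nodes.append(read_task(child, parent_block=bid))
                elif cname in ("completionCondition", "documentation"):
                    pass
                else:
                    unsupported(child)
            nodes.append(
                AdHocBlock(
                    id=bid,
                    task_ids=frozenset(adhoc_members[bid]),
                    mandatory_task_ids=frozenset(mandatory or adhoc_members[bid]),
                    name=el.get("name", ""),
                )
            )
        elif name == "sequenceFlow":
            eid = el.get("id")
            edges.append(Edge(id=eid, source_id=el.get("sourceRef"), target_id=el.get("targetRef")))
            ce = el.find(_b("conditionExpression"))
            if ce is not None and ce.text:
                conditional_flows.append((eid, el.get("sourceRef"), ce.text.strip()))
        else:
            unsupported(el)

    # lane membership assigns roles to tasks that had no potentialOwner
    resolved_nodes = []
    cond_by_source: dict[str, list[tuple[str, str]]] = {}
    for eid, src, text in conditional_flows:
        cond_by_source.setdefault(src, []).append((eid, text))
    outs: dict[str, int] = {}
    ins: dict[str, int] = {}
    for e in edges:
        outs[e.source_id] = outs.get(e.source_id, 0) + 1
        ins[e.target_id] = ins.get(e.target_id, 0) + 1

    for node in nodes:
        if isinstance(node, tuple):
            el, name = node
            gid = el.get("id")
            diverging = outs.get(gid, 0) > 1 or (
                outs.get(gid, 0) == 1 and ins.get(gid, 0) <= 1
                and el.get("gatewayDirection") == "Diverging"
            )
            base = {
                "parallelGateway": ("parallel_split", "parallel_join"),
                "exclusiveGateway": ("exclusive_split", "exclusive_merge"),
                "inclusiveGateway": ("inclusive_split", "inclusive_join"),
            }[name]
            kind = base[0] if diverging else base[1]
            branch_conditions = ()
            if kind in ("exclusive_split", "inclusive_split"):
                branch_conditions = tuple(
                    (eid, parse_expression(text))
                    for eid, text in cond_by_source.get(gid, [])
                )
            resolved_nodes.append(
                GatewayNode(
                    id=gid,
                    kind=kind,
                    branch_conditions=branch_conditions,
                    default_edge_id=el.get("default"),
                )
            )
        elif isinstance(node, ClinicalTask):
            extra = {
                rid for rid, members in lane_membership.items() if node.id in members
            }
            resolved_nodes.append(
                ClinicalTask(
                    id=node.id,
                    name=node.name,
                    role_ids=node.role_ids | extra,
                    guards=node.guards,
                )
            )
        else:
            resolved_nodes.append(node)

    pathway = Pathway(
        id=proc.get("id", "pathway"),
        nodes=tuple(resolved_nodes),
        edges=tuple(edges),
        start_node_id=start_id or "",
        end_node_id=end_id or "",
        roles=tuple(roles[r] for r in sorted(roles)),
        meta=meta,
    )
    report = validate_pathway(pathway)
    for w in warnings:
        report.warn(*w)
    return pathway, report
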