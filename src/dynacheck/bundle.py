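"""Native model bundles: a directory of YAML documents plus rule files.

Layout (see ``dynacheck/schemas/bundle-v1.yaml`` for the normative key
lists)::

    <bundle>/
      pathway.yaml     # the care pathway graph, roles, guard bindings
      forms/*.yaml     # one checklist form per file
      rules/*.rules    # WHEN/THEN rule DSL
      schema.yaml      # patient-context field catalogue

Loading is schema-checked: an unknown mapping key anywhere raises
``SCHEMA_VIOLATION`` with a JSON-pointer-style path. ``load_bundle``
cross-links everything through :func:`dynacheck.model.resolve_model`, so a
successfully loaded model has no dangling references. ``save_bundle`` is
its semantic inverse.
"""

from __future__ import annotations

import datetime as _dt
from importlib import resources
from pathlib import Path

import yaml

from .context import ContextSchema, FieldSpec
from .dsl import parse_rule_dsl, rules_to_dsl
from .errors import SchemaViolationError
from .expressions import parse_expression
from .model import (
    AdHocBlock,
    CheckableItem,
    ChecklistForm,
    ClinicalTask,
    Edge,
    EventNode,
    GatewayNode,
    MetaInfo,
    Model,
    Pathway,
    Role,
    SafetyGuardBinding,
    SupplementaryMaterial,
    TargetClinicalProblem,
    Trigger,
    resolve_model,
)


def _load_bundle_schema() -> dict:
    text = resources.files("dynacheck.schemas").joinpath("bundle-v1.yaml").read_text()
    return yaml.safe_load(text)


_BUNDLE_SCHEMA = _load_bundle_schema()
_ALLOWED = _BUNDLE_SCHEMA["allowed_keys"]
_NODE_KINDS = set(_BUNDLE_SCHEMA["node_kinds"])


def _check_keys(section: str, mapping: object, pointer: str) -> dict:
    if not isinstance(mapping, dict):
        raise SchemaViolationError(f"expected a mapping for {section}", pointer)
    allowed = set(_ALLOWED[section])
    for key in mapping:
        if key not in allowed:
            raise SchemaViolationError(
                f"unknown key {key!r} in {section} (allowed: {sorted(allowed)})",
                f"{pointer}/{key}",
            )
    return mapping


def _req(mapping: dict, key: str, pointer: str):
    if key not in mapping:
        raise SchemaViolationError(f"missing required key {key!r}", pointer)
    return mapping[key]


# ---------------------------------------------------------------------------
# parse


def _parse_meta(raw: object, pointer: str) -> MetaInfo:
    if raw is None:
        return MetaInfo()
    m = _check_keys("meta", raw, pointer)
    created = m.get("created")
    if isinstance(created, str):
        created = _dt.date.fromisoformat(created)
    return MetaInfo(
        title=m.get("title", ""),
        author=m.get("author", ""),
        version=str(m.get("version", "1")),
        created=created,
    )


def _parse_trigger(raw: object, pointer: str) -> Trigger:
    if isinstance(raw, str):
        return Trigger(kind=raw)
    t = _check_keys("trigger", raw, pointer)
    return Trigger(kind=_req(t, "kind", pointer), overdue_after=t.get("after"))


def _parse_guard(raw: object, pointer: str) -> SafetyGuardBinding:
    g = _check_keys("guard", raw, pointer)
    return SafetyGuardBinding(
        trigger=_parse_trigger(_req(g, "trigger", pointer), f"{pointer}/trigger"),
        form_id=_req(g, "form", pointer),
        guard_role_ids=frozenset(g.get("roles", [])),
        blocking=bool(g.get("blocking", False)),
        guards=tuple(
            _parse_guard(sub, f"{pointer}/guards/{i}")
            for i, sub in enumerate(g.get("guards", []))
        ),
    )


def _parse_node(raw: object, pointer: str):
    n = _check_keys("node", raw, pointer)
    nid = _req(n, "id", pointer)
    kind = _req(n, "kind", pointer)
    if kind not in _NODE_KINDS:
        raise SchemaViolationError(f"unknown node kind {kind!r}", f"{pointer}/kind")
    if kind == "task":
        return ClinicalTask(
            id=nid,
            name=n.get("name", nid),
            role_ids=frozenset(n.get("roles", [])),
            guards=tuple(
                _parse_guard(g, f"{pointer}/guards/{i}")
                for i, g in enumerate(n.get("guards", []))
            ),
        )
    if kind in ("start", "end"):
        return EventNode(id=nid, kind=kind)
    if kind == "ad_hoc":
        tasks = n.get("tasks", [])
        return AdHocBlock(
            id=nid,
            task_ids=frozenset(tasks),
            mandatory_task_ids=frozenset(n.get("mandatory", tasks)),
            name=n.get("name", ""),
        )
    conditions = tuple(
        (
            _req(_check_keys("condition", c, f"{pointer}/conditions/{i}"), "edge", pointer),
            parse_expression(_req(c, "when", pointer)),
        )
        for i, c in enumerate(n.get("conditions", []))
    )
    return GatewayNode(
        id=nid,
        kind=kind,
        branch_conditions=conditions,
        default_edge_id=n.get("default_edge"),
    )


def parse_pathway_doc(doc: object, pointer: str = "") -> Pathway:
    top = _check_keys("pathway_doc", doc, pointer or "/")
    p = _check_keys("pathway", _req(top, "pathway", "/"), f"{pointer}/pathway")
    base = f"{pointer}/pathway"
    roles = tuple(
        Role(
            id=_req(_check_keys("role", r, f"{base}/roles/{i}"), "id", base),
            name=r.get("name", r.get("id", "")),
        )
        for i, r in enumerate(p.get("roles", []))
    )
    nodes = tuple(
        _parse_node(n, f"{base}/nodes/{i}") for i, n in enumerate(_req(p, "nodes", base))
    )
    edges = []
    for i, e in enumerate(p.get("edges", [])):
        em = _check_keys("edge", e, f"{base}/edges/{i}")
        src, tgt = _req(em, "from", base), _req(em, "to", base)
        edges.append(Edge(id=em.get("id", f"{src}--{tgt}"), source_id=src, target_id=tgt))
    return Pathway(
        id=_req(p, "id", base),
        nodes=nodes,
        edges=tuple(edges),
        start_node_id=_req(p, "start", base),
        end_node_id=_req(p, "end", base),
        roles=roles,
        meta=_parse_meta(p.get("meta"), f"{base}/meta"),
    )


def _parse_item(raw: object, pointer: str) -> CheckableItem:
    it = _check_keys("item", raw, pointer)
    options = it.get("options", "default")
    if options == "default":
        opts: tuple[str, ...] | None = CheckableItem.__dataclass_fields__["options"].default
    elif options is None:
        opts = None
    else:
        opts = tuple(options)
    return CheckableItem(
        id=_req(it, "id", pointer),
        description=_req(it, "text", pointer),
        options=opts,
        priority=it.get("priority", "normal"),
        supplementary=tuple(
            SupplementaryMaterial(
                kind=_req(_check_keys("material", m, f"{pointer}/supplementary/{i}"), "kind", pointer),
                payload=_req(m, "payload", pointer),
            )
            for i, m in enumerate(it.get("supplementary", []))
        ),
        pre_checked=bool(it.get("pre_checked", False)),
    )


def parse_form_doc(doc: object, pointer: str = "") -> ChecklistForm:
    top = _check_keys("form_doc", doc, pointer or "/")
    f = _check_keys("form", _req(top, "form", "/"), f"{pointer}/form")
    base = f"{pointer}/form"
    problems = []
    for i, praw in enumerate(_req(f, "problems", base)):
        p = _check_keys("problem", praw, f"{base}/problems/{i}")
        problems.append(
            TargetClinicalProblem(
                id=_req(p, "id", base),
                description=p.get("description", ""),
                static_items=tuple(
                    _parse_item(it, f"{base}/problems/{i}/items/{j}")
                    for j, it in enumerate(p.get("items", []))
                ),
                algorithm_ids=tuple(p.get("algorithms", [])),
            )
        )
    return ChecklistForm(
        id=_req(f, "id", base),
        problems=tuple(problems),
        meta=_parse_meta(f.get("meta"), f"{base}/meta"),
    )


def parse_schema_doc(doc: object, pointer: str = "") -> ContextSchema:
    top = _check_keys("schema_doc", doc, pointer or "/")
    s = _check_keys("schema", _req(top, "schema", "/"), f"{pointer}/schema")
    specs = []
    for i, fraw in enumerate(s.get("fields", [])):
        fm = _check_keys("field", fraw, f"{pointer}/schema/fields/{i}")
        specs.append(
            FieldSpec(
                name=_req(fm, "name", pointer),
                type=_req(fm, "type", pointer),
                description=fm.get("description", ""),
            )
        )
    return ContextSchema.from_specs(specs)


# ---------------------------------------------------------------------------
# load / save


def load_documents(path: str | Path) -> tuple[Pathway | None, list, list, ContextSchema]:
    """Parse all bundle documents without cross-link resolution."""
    root = Path(path)
    pathway = None
    pw_file = root / "pathway.yaml"
    if pw_file.exists():
        pathway = parse_pathway_doc(yaml.safe_load(pw_file.read_text()), "/pathway.yaml")
    forms = []
    forms_dir = root / "forms"
    if forms_dir.is_dir():
        for f in sorted(forms_dir.glob("*.yaml")):
            forms.append(parse_form_doc(yaml.safe_load(f.read_text()), f"/forms/{f.name}"))
    rules = []
    rules_dir = root / "rules"
    if rules_dir.is_dir():
        for f in sorted(rules_dir.glob("*.rules")):
            rules.extend(parse_rule_dsl(f.read_text()))
    schema = ContextSchema()
    schema_file = root / "schema.yaml"
    if schema_file.exists():
        schema = parse_schema_doc(yaml.safe_load(schema_file.read_text()), "/schema.yaml")
    return pathway, forms, rules, schema


def load_bundle(path: str | Path) -> Model:
    """Load and fully resolve a bundle directory into a :class:`Model`."""
    pathway, forms, rules, schema = load_documents(path)
    return resolve_model(pathway, forms, rules, schema)


# -- serialization ----------------------------------------------------------


def _meta_to_yaml(meta: MetaInfo) -> dict:
    d = {"title": meta.title, "author": meta.author, "version": meta.version}
    if meta.created:
        d["created"] = meta.created.isoformat()
    return d


def _guard_to_yaml(g: SafetyGuardBinding) -> dict:
    trigger: object = g.trigger.kind
    if g.trigger.overdue_after is not None:
        trigger = {"kind": g.trigger.kind, "after": g.trigger.overdue_after}
    d: dict = {"trigger": trigger, "form": g.form_id}
    if g.guard_role_ids:
        d["roles"] = sorted(g.guard_role_ids)
    if g.blocking:
        d["blocking"] = True
    if g.guards:
        d["guards"] = [_guard_to_yaml(s) for s in g.guards]
    return d


def _node_to_yaml(n) -> dict:
    if isinstance(n, ClinicalTask):
        d: dict = {"id": n.id, "kind": "task", "name": n.name, "roles": sorted(n.role_ids)}
        if n.guards:
            d["guards"] = [_guard_to_yaml(g) for g in n.guards]
        return d
    if isinstance(n, EventNode):
        return {"id": n.id, "kind": n.kind}
    if isinstance(n, AdHocBlock):
        d = {"id": n.id, "kind": "ad_hoc", "tasks": sorted(n.task_ids)}
        if n.mandatory_task_ids != n.task_ids:
            d["mandatory"] = sorted(n.mandatory_task_ids)
        if n.name:
            d["name"] = n.name
        return d
    d = {"id": n.id, "kind": n.kind}
    if n.branch_conditions:
        d["conditions"] = [
            {"edge": eid, "when": expr.to_text()} for eid, expr in n.branch_conditions
        ]
    if n.default_edge_id:
        d["default_edge"] = n.default_edge_id
    return d


def pathway_to_yaml(pathway: Pathway) -> dict:
    return {
        "pathway": {
            "id": pathway.id,
            "meta": _meta_to_yaml(pathway.meta),
            "roles": [{"id": r.id, "name": r.name} for r in pathway.roles],
            "nodes": [_node_to_yaml(n) for n in pathway.nodes],
            "edges": [
                {"id": e.id, "from": e.source_id, "to": e.target_id}
                for e in pathway.edges
            ],
            "start": pathway.start_node_id,
            "end": pathway.end_node_id,
        }
    }


def form_to_yaml(form: ChecklistForm) -> dict:
    problems = []
    for p in form.problems:
        items = []
        for it in p.static_items:
            d: dict = {"id": it.id, "text": it.description}
            if it.options is None:
                d["options"] = None
            elif tuple(it.options) != CheckableItem.__dataclass_fields__["options"].default:
                d["options"] = list(it.options)
            if it.priority != "normal":
                d["priority"] = it.priority
            if it.pre_checked:
                d["pre_checked"] = True
            if it.supplementary:
                d["supplementary"] = [
                    {"kind": m.kind, "payload": m.payload} for m in it.supplementary
                ]
            items.append(d)
        pd: dict = {"id": p.id, "description": p.description}
        if p.algorithm_ids:
            pd["algorithms"] = list(p.algorithm_ids)
        if items:
            pd["items"] = items
        problems.append(pd)
    return {"form": {"id": form.id, "meta": _meta_to_yaml(form.meta), "problems": problems}}


def schema_to_yaml(schema: ContextSchema) -> dict:
    return {
        "schema": {
            "fields": [
                {"name": s.name, "type": s.type, "description": s.description}
                for s in schema.fields.values()
            ]
        }
    }


def save_bundle(model: Model, path: str | Path) -> None:
    """Write a model out as a bundle directory (inverse of load, semantically)."""
    root = Path(path)
    (root / "forms").mkdir(parents=True, exist_ok=True)
    (root / "rules").mkdir(parents=True, exist_ok=True)
    dump = lambda obj: yaml.safe_dump(obj, sort_keys=False, allow_unicode=True)
    (root / "pathway.yaml").write_text(dump(pathway_to_yaml(model.pathway)))
    for form in model.forms:
        (root / "forms" / f"{form.id}.yaml").write_text(dump(form_to_yaml(form)))
    if model.rules:
        (root / "rules" / "rules.rules").write_text(rules_to_dsl(model.rules))
    (root / "schema.yaml").write_text(dump(schema_to_yaml(model.schema)))
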