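"""Build and render patient-specific checklist instances.

Instantiation merges a form's static items with the effects of its clinical
rules evaluated against one patient context: rules may add items (appended
at the end of their target problem's block), highlight items in red,
pre-check items (rendered gray / ``[x]``), raise priority (the trailing "M"
mark) and attach supplementary material. ``{field}`` slots in item text bind
patient values; a missing field renders as an em dash and suppresses any
auto-check of that item, so the system never claims to have verified
something it could not read.

Three renderers share one semantic model: 80-column plain text, a
self-contained HTML page with semantic classes (``item--auto``,
``item--red``, ``item--priority``), and an XML document conforming to the
schema shipped in ``dynacheck/schemas/checklist-instance.xsd``. Rendering is
deterministic and the XML round-trips byte-identically.
"""

from __future__ import annotations

import datetime as _dt
import html as _html
import re
from dataclasses import dataclass, replace

from lxml import etree

from .context import PatientContext, value_kind
from .errors import (
    BadOptionError,
    DanglingItemRefError,
    DynacheckError,
    NoOptionsError,
    UnknownFormatError,
)
from .model import (
    SLOT_RE,
    ChecklistForm,
    CheckableItem,
    Model,
    SupplementaryMaterial,
)
from .rules import EvaluationTrace, RuleEffect, fire_rules

ITEM_STATES = ("unchecked", "checked", "auto_checked", "not_applicable")
MISSING_MARK = "—"  # em dash for unbound slots


class GuidancePrecheckError(DynacheckError):
    code = "GUIDANCE_PRECHECK"


@dataclass(frozen=True)
class ItemInstance:
    """One rendered checklist entry for one patient."""

    item_id: str
    problem_id: str
    rendered_text: str
    state: str = "unchecked"
    flags: frozenset[str] = frozenset()  # subset of {highlight_red, priority_mark}
    bound_values: tuple[tuple[str, object], ...] = ()
    provenance: str = "static"  # "static" or "rule:a>b" chain
    options: tuple[str, ...] | None = None
    supplementary: tuple[SupplementaryMaterial, ...] = ()

    @property
    def guidance_only(self) -> bool:
        return self.options is None


@dataclass(frozen=True)
class ChecklistInstance:
    """A patient-specific checklist: ordered items plus audit trail."""

    instance_id: str
    form_id: str
    patient_id: str
    generated_at: int
    items: tuple[ItemInstance, ...]
    problem_order: tuple[tuple[str, str], ...] = ()  # (problem_id, description)
    audit: tuple[str, ...] = ()

    def item(self, item_id: str) -> ItemInstance:
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise DanglingItemRefError(f"no item {item_id!r} in instance")

    def rule_added_items(self) -> list[ItemInstance]:
        return [i for i in self.items if i.provenance != "static"]


def _bind(template: str, ctx: PatientContext) -> tuple[str, dict[str, object], bool]:
    """Substitute ``{field}`` slots; returns (text, bound, all_present)."""
    bound: dict[str, object] = {}
    complete = True

    def sub(m: re.Match) -> str:
        nonlocal complete
        name = m.group(1)
        if ctx.has(name):
            v = ctx.get(name)
            bound[name] = v
            return _fmt_value(v)
        complete = False
        return MISSING_MARK

    text = SLOT_RE.sub(sub, template)
    return text, bound, complete


def _fmt_value(v: object) -> str:
    if isinstance(v, bool):
        return "yes" if v else "no"
    if isinstance(v, float) and v.is_integer():
        return str(int(v))
    if isinstance(v, _dt.date):
        return v.isoformat()
    return str(v)


def _make_item_instance(
    item: CheckableItem, problem_id: str, ctx: PatientContext, provenance: str
) -> ItemInstance:
    text, bound, complete = _bind(item.description, ctx)
    state = "unchecked"
    if item.pre_checked and not item.guidance_only and complete:
        state = "auto_checked"
    flags = frozenset({"priority_mark"}) if item.priority == "high" else frozenset()
    return ItemInstance(
        item_id=item.id,
        problem_id=problem_id,
        rendered_text=text,
        state=state,
        flags=flags,
        bound_values=tuple(sorted(bound.items())),
        provenance=provenance,
        options=item.options,
        supplementary=item.supplementary,
    )


def instantiate_checklist(
    form: ChecklistForm,
    ctx: PatientContext,
    model: Model,
    *,
    instance_id: str | None = None,
    generated_at: int = 0,
    trace: EvaluationTrace | None = None,
) -> ChecklistInstance:
    """Instantiate ``form`` for one patient by applying its clinical rules.

    Effects apply in firing order; ``add_item`` appends within the target
    problem's block (form order is otherwise preserved). An effect naming an
    item absent from the instance raises :class:`DanglingItemRefError`.
    """
    rule_map = model.rule_map()
    items: dict[str, list[ItemInstance]] = {}
    problem_of_rule: dict[str, str] = {}
    ordered_rules = []
    for p in form.problems:
        items[p.id] = [
            _make_item_instance(i, p.id, ctx, "static") for i in p.static_items
        ]
        for aid in p.algorithm_ids:
            rule = rule_map[aid]
            ordered_rules.append(rule)
            problem_of_rule.setdefault(aid, p.id)

    effects = fire_rules(
        ordered_rules, ctx, all_rules=model.rules, schema=model.schema, trace=trace
    )
    for eff in effects:
        _apply_effect(eff, items, ctx, problem_of_rule, form)

    ordered: list[ItemInstance] = []
    for p in form.problems:
        ordered.extend(items[p.id])
    if not ordered:
        raise DynacheckError(f"instance of form {form.id!r} has no items")
    return ChecklistInstance(
        instance_id=instance_id or f"{form.id}.{ctx.patient_id}",
        form_id=form.id,
        patient_id=ctx.patient_id,
        generated_at=generated_at,
        items=tuple(ordered),
        problem_order=tuple((p.id, p.description) for p in form.problems),
    )


def _target_problem(
    eff: RuleEffect, problem_of_rule: dict[str, str], form: ChecklistForm
) -> str:
    # innermost rule with an explicit problem wins, else the problem that
    # listed the outermost rule as its algorithm
    for rid in reversed(eff.provenance):
        pid = problem_of_rule.get(rid)
        if pid:
            return pid
    return form.problems[0].id


def _apply_effect(
    eff: RuleEffect,
    items: dict[str, list[ItemInstance]],
    ctx: PatientContext,
    problem_of_rule: dict[str, str],
    form: ChecklistForm,
) -> None:
    a = eff.action
    provenance = "rule:" + ">".join(eff.provenance)

    def locate(item_id: str) -> tuple[str, int]:
        for pid, lst in items.items():
            for i, inst in enumerate(lst):
                if inst.item_id == item_id:
                    return pid, i
        raise DanglingItemRefError(
            f"effect {a.kind!r} from {provenance} targets missing item {item_id!r}"
        )

    if a.kind == "add_item":
        pid = _target_problem(eff, problem_of_rule, form)
        items[pid].append(_make_item_instance(a.item, pid, ctx, provenance))
        return
    pid, i = locate(a.item_id)
    inst = items[pid][i]
    if a.kind == "highlight":
        inst = replace(inst, flags=inst.flags | {"highlight_red"})
    elif a.kind == "pre_check":
        if inst.guidance_only:
            raise GuidancePrecheckError(
                f"rule {provenance} pre-checks guidance-only item {a.item_id!r}"
            )
        # a missing binding suppresses auto-check: the claim is unverifiable
        slots_complete = MISSING_MARK not in inst.rendered_text
        if slots_complete and inst.state == "unchecked":
            inst = replace(inst, state="auto_checked")
    elif a.kind == "set_priority":
        if a.level == "high":
            inst = replace(inst, flags=inst.flags | {"priority_mark"})
        else:
            inst = replace(inst, flags=inst.flags - {"priority_mark"})
    elif a.kind == "attach_material":
        inst = replace(inst, supplementary=inst.supplementary + (a.material,))
    items[pid][i] = inst


# ---------------------------------------------------------------------------
# human interaction


def record_check(
    instance: ChecklistInstance, item_id: str, actor_id: str, option: str
) -> ChecklistInstance:
    """Record a human answer on an item.

    Guidance-only items take no answer (``NO_OPTIONS``); the option must be
    one of the item's declared options (``BAD_OPTION``). Overriding an
    auto-checked item is allowed but logged as an override.
    """
    target = instance.item(item_id)
    if target.guidance_only:
        raise NoOptionsError(f"item {item_id!r} is guidance-only")
    if option not in target.options:
        raise BadOptionError(
            f"option {option!r} not in {list(target.options)} for item {item_id!r}"
        )
    new_state = "not_applicable" if option == "not_applicable" else "checked"
    audit = instance.audit + (
        f"{actor_id} answered {option!r} on {item_id}"
        + (" (override of auto-check)" if target.state == "auto_checked" else ""),
    )
    new_items = tuple(
        replace(it, state=new_state) if it.item_id == item_id else it
        for it in instance.items
    )
    return replace(instance, items=new_items, audit=audit)


# ---------------------------------------------------------------------------
# rendering

_TEXT_WIDTH = 80


def render_instance(instance: ChecklistInstance, format: str = "text") -> str:
    """Render deterministically to ``text``, ``html`` or ``xml``."""
    if format == "text":
        return _render_text(instance)
    if format == "html":
        return _render_html(instance)
    if format == "xml":
        return render_instance_xml(instance)
    raise UnknownFormatError(f"unknown render format {format!r}")


_CHECKBOX = {
    "unchecked": "[ ]",
    "checked": "[X]",
    "auto_checked": "[x]",
    "not_applicable": "[-]",
}


def _item_line(it: ItemInstance) -> str:
    prefix = "!" if "highlight_red" in it.flags else " "
    if it.guidance_only:
        box = " - "
    else:
        box = _CHECKBOX[it.state]
    suffix = " M" if "priority_mark" in it.flags else ""
    line = f"{prefix}{box} {it.rendered_text}{suffix}"
    return line[:_TEXT_WIDTH] if len(line) > _TEXT_WIDTH else line


def _render_text(instance: ChecklistInstance) -> str:
    lines = [
        f"Checklist {instance.form_id} for patient {instance.patient_id}",
        f"instance {instance.instance_id} at t={instance.generated_at}min",
        "=" * 40,
    ]
    by_problem: dict[str, list[ItemInstance]] = {}
    for it in instance.items:
        by_problem.setdefault(it.problem_id, []).append(it)
    for pid, desc in instance.problem_order:
        lines.append(f"-- {desc or pid}")
        for it in by_problem.get(pid, []):
            lines.append(_item_line(it))
            for mat in it.supplementary:
                lines.append(f"      ({mat.kind}: {mat.payload})")
    for entry in instance.audit:
        lines.append(f"# {entry}")
    return "\n".join(lines) + "\n"


_HTML_STYLE = (
    "body{font-family:sans-serif;max-width:48em}"
    "ul{list-style:none;padding-left:0}"
    ".item--auto{color:#666;background:#eee}"
    ".item--red{color:#fff;background:#c00}"
    ".item--priority::after{content:' M';font-weight:bold}"
)


def _render_html(instance: ChecklistInstance) -> str:
    e = _html.escape
    parts = [
        "<!DOCTYPE html>",
        "<html><head><meta charset=\"utf-8\"/>",
        f"<title>{e(instance.form_id)} – {e(instance.patient_id)}</title>",
        f"<style>{_HTML_STYLE}</style></head><body>",
        f"<h1>Checklist {e(instance.form_id)}</h1>",
        f"<p>patient {e(instance.patient_id)}, instance {e(instance.instance_id)}</p>",
    ]
    by_problem: dict[str, list[ItemInstance]] = {}
    for it in instance.items:
        by_problem.setdefault(it.problem_id, []).append(it)
    for pid, desc in instance.problem_order:
        parts.append(f"<h2>{e(desc or pid)}</h2><ul>")
        for it in by_problem.get(pid, []):
            classes = ["item"]
            if it.state == "auto_checked":
                classes.append("item--auto")
            if "highlight_red" in it.flags:
                classes.append("item--red")
            if "priority_mark" in it.flags:
                classes.append("item--priority")
            box = "" if it.guidance_only else f"{_CHECKBOX[it.state]} "
            parts.append(
                f'<li class="{" ".join(classes)}" data-state="{it.state}">'
                f"{box}{e(it.rendered_text)}</li>"
            )
        parts.append("</ul>")
    parts.append("</body></html>")
    return "\n".join(parts) + "\n"


# ---------------------------------------------------------------------------
# XML round-trip

_XML_KINDS = {"number", "boolean", "text", "date"}


def render_instance_xml(instance: ChecklistInstance) -> str:
    root = etree.Element("checklist")
    root.set("instance_id", instance.instance_id)
    root.set("form_id", instance.form_id)
    root.set("patient_id", instance.patient_id)
    root.set("generated_at", str(instance.generated_at))
    by_problem: dict[str, list[ItemInstance]] = {}
    for it in instance.items:
        by_problem.setdefault(it.problem_id, []).append(it)
    for pid, desc in instance.problem_order:
        pel = etree.SubElement(root, "problem")
        pel.set("id", pid)
        pel.set("description", desc)
        for it in by_problem.get(pid, []):
            iel = etree.SubElement(pel, "item")
            iel.set("id", it.item_id)
            iel.set("state", it.state)
            iel.set("flags", " ".join(sorted(it.flags)))
            iel.set("provenance", it.provenance)
            if it.options is not None:
                iel.set("options", "|".join(it.options))
            tel = etree.SubElement(iel, "text")
            tel.text = it.rendered_text
            for slot, value in it.bound_values:
                bel = etree.SubElement(iel, "bind")
                bel.set("slot", slot)
                bel.set("kind", value_kind(value))
                bel.set("value", _xml_value(value))
            for mat in it.supplementary:
                mel = etree.SubElement(iel, "material")
                mel.set("kind", mat.kind)
                mel.set("payload", mat.payload)
    for entry in instance.audit:
        ael = etree.SubElement(root, "audit")
        ael.text = entry
    return etree.tostring(
        root, pretty_print=True, xml_declaration=True, encoding="UTF-8"
    ).decode("utf-8")


def _xml_value(v: object) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, _dt.date):
        return v.isoformat()
    return str(v)


def _parse_value(kind: str, raw: str) -> object:
    if kind == "boolean":
        return raw == "true"
    if kind == "number":
        f = float(raw)
        return int(f) if f.is_integer() and "." not in raw else f
    if kind == "date":
        return _dt.date.fromisoformat(raw)
    return raw


def parse_instance_xml(text: str | bytes) -> ChecklistInstance:
    """Inverse of :func:`render_instance_xml` (byte-stable round-trip)."""
    if isinstance(text, str):
        text = text.encode("utf-8")
    root = etree.fromstring(text)
    items: list[ItemInstance] = []
    problem_order: list[tuple[str, str]] = []
    for pel in root.findall("problem"):
        pid = pel.get("id")
        problem_order.append((pid, pel.get("description", "")))
        for iel in pel.findall("item"):
            opts = iel.get("options")
            binds = tuple(
                (b.get("slot"), _parse_value(b.get("kind"), b.get("value")))
                for b in iel.findall("bind")
            )
            mats = tuple(
                SupplementaryMaterial(kind=m.get("kind"), payload=m.get("payload"))
                for m in iel.findall("material")
            )
            items.append(
                ItemInstance(
                    item_id=iel.get("id"),
                    problem_id=pid,
                    rendered_text=iel.findtext("text") or "",
                    state=iel.get("state"),
                    flags=frozenset(f for f in iel.get("flags", "").split() if f),
                    bound_values=binds,
                    provenance=iel.get("provenance", "static"),
                    options=tuple(opts.split("|")) if opts is not None else None,
                    supplementary=mats,
                )
            )
    return ChecklistInstance(
        instance_id=root.get("instance_id"),
        form_id=root.get("form_id"),
        patient_id=root.get("patient_id"),
        generated_at=int(root.get("generated_at", "0")),
        items=tuple(items),
        problem_order=tuple(problem_order),
        audit=tuple(a.text or "" for a in root.findall("audit")),
    )
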