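"""Checklist instantiation, rendering and human check recording."""

import pytest

from dynacheck.checklist import (
    GuidancePrecheckError,
    instantiate_checklist,
    parse_instance_xml,
    record_check,
    render_instance,
)
from dynacheck.context import PatientContext
from dynacheck.errors import (
    BadOptionError,
    DanglingItemRefError,
    NoOptionsError,
    UnknownFormatError,
)
from dynacheck.rules import fire_rules


def ctx(**values):
    return PatientContext(patient_id="pat", values=values)


@pytest.fixture
def preop(pci):
    return pci.form_map()["pci_preop"]


class TestInstantiate:
    def test_reduced_lvef_adds_one_red_alert_with_bound_value(self, pci, preop):
        inst = instantiate_checklist(preop, ctx(lvef=36), pci)
        added = inst.rule_added_items()
        assert len(added) == 1
        alert = added[0]
        assert "highlight_red" in alert.flags
        assert dict(alert.bound_values) == {"lvef": 36}
        assert "36" in alert.rendered_text
        assert alert.provenance == "rule:lvef_alert"

    def test_normal_lvef_adds_nothing(self, pci, preop):
        inst = instantiate_checklist(preop, ctx(lvef=60), pci)
        assert inst.rule_added_items() == []

    def test_item_count_identity(self, pci, preop, example_patient):
        inst = instantiate_checklist(preop, example_patient, pci)
        ordered_rules = [
            pci.rule_map()[aid] for p in preop.problems for aid in p.algorithm_ids
        ]
        effects = fire_rules(ordered_rules, example_patient,
                             all_rules=pci.rules, schema=pci.schema)
        n_added = sum(1 for e in effects if e.action.kind == "add_item")
        assert len(inst.items) == len(preop.items()) + n_added

    def test_added_item_appends_within_its_problem_block(self, pci, preop):
        inst = instantiate_checklist(preop, ctx(lvef=36), pci)
        cardiac = [i for i in inst.items if i.problem_id == "cardiac_function"]
        assert cardiac[-1].item_id == "lvef_alert_item"
        # form order otherwise preserved
        assert [i.problem_id for i in inst.items] == sorted(
            [i.problem_id for i in inst.items],
            key=["cardiac_function", "renal_risk", "medication"].index,
        )

    def test_pre_check_rule_sets_auto_checked(self, pci, preop):
        inst = instantiate_checklist(preop, ctx(antiplatelet_given=True), pci)
        assert inst.item("antiplatelet_item").state == "auto_checked"

    def test_missing_binding_renders_dash_and_suppresses_autocheck(self, pci, preop):
        inst = instantiate_checklist(preop, ctx(), pci)
        assert "—" in inst.item("lvef_documented").rendered_text

    def test_contextual_monotonicity(self, pci, preop, example_patient):
        """Removing a context field never adds items (unknown never fires)."""
        full = instantiate_checklist(preop, example_patient, pci)
        for field in list(example_patient.values):
            reduced = instantiate_checklist(
                preop, example_patient.without(field), pci
            )
            assert len(reduced.items) <= len(full.items)
            added_ids = {i.item_id for i in reduced.rule_added_items()}
            assert added_ids <= {i.item_id for i in full.rule_added_items()}

    def test_dangling_effect_target(self, pci, preop):
        from dynacheck.expressions import parse_expression
        from dynacheck.model import Model
        from dynacheck.rules import Action, Rule

        bad = Rule(
            id="antiplatelet_check",  # shadow the bundled rule with a bad target
            condition=parse_expression("antiplatelet_given == true"),
            actions=(Action(kind="highlight", item_id="no_such_item", color="red"),),
        )
        rules = tuple(bad if r.id == "antiplatelet_check" else r for r in pci.rules)
        model = Model(pathway=pci.pathway, forms=pci.forms, rules=rules,
                      schema=pci.schema)
        with pytest.raises(DanglingItemRefError):
            instantiate_checklist(preop, ctx(antiplatelet_given=True), model)

    def test_precheck_of_guidance_item_rejected(self, cabg):
        from dynacheck.expressions import parse_expression
        from dynacheck.model import Model
        from dynacheck.rules import Action, Rule

        form = cabg.form_map()["anesthesia_checklist"]
        rule = Rule(
            id="bad", condition=parse_expression("diabetes == true"),
            actions=(Action(kind="pre_check", item_id="emergency_drugs"),),
        )
        problems = tuple(
            p.__class__(id=p.id, description=p.description,
                        static_items=p.static_items, algorithm_ids=("bad",))
            for p in form.problems
        )
        form2 = form.__class__(id=form.id, problems=problems, meta=form.meta)
        model = Model(pathway=cabg.pathway, forms=(form2,),
                      rules=cabg.rules + (rule,), schema=cabg.schema)
        with pytest.raises(GuidancePrecheckError):
            instantiate_checklist(form2, ctx(diabetes=True), model)


class TestRender:
    def test_text_prefixes_and_marks(self, pci, preop, example_patient):
        text = render_instance(
            instantiate_checklist(preop, example_patient, pci), "text"
        )
        lines = text.splitlines()
        # red alert gets the "!" prefix; high priority ends with " M"
        alert = next(l for l in lines if "evaluate cardiac function" in l)
        assert alert.startswith("!") and alert.endswith(" M")
        # auto-checked medication item rendered as [x]
        auto = next(l for l in lines if "antiplatelet" in l.lower())
        assert auto.lstrip().startswith("[x]")
        # an untouched item keeps the plain checkbox
        plain = next(l for l in lines if "hydration plan" in l)
        assert plain == " [ ] Peri-procedural hydration plan in place"

    def test_html_semantic_classes(self, pci, preop, example_patient):
        html = render_instance(
            instantiate_checklist(preop, example_patient, pci), "html"
        )
        assert "item--red" in html and "item--auto" in html and "item--priority" in html

    def test_render_is_deterministic(self, pci, preop, example_patient):
        inst = instantiate_checklist(preop, example_patient, pci)
        for fmt in ("text", "html", "xml"):
            assert render_instance(inst, fmt) == render_instance(inst, fmt)

    def test_unknown_format(self, pci, preop, example_patient):
        inst = instantiate_checklist(preop, example_patient, pci)
        with pytest.raises(UnknownFormatError):
            render_instance(inst, "pdf")

    def test_xml_round_trip_is_byte_identical(self, pci, preop, example_patient):
        inst = instantiate_checklist(preop, example_patient, pci)
        xml = render_instance(inst, "xml")
        assert render_instance(parse_instance_xml(xml), "xml") == xml

    def test_xml_validates_against_shipped_schema(self, pci, preop, example_patient):
        from importlib import resources

        from lxml import etree

        xsd_path = resources.files("dynacheck.schemas") / "checklist-instance.xsd"
        xsd = etree.XMLSchema(etree.fromstring(xsd_path.read_bytes()))
        xml = render_instance(instantiate_checklist(preop, example_patient, pci), "xml")
        xsd.assertValid(etree.fromstring(xml.encode()))


class TestRecordCheck:
    def test_check_transition(self, pci, preop):
        inst = instantiate_checklist(preop, ctx(lvef=60), pci)
        inst = record_check(inst, "hydration_plan", "dr_a", "yes")
        assert inst.item("hydration_plan").state == "checked"

    def test_not_applicable(self, pci, preop):
        inst = instantiate_checklist(preop, ctx(lvef=60), pci)
        inst = record_check(inst, "hydration_plan", "dr_a", "not_applicable")
        assert inst.item("hydration_plan").state == "not_applicable"

    def test_guidance_item_refuses_options(self, cabg):
        form = cabg.form_map()["anesthesia_checklist"]
        inst = instantiate_checklist(form, ctx(), cabg)
        with pytest.raises(NoOptionsError):
            record_check(inst, "emergency_drugs", "dr_a", "yes")

    def test_bad_option(self, pci, preop):
        inst = instantiate_checklist(preop, ctx(lvef=60), pci)
        with pytest.raises(BadOptionError):
            record_check(inst, "hydration_plan", "dr_a", "maybe")

    def test_override_of_auto_check_is_logged(self, pci, preop):
        inst = instantiate_checklist(preop, ctx(antiplatelet_given=True), pci)
        assert inst.item("antiplatelet_item").state == "auto_checked"
        inst = record_check(inst, "antiplatelet_item", "dr_a", "no")
        assert inst.item("antiplatelet_item").state == "checked"
        assert any("override" in entry for entry in inst.audit)
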