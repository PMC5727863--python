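"""BPMN subset mapping: importer branches, strict mode, round-trips."""

import numpy as np
import pytest

from dynacheck.bpmn import BPMN_NS, export_bpmn, import_bpmn
from dynacheck.errors import UnsupportedElementError
from dynacheck.model import AdHocBlock, GatewayNode

from _helpers import assert_pathway_isomorphic, random_structured_pathway


def bpmn_doc(body: str) -> str:
    return (
        f'<definitions xmlns="{BPMN_NS}" targetNamespace="urn:test" id="defs">'
        f"<process id=\"proc\">{body}</process></definitions>"
    )


SEQUENTIAL = bpmn_doc(
    '<startEvent id="s"/><endEvent id="e"/>'
    '<userTask id="t1" name="first"/><userTask id="t2" name="second"/>'
    '<sequenceFlow id="f1" sourceRef="s" targetRef="t1"/>'
    '<sequenceFlow id="f2" sourceRef="t1" targetRef="t2"/>'
    '<sequenceFlow id="f3" sourceRef="t2" targetRef="e"/>'
)


class TestImport:
    def test_two_user_tasks_one_flow_is_sequential(self):
        pathway, _ = import_bpmn(SEQUENTIAL)
        tasks = pathway.tasks()
        assert [t.id for t in tasks] == ["t1", "t2"]
        assert {(e.source_id, e.target_id) for e in pathway.edges} >= {("t1", "t2")}

    def test_parallel_gateways_mapped_by_degree(self):
        doc = bpmn_doc(
            '<startEvent id="s"/><endEvent id="e"/>'
            '<parallelGateway id="g1"/><parallelGateway id="g2"/>'
            '<userTask id="a" name="a"/><userTask id="b" name="b"/>'
            '<sequenceFlow id="f1" sourceRef="s" targetRef="g1"/>'
            '<sequenceFlow id="f2" sourceRef="g1" targetRef="a"/>'
            '<sequenceFlow id="f3" sourceRef="g1" targetRef="b"/>'
            '<sequenceFlow id="f4" sourceRef="a" targetRef="g2"/>'
            '<sequenceFlow id="f5" sourceRef="b" targetRef="g2"/>'
            '<sequenceFlow id="f6" sourceRef="g2" targetRef="e"/>'
        )
        pathway, report = import_bpmn(doc)
        kinds = {
            n.id: n.kind for n in pathway.nodes if isinstance(n, GatewayNode)
        }
        assert kinds == {"g1": "parallel_split", "g2": "parallel_join"}
        assert report.ok or all(c == "NO_ROLE" for c in report.codes())

    def test_condition_expression_read_with_native_grammar(self):
        doc = bpmn_doc(
            '<startEvent id="s"/><endEvent id="e"/>'
            '<exclusiveGateway id="x" default="f3"/>'
            '<userTask id="a" name="a"/><userTask id="b" name="b"/>'
            '<exclusiveGateway id="m"/>'
            '<sequenceFlow id="f1" sourceRef="s" targetRef="x"/>'
            '<sequenceFlow id="f2" sourceRef="x" targetRef="a">'
            "<conditionExpression>lvef &lt; 50</conditionExpression></sequenceFlow>"
            '<sequenceFlow id="f3" sourceRef="x" targetRef="b"/>'
            '<sequenceFlow id="f4" sourceRef="a" targetRef="m"/>'
            '<sequenceFlow id="f5" sourceRef="b" targetRef="m"/>'
            '<sequenceFlow id="f6" sourceRef="m" targetRef="e"/>'
        )
        pathway, _ = import_bpmn(doc)
        split = pathway.node_map()["x"]
        assert split.kind == "exclusive_split"
        assert split.default_edge_id == "f3"
        (edge_id, expr), = split.branch_conditions
        assert edge_id == "f2" and expr.to_text() == "lvef < 50"

    def test_adhoc_subprocess_membership(self):
        doc = bpmn_doc(
            '<startEvent id="s"/><endEvent id="e"/>'
            '<adHocSubProcess id="ah">'
            '<userTask id="m1" name="m1"/><userTask id="m2" name="m2"/>'
            "</adHocSubProcess>"
            '<sequenceFlow id="f1" sourceRef="s" targetRef="ah"/>'
            '<sequenceFlow id="f2" sourceRef="ah" targetRef="e"/>'
        )
        pathway, _ = import_bpmn(doc)
        block = pathway.node_map()["ah"]
        assert isinstance(block, AdHocBlock)
        assert block.task_ids == {"m1", "m2"} == block.mandatory_task_ids

    def test_lane_assigns_roles(self):
        doc = bpmn_doc(
            '<laneSet id="ls"><lane id="lane_nurse" name="Nurse">'
            "<flowNodeRef>t1</flowNodeRef><flowNodeRef>t2</flowNodeRef>"
            "</lane></laneSet>" + SEQUENTIAL.split("<process id=\"proc\">")[1]
            .rsplit("</process>")[0]
        )
        pathway, report = import_bpmn(doc)
        assert report.ok
        assert all(t.role_ids == {"nurse"} for t in pathway.tasks())

    def test_script_task_rejected_in_strict_mode(self):
        doc = bpmn_doc(SEQUENTIAL.split("<process id=\"proc\">")[1]
                       .rsplit("</process>")[0] + '<scriptTask id="hack"/>')
        with pytest.raises(UnsupportedElementError) as err:
            import_bpmn(doc, strict=True)
        assert "hack" in str(err.value)

    def test_script_task_skipped_with_warning_in_lenient_mode(self):
        doc = bpmn_doc(SEQUENTIAL.split("<process id=\"proc\">")[1]
                       .rsplit("</process>")[0] + '<scriptTask id="hack"/>')
        pathway, report = import_bpmn(doc, strict=False)
        assert "hack" not in pathway.node_map()
        assert any(c == "UNSUPPORTED_ELEMENT" for c, _, _ in report.warnings)


class TestExport:
    def test_cabg_export_contains_nineteen_user_tasks(self, cabg):
        xml = export_bpmn(cabg.pathway)
        assert xml.count(b"<userTask") == 19

    def test_fixture_round_trips_are_isomorphic(self, cabg, pci):
        for model in (cabg, pci):
            reimported, report = import_bpmn(export_bpmn(model.pathway))
            assert report.ok
            assert_pathway_isomorphic(model.pathway, reimported)

    def test_adhoc_round_trip_preserves_membership(self, pci):
        reimported, _ = import_bpmn(export_bpmn(pci.pathway))
        block = reimported.node_map()["postop_observation"]
        original = pci.pathway.node_map()["postop_observation"]
        assert block.task_ids == original.task_ids
        assert block.mandatory_task_ids == original.mandatory_task_ids

    def test_guard_bindings_survive_extension_round_trip(self, pci):
        reimported, _ = import_bpmn(export_bpmn(pci.pathway))
        guards = reimported.node_map()["perform_pci"].guards
        assert len(guards) == 1
        assert guards[0].trigger.kind == "on_entry"
        assert guards[0].form_id == "pci_timeout"
        assert guards[0].guards[0].form_id == "pci_signout"
        assert guards[0].guards[0].trigger.kind == "on_exit"

    def test_random_structured_pathways_round_trip(self):
        rng = np.random.default_rng(42)
        for _ in range(40):
            pathway = random_structured_pathway(rng).pathway
            reimported, report = import_bpmn(export_bpmn(pathway))
            assert report.ok, str(report)
            assert_pathway_isomorphic(pathway, reimported)

    def test_shipped_bpmn_exports_match_the_bundles(self, cabg, pci):
        from dynacheck.fixtures import fixture_bpmn

        for name, model in (("cabg", cabg), ("pci", pci)):
            pathway, report = import_bpmn(fixture_bpmn(name))
            assert report.ok
            assert_pathway_isomorphic(model.pathway, pathway)
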