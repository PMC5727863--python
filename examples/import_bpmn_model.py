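"""Round-trip a pathway through BPMN 2.0 XML.

Clinical tasks become userTask elements, roles become lanes, gateways map
by kind and degree, and the concepts BPMN lacks (triggers, guard bindings,
ad-hoc mandatory sets) travel in extensionElements under the package's own
namespace — so export -> import is graph-isomorphic.
"""

from dynacheck import export_bpmn, import_bpmn, pci_fixture

model = pci_fixture()
xml = export_bpmn(model.pathway)
print(f"exported {len(xml)} bytes of BPMN; first lines:")
print("\n".join(xml.decode().splitlines()[:6]))

reimported, report = import_bpmn(xml, strict=True)
print(f"\nreimport valid: {report.ok}")
print(f"nodes preserved: {sorted(n.id for n in reimported.nodes) == sorted(n.id for n in model.pathway.nodes)}")
guard = reimported.node_map()["perform_pci"].guards[0]
print(f"guard survived the extension round-trip: form={guard.form_id}, "
      f"trigger={guard.trigger.kind}, nested={len(guard.guards)}")
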