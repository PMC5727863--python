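# Native model bundle, schema version 1.
#
# A bundle is a directory:
#   pathway.yaml     - the care pathway (one document, top key `pathway`)
#   forms/*.yaml     - checklist forms (one per file, top key `form`)
#   rules/*.rules    - situation-action rules in the WHEN/THEN DSL
#   schema.yaml      - patient-context field catalogue (top key `schema`)
#
# `allowed_keys` below is normative: loaders reject any mapping key not
# listed for its section (SCHEMA_VIOLATION with a pointer path).
version: 1
allowed_keys:
  pathway_doc: [pathway]
  pathway: [id, meta, roles, nodes, edges, start, end]
  meta: [title, author, version, created]
  role: [id, name]
  node: [id, kind, name, roles, guards, conditions, default_edge, tasks, mandatory]
  guard: [trigger, form, roles, blocking, guards]
  trigger: [kind, after]
  condition: [edge, when]
  edge: [id, from, to]
  form_doc: [form]
  form: [id, meta, problems]
  problem: [id, description, algorithms, items]
  item: [id, text, options, priority, pre_checked, supplementary]
  material: [kind, payload]
  schema_doc: [schema]
  schema: [fields]
  field: [name, type, description]
node_kinds:
  - task
  - start
  - end
  - parallel_split
  - parallel_join
  - exclusive_split
  - exclusive_merge
  - inclusive_split
  - inclusive_join
  - ad_hoc
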