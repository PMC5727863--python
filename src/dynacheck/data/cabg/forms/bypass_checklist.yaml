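form:
  id: bypass_checklist
  meta:
    title: Bypass circuit readiness
    author: dynacheck
    version: '1.0'
    created: '2024-01-15'
  problems:
  - id: bypass_prep
    description: Bypass circuit readiness
    items:
    - id: circuit_primed
      text: Circuit primed and de-aired
    - id: backup_oxygenator
      text: Backup oxygenator available
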