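schema:
  fields:
  - name: lvef
    type: number
    description: left ventricular ejection fraction, %
  - name: renal_insufficiency
    type: boolean
    description: renal insufficiency diagnosed
  - name: antiplatelet_given
    type: boolean
    description: dual antiplatelet therapy given
  - name: contrast_allergy
    type: boolean
    description: known contrast allergy
  - name: age
    type: number
    description: age, years
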