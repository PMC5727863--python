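schema:
  fields:
  - name: complication
    type: boolean
    description: post-operative complication present
  - name: renal_insufficiency
    type: boolean
    description: renal insufficiency diagnosed
  - name: diabetes
    type: boolean
    description: diabetes mellitus
  - name: blood_crossmatch_done
    type: boolean
    description: cross-typing samples taken
  - name: hemoglobin
    type: number
    description: hemoglobin, g/dL
  - name: age
    type: number
    description: age, years
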