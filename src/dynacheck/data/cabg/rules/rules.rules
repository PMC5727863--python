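RULE renal_alert FOR preop_risk
WHEN renal_insufficiency == true
THEN add_item "Renal insufficiency noticed"
  AND highlight renal_alert_item red

RULE crossmatch_check FOR admission
WHEN blood_crossmatch_done == true
THEN pre_check crossmatch_item

RULE diabetes_screen FOR preop_risk
WHEN diabetes == true
THEN invoke_rule glucose_protocol

RULE glucose_protocol FOR preop_risk
WHEN diabetes == true
THEN add_item glucose_item "Start peri-operative glucose protocol" priority high
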