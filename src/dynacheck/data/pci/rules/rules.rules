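RULE lvef_alert FOR cardiac_function
WHEN lvef < 50
THEN add_item "LVEF {lvef}: evaluate cardiac function before intervention" priority high
  AND highlight lvef_alert_item red

RULE renal_alert FOR renal_risk
WHEN renal_insufficiency == true
THEN add_item "Renal insufficiency noticed"
  AND highlight renal_alert_item red

RULE antiplatelet_check FOR medication
WHEN antiplatelet_given == true
THEN pre_check antiplatelet_item
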