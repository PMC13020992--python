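# Default triangle-completion outbound design: 7 shapes chosen to span a
# wide range of ideal inbound turn angles and distances (replaceable;
# mirror left/right versions are generated automatically).
# Each shape is presented 4 times per environment (2 left, 2 right).
repetitions: 4
shapes:
  - {shape_id: S1, leg1_deg: 30, mid_turn_deg: 60,  leg2_deg: 30}
  - {shape_id: S2, leg1_deg: 50, mid_turn_deg: 60,  leg2_deg: 70}
  - {shape_id: S3, leg1_deg: 50, mid_turn_deg: 90,  leg2_deg: 50}
  - {shape_id: S4, leg1_deg: 70, mid_turn_deg: 90,  leg2_deg: 30}
  - {shape_id: S5, leg1_deg: 70, mid_turn_deg: 120, leg2_deg: 70}
  - {shape_id: S6, leg1_deg: 90, mid_turn_deg: 90,  leg2_deg: 90}
  - {shape_id: S7, leg1_deg: 90, mid_turn_deg: 120, leg2_deg: 50}
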