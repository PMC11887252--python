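# Default 16-view examination protocol (ASE-ordered subset).
#
# Each view lists the control state that ideally attains it
# (depth cm; rotation, ante_retro, left_right, omniplane deg),
# per-landmark tolerance limits L1..L3 (cm) and the in-plane offsets
# (u, v in cm along the two in-plane axes) of the three expert landmark
# points P1..P3 relative to the transducer tip.  Landmark coordinates are
# synthetic: they are generated through the forward kinematic model at the
# target state, which guarantees a perfectly positioned plane scores 1.0.
views:
  - {view_id: 1,  view_name: "ME 5-chamber",          target_state: {depth: 29.0, rotation: 0.0,   ante_retro: 5.0,  left_right: 0.0, omniplane: 0.0},   tolerances: [0.8, 0.8, 0.8], ref_offsets: [[4.0, 1.0], [-3.0, 2.5], [2.0, -3.0]]}
  - {view_id: 2,  view_name: "ME 4-chamber",          target_state: {depth: 30.0, rotation: 0.0,   ante_retro: 0.0,  left_right: 0.0, omniplane: 0.0},   tolerances: [0.8, 0.8, 0.8], ref_offsets: [[4.0, 1.0], [-3.0, 2.5], [2.0, -3.0]]}
  - {view_id: 3,  view_name: "ME Mitral Commissural", target_state: {depth: 30.0, rotation: 0.0,   ante_retro: 0.0,  left_right: 0.0, omniplane: 60.0},  tolerances: [0.8, 0.8, 0.8], ref_offsets: [[4.0, 1.0], [-3.0, 2.5], [2.0, -3.0]]}
  - {view_id: 4,  view_name: "ME Mitral 2-chamber",   target_state: {depth: 30.0, rotation: 0.0,   ante_retro: 0.0,  left_right: 0.0, omniplane: 90.0},  tolerances: [0.8, 0.8, 0.8], ref_offsets: [[4.0, 1.0], [-3.0, 2.5], [2.0, -3.0]]}
  - {view_id: 5,  view_name: "ME Mitral LAX",         target_state: {depth: 30.0, rotation: 0.0,   ante_retro: 0.0,  left_right: 0.0, omniplane: 135.0}, tolerances: [0.8, 0.8, 0.8], ref_offsets: [[4.0, 1.0], [-3.0, 2.5], [2.0, -3.0]]}
  - {view_id: 6,  view_name: "ME AV LAX",             target_state: {depth: 28.0, rotation: 0.0,   ante_retro: 5.0,  left_right: 0.0, omniplane: 120.0}, tolerances: [0.8, 0.8, 0.8], ref_offsets: [[4.0, 1.0], [-3.0, 2.5], [2.0, -3.0]]}
  - {view_id: 7,  view_name: "ME Asc Ao LAX",         target_state: {depth: 26.0, rotation: 0.0,   ante_retro: 0.0,  left_right: 0.0, omniplane: 100.0}, tolerances: [0.8, 0.8, 0.8], ref_offsets: [[4.0, 1.0], [-3.0, 2.5], [2.0, -3.0]]}
  - {view_id: 8,  view_name: "ME Asc Ao SAX",         target_state: {depth: 26.0, rotation: 0.0,   ante_retro: 0.0,  left_right: 0.0, omniplane: 30.0},  tolerances: [0.8, 0.8, 0.8], ref_offsets: [[4.0, 1.0], [-3.0, 2.5], [2.0, -3.0]]}
  - {view_id: 9,  view_name: "RV inflow-outflow",     target_state: {depth: 29.0, rotation: 15.0,  ante_retro: 0.0,  left_right: 0.0, omniplane: 60.0},  tolerances: [0.8, 0.8, 0.8], ref_offsets: [[4.0, 1.0], [-3.0, 2.5], [2.0, -3.0]]}
  - {view_id: 10, view_name: "ME AV SAX",             target_state: {depth: 28.0, rotation: 0.0,   ante_retro: 5.0,  left_right: 0.0, omniplane: 30.0},  tolerances: [0.8, 0.8, 0.8], ref_offsets: [[4.0, 1.0], [-3.0, 2.5], [2.0, -3.0]]}
  - {view_id: 11, view_name: "ME Bicaval",            target_state: {depth: 29.0, rotation: 45.0,  ante_retro: 0.0,  left_right: 0.0, omniplane: 110.0}, tolerances: [0.8, 0.8, 0.8], ref_offsets: [[4.0, 1.0], [-3.0, 2.5], [2.0, -3.0]]}
  - {view_id: 12, view_name: "TG Basal SAX",          target_state: {depth: 42.0, rotation: 0.0,   ante_retro: 15.0, left_right: 0.0, omniplane: 0.0},   tolerances: [0.8, 0.8, 0.8], ref_offsets: [[4.0, 1.0], [-3.0, 2.5], [2.0, -3.0]]}
  - {view_id: 13, view_name: "TG mid-papillary SAX",  target_state: {depth: 44.0, rotation: 0.0,   ante_retro: 10.0, left_right: 0.0, omniplane: 0.0},   tolerances: [0.8, 0.8, 0.8], ref_offsets: [[4.0, 1.0], [-3.0, 2.5], [2.0, -3.0]]}
  - {view_id: 14, view_name: "TG 2-chamber",          target_state: {depth: 44.0, rotation: 0.0,   ante_retro: 10.0, left_right: 0.0, omniplane: 90.0},  tolerances: [0.8, 0.8, 0.8], ref_offsets: [[4.0, 1.0], [-3.0, 2.5], [2.0, -3.0]]}
  - {view_id: 15, view_name: "Desc Ao SAX",           target_state: {depth: 35.0, rotation: 180.0, ante_retro: 0.0,  left_right: 0.0, omniplane: 0.0},   tolerances: [0.8, 0.8, 0.8], ref_offsets: [[4.0, 1.0], [-3.0, 2.5], [2.0, -3.0]]}
  - {view_id: 16, view_name: "Desc Ao LAX",           target_state: {depth: 35.0, rotation: 180.0, ante_retro: 0.0,  left_right: 0.0, omniplane: 90.0},  tolerances: [0.8, 0.8, 0.8], ref_offsets: [[4.0, 1.0], [-3.0, 2.5], [2.0, -3.0]]}
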