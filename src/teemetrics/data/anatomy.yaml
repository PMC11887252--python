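# Default esophagus centerline: a gentle thoracic curve (cm).
# Depth is arc length from the first point (mouth end).
control_points:
  - [0.0, 0.0, 0.0]
  - [0.6, 0.2, 12.0]
  - [1.6, 0.6, 24.0]
  - [2.6, 1.4, 36.0]
  - [2.9, 2.4, 48.0]
  - [2.2, 3.2, 62.0]
depth_range: [20.0, 50.0]
max_depth_perforation: 55.0
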