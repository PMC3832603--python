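{
  "camera": "Canon 40D",
  "channel": "red",
  "bit_depth": 8,
  "g_max": 250.0,
  "p_min": 31.0,
  "e_max_umol": 0.0122,
  "biexp": {
    "b": 103.0,
    "c": 3640.0,
    "d": 157.0,
    "g": 981.0,
    "ci_halfwidths": {"b": 34.0, "c": 960.0, "d": 33.0, "g": 159.0}
  },
  "bezier": {
    "x": [0.0109, 0.0131, 0.0274, 0.0187],
    "y": [0.220, 0.273, 0.866, 0.962],
    "ci_x": [0.000191, 0.000519, 0.00107, 0.00130],
    "ci_y": [0.00385, 0.00610, 0.00355, 0.00109]
  }
}
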