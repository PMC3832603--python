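{
  "camera": "Canon 40D",
  "channel": "blue",
  "bit_depth": 8,
  "g_max": 250.0,
  "p_min": 31.0,
  "e_max_umol": 0.0124,
  "biexp": {
    "b": 75.8,
    "c": 5240.0,
    "d": 179.0,
    "g": 1065.0,
    "ci_halfwidths": {"b": 19.0, "c": 1460.0, "d": 20.0, "g": 110.0}
  },
  "bezier": {
    "x": [0.0125, 0.0145, 0.0540, 0.233],
    "y": [0.218, 0.311, 0.828, 0.942],
    "ci_x": [0.000249, 0.000846, 0.00186, 0.00167],
    "ci_y": [0.00365, 0.00561, 0.00329, 0.00105]
  }
}
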