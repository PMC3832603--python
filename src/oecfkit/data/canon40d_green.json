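{
  "camera": "Canon 40D",
  "channel": "green",
  "bit_depth": 8,
  "g_max": 250.0,
  "p_min": 31.0,
  "e_max_umol": 0.0125,
  "biexp": {
    "b": 85.5,
    "c": 4200.0,
    "d": 172.0,
    "g": 961.0,
    "ci_halfwidths": {"b": 21.0, "c": 1000.0, "d": 22.0, "g": 99.0}
  },
  "bezier": {
    "x": [0.0121, 0.0118, 0.0468, 0.196],
    "y": [0.229, 0.302, 0.834, 0.940],
    "ci_x": [0.000240, 0.000515, 0.000935, 0.000561],
    "ci_y": [0.00403, 0.00600, 0.00351, 0.000544]
  }
}
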