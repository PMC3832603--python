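{
  "camera": "Nikon D70s (UV-modified)",
  "channel": "red-UV",
  "bit_depth": 8,
  "g_max": 250.0,
  "p_min": 37.0,
  "e_max_umol": 0.0081,
  "biexp": {
    "b": 248.0,
    "c": 1540.0,
    "d": 12.0,
    "g": 14700.0,
    "ci_halfwidths": {"b": 16.0, "c": 20.0, "d": 13.0, "g": 27300.0}
  },
  "bezier": {
    "x": [0.0202, 0.0370, 0.0704, 0.237],
    "y": [0.240, 0.321, 0.865, 0.958],
    "ci_x": [0.000461, 0.00151, 0.00349, 0.00320],
    "ci_y": [0.00466, 0.00734, 0.00383, 0.00252]
  }
}
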