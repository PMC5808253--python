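[
  {"thetaX": 0, "thetaY": 0, "shape": "cross", "span": 3, "barWidth": 2,
   "magnitude": 0.2, "tOn": 0.0, "tOff": 0.4},
  {"thetaX": 0, "thetaY": -10, "shape": "cross", "span": 3, "barWidth": 2,
   "magnitude": 0.3, "tOn": 0.4}
]
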