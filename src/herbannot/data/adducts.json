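[
  {"name": "[M-H]-",      "polarity": "negative", "gain": "",       "loss": "H", "electrons": 1,  "charge": 1},
  {"name": "[M+HCOO]-",   "polarity": "negative", "gain": "CHO2",   "loss": "",  "electrons": 1,  "charge": 1},
  {"name": "[M+CH3COO]-", "polarity": "negative", "gain": "C2H3O2", "loss": "",  "electrons": 1,  "charge": 1},
  {"name": "[M+Cl]-",     "polarity": "negative", "gain": "Cl",     "loss": "",  "electrons": 1,  "charge": 1},
  {"name": "[M+e]-",      "polarity": "negative", "gain": "",       "loss": "",  "electrons": 1,  "charge": 1},
  {"name": "[M+H]+",      "polarity": "positive", "gain": "H",      "loss": "",  "electrons": -1, "charge": 1},
  {"name": "[M+Na]+",     "polarity": "positive", "gain": "Na",     "loss": "",  "electrons": -1, "charge": 1},
  {"name": "[M-e]+",      "polarity": "positive", "gain": "",       "loss": "",  "electrons": -1, "charge": 1}
]
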