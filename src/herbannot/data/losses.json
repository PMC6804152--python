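[
  {"name": "Glc",       "formula": "C6H10O5", "role": "sugar"},
  {"name": "Rha",       "formula": "C6H10O4", "role": "sugar"},
  {"name": "GlurA",     "formula": "C6H8O6",  "role": "sugar"},
  {"name": "Pen",       "formula": "C5H8O4",  "role": "sugar"},
  {"name": "malonyl",   "formula": "C3H2O3",  "role": "acyl"},
  {"name": "acetyl",    "formula": "C2H2O",   "role": "acyl"},
  {"name": "H2O",       "formula": "H2O",     "role": "small"},
  {"name": "CO2",       "formula": "CO2",     "role": "small"},
  {"name": "HCOOH",     "formula": "CH2O2",   "role": "small"},
  {"name": "CH3COOH",   "formula": "C2H4O2",  "role": "small"},
  {"name": "CO",        "formula": "CO",      "role": "small"},
  {"name": "CH4",       "formula": "CH4",     "role": "small"},
  {"name": "CH3OH",     "formula": "CH4O",    "role": "small"},
  {"name": "CH3",       "formula": "CH3",     "role": "small"},
  {"name": "C6H12",     "formula": "C6H12",   "role": "side-chain"},
  {"name": "danshensu", "formula": "C9H10O5", "role": "acid-unit"},
  {"name": "caffeoyl",  "formula": "C9H8O4",  "role": "acid-unit"},
  {"name": "feruloyl",  "formula": "C10H8O3", "role": "acid-unit"},
  {"name": "coumaroyl", "formula": "C9H6O2",  "role": "acid-unit"},
  {"name": "cinnamoyl", "formula": "C9H6O",   "role": "acid-unit"}
]
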