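{
 "shared": [
  "hv",
  "CO2",
  "NO3",
  "Pi",
  "NH3",
  "Ac",
  "GLYC",
  "SO4",
  "H2S"
 ],
 "env_exchange": {
  "hv": [
   -1.03,
   0.0
  ],
  "CO2": [
   -1000.0,
   1000.0
  ],
  "NO3": [
   -1.0,
   1000.0
  ],
  "Pi": [
   -1.0,
   1000.0
  ],
  "NH3": [
   0.0,
   1000.0
  ],
  "Ac": [
   0.0,
   1000.0
  ],
  "GLYC": [
   0.0,
   1000.0
  ],
  "SO4": [
   -1000.0,
   1000.0
  ],
  "H2S": [
   0.0,
   1000.0
  ]
 }
}
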