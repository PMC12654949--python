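{
 "pairs": [
  {"nt1": "A.G3", "nt2": "A.C22", "name": "WC", "LW": "cWW"},
  {"nt1": "A.G4", "nt2": "A.U21", "name": "Wobble", "LW": "cWW"},
  {"nt1": "A.A7", "nt2": "A.U16", "name": "Hoogsteen", "LW": "tHW"}
 ]
}
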