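{
  "alias_map": {
    "mre11": "mre11a"
  },
  "ortholog_map": {
    "banp": ["banp"],
    "cd22": ["cd22"],
    "eif2b3": ["eif2b3"],
    "ghitm": ["ghitm"],
    "hbb-b1": ["hbbl"],
    "mre11a": ["mre11a"],
    "nr4a3": ["nr4a3"],
    "orai1": ["orai1"],
    "sh3bgr": ["sh3bgr"],
    "shox2": ["shox2"],
    "spint1": ["spint1"]
  },
  "family_map": {
    "defb17": "defb",
    "defb1": "defb",
    "fcgr3a": "fcgr3",
    "fcgr3b": "fcgr3",
    "fcrl2": "fcrl",
    "fcrl1": "fcrl",
    "hbb-b1": "hb",
    "hbbl": "hb",
    "hba1": "hb",
    "hbad": "hb",
    "hbm": "hb",
    "hbz1": "hb",
    "hspa1b": "hspa",
    "hspa5": "hspa",
    "hspa8": "hspa",
    "ifi27l2b": "ifi",
    "ifi6": "ifi",
    "krt2": "krt",
    "krt17": "krt",
    "liph": "lip",
    "lipa": "lip",
    "lipm": "lip",
    "lipml": "lip",
    "mogat2": "mogat",
    "mogat1": "mogat",
    "morn1": "morn",
    "morn2": "morn",
    "nr4a3": "nr",
    "nr2c1": "nr",
    "nr3c1": "nr",
    "nr5a1": "nr",
    "p2rx4": "p2rx",
    "p2rx6": "p2rx",
    "pcdhb9": "pcdh",
    "pcdh20": "pcdh",
    "pcdhac1": "pcdh",
    "pcdhb15": "pcdh",
    "pcdhga1": "pcdh",
    "pcdhgb4": "pcdh",
    "pla2g2c": "pla",
    "pla1a": "pla",
    "pla2g4a": "pla",
    "pla2g4c": "pla",
    "pla2g5": "pla",
    "pla2g7": "pla",
    "rbm3": "rbm",
    "rbm11": "rbm",
    "tpm2": "tpm",
    "tpm4": "tpm",
    "plac8": "plac8",
    "ifi47": "ifi47",
    "shox2": "shox2",
    "sh3bgr": "sh3bgr",
    "fus": "fus",
    "fuca1": "fuca1"
  }
}
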