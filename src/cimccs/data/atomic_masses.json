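{
  "version": "CODATA-2018/AME-2020 monoisotopic masses, Da",
  "masses": {
    "H": 1.00782503207,
    "Li": 7.01600455,
    "B": 11.0093054,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "F": 18.99840322,
    "Na": 22.9897692809,
    "Mg": 23.9850417,
    "Si": 27.9769265325,
    "P": 30.97376163,
    "S": 31.97207100,
    "Cl": 34.96885268,
    "K": 38.96370668,
    "Ca": 39.96259098,
    "Fe": 55.9349375,
    "Se": 73.9224764,
    "Br": 78.9183371,
    "I": 126.904473
  }
}
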