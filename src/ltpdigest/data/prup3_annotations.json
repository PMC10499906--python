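{
  "accession": "Q9LED1",
  "label": "Pru p 3.0102",
  "numbering_origin": 1,
  "epitopes": [
    {"label": "A11-G20", "start": 11, "end": 20},
    {"label": "I31-T40", "start": 31, "end": 40},
    {"label": "G71-K80", "start": 71, "end": 80}
  ],
  "disulphide_pairs": [[3, 50], [13, 27], [28, 73], [48, 87]],
  "phosphoserines": [55, 57, 82]
}
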