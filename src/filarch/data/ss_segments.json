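{
  "_comment": "Editable segment annotation table: protein -> {segment: [first_residue, last_residue]} in author numbering. 'toy6' matches the default coarse-grained six-helix protomer from filarch.synthetic. 'PYD_template' is a generic ~93-residue death-fold layout shipped as a starting point only - edit the ranges to your protein's actual helix boundaries before interface typing on real models.",
  "toy6": {
    "h1": [1, 13],
    "loop_h1h2": [14, 15],
    "h2": [16, 28],
    "loop_h2h3": [29, 30],
    "h3": [31, 43],
    "loop_h3h4": [44, 45],
    "h4": [46, 58],
    "loop_h4h5": [59, 60],
    "h5": [61, 73],
    "loop_h5h6": [74, 75],
    "h6": [76, 88]
  },
  "PYD_template": {
    "h1": [3, 14],
    "loop_h1h2": [15, 16],
    "h2": [17, 28],
    "loop_h2h3": [29, 40],
    "h3": [41, 46],
    "loop_h3h4": [47, 48],
    "h4": [49, 58],
    "loop_h4h5": [59, 61],
    "h5": [62, 74],
    "loop_h5h6": [75, 79],
    "h6": [80, 91]
  }
}
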