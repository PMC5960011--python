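{
  "scheme": {
    "A": ["N", "S"],
    "Ap": ["E", "W"],
    "B": ["NE", "SW"],
    "Bp": ["SE", "NW"]
  },
  "n_participants": 85,
  "p": {
    "AB": [[0.095, 0.405], [0.405, 0.095]],
    "ABp": [[0.405, 0.095], [0.095, 0.405]],
    "ApB": [[0.095, 0.405], [0.405, 0.095]],
    "ApBp": [[0.095, 0.405], [0.405, 0.095]]
  }
}
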