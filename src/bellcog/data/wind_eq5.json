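{
  "scheme": {
    "A": ["N", "S"],
    "Ap": ["E", "W"],
    "B": ["NE", "SW"],
    "Bp": ["SE", "NW"]
  },
  "n_participants": 85,
  "p": {
    "AB": [[0.10, 0.40], [0.40, 0.10]],
    "ABp": [[0.41, 0.09], [0.09, 0.41]],
    "ApB": [[0.10, 0.40], [0.40, 0.10]],
    "ApBp": [[0.09, 0.41], [0.41, 0.09]]
  }
}
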