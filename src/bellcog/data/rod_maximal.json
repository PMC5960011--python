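{
  "comment": "Rigid-rod configuration attaining |S| = 4: minimal admissible symmetric bands (epsilon = sqrt(2)/2, d = 0) at the maximal-violation coplanar angle set.",
  "epsilon": 0.7071067811865476,
  "d": 0.0,
  "order_policy": "uniform-mix",
  "orientations": {
    "A": 0.0,
    "B": 0.7853981633974483,
    "Ap": 1.5707963267948966,
    "Bp": 2.356194490192345
  }
}
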