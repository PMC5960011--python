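measurement,i,j,probability
AB,1,1,0.13
AB,1,2,0.55
AB,2,1,0.25
AB,2,2,0.07
ABp,1,1,0.47
ABp,1,2,0.12
ABp,2,1,0.06
ABp,2,2,0.35
ApB,1,1,0.13
ApB,1,2,0.38
ApB,2,1,0.42
ApB,2,2,0.07
ApBp,1,1,0.09
ApBp,1,2,0.44
ApBp,2,1,0.38
ApBp,2,2,0.09
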