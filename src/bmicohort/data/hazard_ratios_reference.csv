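state,age_lo,age_hi,hr,hr_lo,hr_hi
NW,2,40,1.0,1.0,1.0
NW,40,60,1.0,1.0,1.0
NW,60,80,1.0,1.0,1.0
NW,80,101,1.0,1.0,1.0
OW,2,40,1.11,1.05,1.17
OW,40,60,1.11,1.05,1.17
OW,60,80,1.08,1.02,1.14
OW,80,101,1.04,0.98,1.1
OB1,2,40,1.5,1.38,1.62
OB1,40,60,1.45,1.33,1.57
OB1,60,80,1.35,1.23,1.47
OB1,80,101,1.2,1.08,1.32
OB2,2,40,2.1,1.85,2.35
OB2,40,60,1.95,1.7,2.2
OB2,60,80,1.7,1.45,1.95
OB2,80,101,1.4,1.15,1.65
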