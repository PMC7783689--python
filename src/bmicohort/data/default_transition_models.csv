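sex,transition,band,family,param1,param2
female,NW-OW,child,lognormal,3.16,1.22
male,NW-OW,child,lognormal,3.27,1.19
female,NW-OW,adolescent,weibull,-5.75,1.85
male,NW-OW,adolescent,weibull,-6.95,2.42
female,NW-OW,adult,exponential,0.03304,
male,NW-OW,adult,exponential,0.039365,
female,OW-OB1,child,lognormal,3.32,1.51
male,OW-OB1,child,lognormal,3.28,1.31
female,OW-OB1,adolescent,weibull,-5.22,1.77
male,OW-OB1,adolescent,weibull,-4.53,1.54
female,OW-OB1,adult,exponential,0.024088,
male,OW-OB1,adult,exponential,0.016434,
female,OB1-OB2,child,lognormal,3.35,1.62
male,OB1-OB2,child,lognormal,3.44,1.62
female,OB1-OB2,adolescent,gompertz,0.12,0.02
male,OB1-OB2,adolescent,gompertz,0.02,0.05
female,OB1-OB2,adult,gompertz,-0.02,0.05
male,OB1-OB2,adult,gompertz,0.01,0.02
female,OW-NW,child,lognormal,1.64,0.95
male,OW-NW,child,lognormal,1.44,0.91
female,OW-NW,adolescent,gompertz,-0.3,0.22
male,OW-NW,adolescent,gompertz,-0.36,0.22
female,OW-NW,adult,gompertz,0.04,0.00141
male,OW-NW,adult,gompertz,0.05,0.00086
female,OB1-OW,child,lognormal,1.28,0.92
male,OB1-OW,child,lognormal,1.26,0.89
female,OB1-OW,adolescent,gompertz,-0.43,0.31
male,OB1-OW,adolescent,gompertz,-0.32,0.16
female,OB1-OW,adult,gompertz,0.03,0.00227
male,OB1-OW,adult,gompertz,0.05,0.0016
female,OB2-OB1,child,lognormal,1.27,0.77
male,OB2-OB1,child,lognormal,1.37,0.84
female,OB2-OB1,adolescent,gompertz,-0.35,0.48
male,OB2-OB1,adolescent,gompertz,-0.16,0.16
female,OB2-OB1,adult,gompertz,0.02,0.00782
male,OB2-OB1,adult,gompertz,0.04,0.00414
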