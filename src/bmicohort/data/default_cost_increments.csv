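sex,state,ame_eur,se_eur
female,OW,160,85.1
female,OB1,631,180.3
female,OB2,698,199.4
male,OW,-96,94.6
male,OB1,182,126.4
male,OB2,1456,416.0
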