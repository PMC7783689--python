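sex,age,ow,ob1,ob2
female,2,18.09,19.81,21.13
female,3,18.522,20.447,21.997
female,4,18.954,21.084,22.864
female,5,19.386,21.721,23.731
female,6,19.817,22.357,24.598
female,7,20.249,22.994,25.464
female,8,20.681,23.631,26.331
female,9,21.113,24.268,27.198
female,10,21.545,24.905,28.065
female,11,21.977,25.542,28.932
female,12,22.409,26.179,29.799
female,13,22.841,26.816,30.666
female,14,23.273,27.453,31.532
female,15,23.704,28.089,32.399
female,16,24.136,28.726,33.266
female,17,24.568,29.363,34.133
male,2,18.41,20.09,21.9
male,3,18.822,20.709,22.719
male,4,19.234,21.329,23.537
male,5,19.646,21.948,24.356
male,6,20.058,22.567,25.175
male,7,20.469,23.187,25.994
male,8,20.881,23.806,26.812
male,9,21.293,24.426,27.631
male,10,21.705,25.045,28.45
male,11,22.117,25.664,29.269
male,12,22.529,26.284,30.087
male,13,22.941,26.903,30.906
male,14,23.352,27.523,31.725
male,15,23.764,28.142,32.544
male,16,24.176,28.761,33.362
male,17,24.588,29.381,34.181
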