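term,value
anchor,1.0
MO2,0.039
MO3,0.076
MO4,0.184
MO5,0.263
SC2,0.047
SC3,0.078
SC4,0.157
SC5,0.204
UA2,0.036
UA3,0.057
UA4,0.122
UA5,0.191
PD2,0.044
PD3,0.071
PD4,0.192
PD5,0.268
AD2,0.049
AD3,0.083
AD4,0.205
AD5,0.271
N45,0.028
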