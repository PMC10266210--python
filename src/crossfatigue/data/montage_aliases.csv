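name_a,name_b
T7,T3
T8,T4
P7,T5
P8,T6
M1,A1
M2,A2
CP1,CP3
CP2,CP4
P1,P3
P2,P4
PO3,T5
PO4,T6
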