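ecc_deg,value
0,0.030
2,0.034
4,0.040
6,0.047
8,0.055
10,0.064
12,0.074
15,0.088
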