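ecc_deg,value
0,1.80
0.5,1.70
1,1.50
1.5,1.25
2,0.95
2.5,0.65
3,0.38
3.5,0.15
4,0.0
15,0.0
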