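ecc_deg,value
0,0.268
2,0.269
4,0.271
6,0.274
8,0.277
10,0.281
12,0.286
15,0.292
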