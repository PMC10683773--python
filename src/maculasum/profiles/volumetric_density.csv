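ecc_deg,value
0,150000
0.5,250000
1,380000
1.5,470000
2,520000
3,560000
4,550000
5,520000
6,480000
7,440000
8,400000
9,370000
10,340000
12,300000
15,260000
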