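ecc_deg,value
0,4.0
1,4.2
2,4.8
3,5.6
4,6.6
5,7.8
6,9.2
7,10.8
8,12.6
9,14.6
10,16.8
12,21.5
15,30.0
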