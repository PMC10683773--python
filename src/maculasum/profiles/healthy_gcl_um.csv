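ecc_deg,value
0,12
0.5,18
1,26
1.5,34
2,42
2.5,48
3,51
3.5,52
4,51
5,47
6,42
7,37
8,32
9,28
10,25
12,21
15,17
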