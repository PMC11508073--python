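dose_gy,cells_scored,centric_rings,acentric_rings
0,112,0,0
0.1,100,0,0
0.25,135,0,0
0.5,154,2,0
0.75,282,5,0
1,220,6,3
2,188,11,6
3,119,12,4
4,137,19,9
5,60,13,8
7.5,37,14,5
10,28,12,10
15,25,22,17
20,49,37,23
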