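dose_gy,cells_scored,aberration_class,count,n_cells
0,112,dicentric_equivalents,0,112
0.1,100,dicentric_equivalents,0,98
0.1,100,dicentric_equivalents,1,2
0.25,135,dicentric_equivalents,0,128
0.25,135,dicentric_equivalents,1,7
0.5,154,dicentric_equivalents,0,136
0.5,154,dicentric_equivalents,1,17
0.5,154,dicentric_equivalents,2,1
0.75,282,dicentric_equivalents,0,234
0.75,282,dicentric_equivalents,1,43
0.75,282,dicentric_equivalents,2,5
1,220,dicentric_equivalents,0,154
1,220,dicentric_equivalents,1,51
1,220,dicentric_equivalents,2,12
1,220,dicentric_equivalents,3,3
2,188,dicentric_equivalents,0,94
2,188,dicentric_equivalents,1,64
2,188,dicentric_equivalents,2,23
2,188,dicentric_equivalents,3,5
2,188,dicentric_equivalents,4,2
3,119,dicentric_equivalents,0,30
3,119,dicentric_equivalents,1,41
3,119,dicentric_equivalents,2,30
3,119,dicentric_equivalents,3,13
3,119,dicentric_equivalents,4,4
3,119,dicentric_equivalents,5,1
4,137,dicentric_equivalents,0,16
4,137,dicentric_equivalents,1,35
4,137,dicentric_equivalents,2,39
4,137,dicentric_equivalents,3,26
4,137,dicentric_equivalents,4,7
4,137,dicentric_equivalents,5,8
4,137,dicentric_equivalents,6,3
4,137,dicentric_equivalents,7,3
5,60,dicentric_equivalents,1,8
5,60,dicentric_equivalents,2,16
5,60,dicentric_equivalents,3,15
5,60,dicentric_equivalents,4,11
5,60,dicentric_equivalents,5,8
5,60,dicentric_equivalents,6,2
7.5,37,dicentric_equivalents,1,1
7.5,37,dicentric_equivalents,3,3
7.5,37,dicentric_equivalents,4,5
7.5,37,dicentric_equivalents,5,8
7.5,37,dicentric_equivalents,6,9
7.5,37,dicentric_equivalents,7,6
7.5,37,dicentric_equivalents,8,1
7.5,37,dicentric_equivalents,9,4
10,28,dicentric_equivalents,4,1
10,28,dicentric_equivalents,5,2
10,28,dicentric_equivalents,6,6
10,28,dicentric_equivalents,7,5
10,28,dicentric_equivalents,8,7
10,28,dicentric_equivalents,9,6
10,28,dicentric_equivalents,10,1
15,25,dicentric_equivalents,5,1
15,25,dicentric_equivalents,6,1
15,25,dicentric_equivalents,7,2
15,25,dicentric_equivalents,8,4
15,25,dicentric_equivalents,9,5
15,25,dicentric_equivalents,10,4
15,25,dicentric_equivalents,11,2
15,25,dicentric_equivalents,12,3
15,25,dicentric_equivalents,13,2
15,25,dicentric_equivalents,15,1
20,49,dicentric_equivalents,7,1
20,49,dicentric_equivalents,8,3
20,49,dicentric_equivalents,9,3
20,49,dicentric_equivalents,10,1
20,49,dicentric_equivalents,11,5
20,49,dicentric_equivalents,12,5
20,49,dicentric_equivalents,13,4
20,49,dicentric_equivalents,14,4
20,49,dicentric_equivalents,15,4
20,49,dicentric_equivalents,16,7
20,49,dicentric_equivalents,17,6
20,49,dicentric_equivalents,18,5
20,49,dicentric_equivalents,19,1
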