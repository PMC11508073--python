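preparation,donor,dose_gy,cells_scored,dicentric_equivalents,centric_rings,acentric_rings,compound_fragments,terminal_fragments,interstitial_fragments,printed_total
METAPHASE,donor1,0,250,0,0,0,2,1,0,3
METAPHASE,donor1,0.5,250,20,0,0,24,10,2,56
METAPHASE,donor1,1,250,58,1,0,63,26,10,158
METAPHASE,donor1,3,200,276,6,1,257,89,39,668
METAPHASE,donor1,5,100,255,9,4,237,113,65,683
METAPHASE,donor1,7.5,100,491,19,5,446,216,127,1304
METAPHASE,donor2,0,221,0,0,0,2,1,1,4
METAPHASE,donor2,0.5,164,10,0,0,14,7,3,34
METAPHASE,donor2,1,189,33,3,0,39,13,7,95
METAPHASE,donor2,3,153,167,3,2,176,75,39,462
METAPHASE,donor2,5,44,102,4,1,92,38,20,257
METAPHASE,donor2,7.5,11,50,3,0,31,18,25,127
G2_PCC,donor1,0,250,0,0,0,10,7,0,17
G2_PCC,donor1,0.5,250,22,0,0,29,29,8,88
G2_PCC,donor1,1,250,56,3,1,86,61,18,225
G2_PCC,donor1,3,200,281,11,10,291,181,91,865
G2_PCC,donor1,5,100,321,14,6,288,163,92,884
G2_PCC,donor1,7.5,100,576,18,8,530,310,181,1623
G2_PCC,donor2,0,250,0,0,0,4,4,6,14
G2_PCC,donor2,0.5,250,22,1,1,47,28,2,101
G2_PCC,donor2,1,250,61,7,3,74,34,9,188
G2_PCC,donor2,3,200,247,14,9,279,144,47,740
G2_PCC,donor2,5,100,268,17,15,260,163,77,794
G2_PCC,donor2,7.5,100,500,35,18,535,254,123,1465
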