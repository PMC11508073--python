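condition,preparation,culture_hours,dose_gy,cells_scored,dicentric_equivalents
cal_a_36,G2_PCC,36,0,102,0
cal_a_36,G2_PCC,36,1,50,10
cal_a_36,G2_PCC,36,2,50,22
cal_a_36,G2_PCC,36,4,20,31
cal_a_48,G2_PCC,48,0,50,1
cal_a_48,G2_PCC,48,1,50,9
cal_a_48,G2_PCC,48,2,50,30
cal_a_48,G2_PCC,48,4,17,31
colcemid_48,METAPHASE,48,0,500,0
colcemid_48,METAPHASE,48,1,100,20
colcemid_48,METAPHASE,48,2,100,42
colcemid_48,METAPHASE,48,4,100,185
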