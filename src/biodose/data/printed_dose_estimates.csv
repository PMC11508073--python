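delivered_dose_label,exposure_dose_gy,condition,estimate_gy,lcl_gy,ucl_gy
0,0,cal_a_36,0,0,0
0,0,cal_a_48,0.11,0,0.11
0,0,colcemid_48,0,0,0
1,1,cal_a_36,1.02,0.6,1.53
1,1,cal_a_48,0.95,0.53,1.46
1,1,colcemid_48,1.02,0.72,1.37
2,2,cal_a_36,1.71,1.27,2.2
2,2,cal_a_48,2.07,1.62,2.55
2,2,colcemid_48,1.66,1.35,2
3,4,cal_a_36,3.58,2.87,4.35
3,4,cal_a_48,3.92,3.15,4.76
3,4,colcemid_48,3.95,3.64,4.28
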