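rank,g2_pct,g3_pct,g4_pct,other_pct,p_cycle_w,pct_pole,pct_ski,pct_pole_left,pct_pole_right,cl_aos_m,cr_aos_cpm
1,0,55,23,22,283.3,60.9,39.1,48.3,51.6,10.9,32.2
2,4,53,24,19,292.5,52.1,47.9,43.9,56.1,11.5,30.6
3,12,42,24,22,,,,,,10.8,32.4
4,4,53,23,20,270.5,60.5,39.5,46.6,53.4,10.6,33.0
5,0,57,24,20,305.2,58.6,41.4,43.3,56.6,12.0,29.3
6,8,47,25,19,261.0,58.1,41.9,51.5,48.5,11.0,31.8
7,4,51,24,20,332.9,69.7,30.3,51.1,48.9,10.6,33.1
8,1,56,24,18,288.1,60.4,39.6,48.1,51.9,10.1,34.7
9,0,32,48,20,281.7,60.1,39.9,52.4,47.1,11.2,31.6
10,23,34,25,17,267.0,47.8,52.2,50.5,49.4,10.7,32.8
11,12,45,23,20,,,,,,10.0,35.2
12,21,36,23,21,286.3,59.8,40.2,44.8,55.2,10.9,32.3
13,22,33,26,19,300.2,50.7,49.3,46.6,53.4,10.1,35.0
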