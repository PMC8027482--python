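rank,breaks,tte_s,pct_hrmax_ip,pct_vo2max_ip,vo2_ip,tsi_arm_ip,tsi_leg_ip,rpe_ip,bla_aos,peak_hr_ip,peak_hr_aos,peak_vo2_ip,peak_vo2_aos,vo2max,ge_g2,ge_g3,ge_g4,ge_oa
1,0,130,83.5,74.2,54.7,59.4,61.3,16,10.5,182,193,70.5,74.3,73.8,17.7,15.9,12.7,15.4
2,0,119,85.1,73.2,53.4,43.8,51.9,17,7.2,184,190,71.7,73.4,73.0,17.4,15.1,12.6,15.0
3,0,101,87.3,78.2,53.2,45.2,55.3,16,14.3,171,177,69.4,71.0,68.1,17.0,14.9,12.0,14.7
4,0,91,90.2,74.9,55.0,45.0,58.1,18,12.0,199,202,73.1,71.7,73.4,17.3,15.4,13.0,15.2
5,0,82,88.0,73.2,53.0,58.5,64.6,15,8.7,187,189,67.6,67.7,72.5,16.9,14.8,12.9,14.9
6,0,74,88.8,76.7,56.8,36.0,51.4,17,12.9,203,202,72.7,71.4,74.0,16.4,14.5,12.1,14.4
7,0,65,88.5,79.3,51.3,47.8,57.3,20,10.2,191,189,66.1,61.8,64.8,17.4,14.9,12.8,15.0
8,0,60,90.6,78.0,53.4,50.1,63.3,19,12.0,193,194,66.1,65.0,68.5,17.3,15.0,12.9,15.1
9,0,47,89.0,79.4,53.2,65.3,69.7,17,11.8,193,189,68.6,62.9,67.0,17.1,15.1,12.7,15.0
10,1,50,93.7,81.6,58.8,54.4,65.2,20,16.7,202,200,72.6,69.1,72.0,15.8,14.0,11.7,13.8
11,2,62,92.6,83.8,54.7,42.4,46.5,19,18.7,195,196,69.3,63.3,65.3,16.7,14.6,12.1,14.3
12,2,47,91.5,86.6,55.2,63.8,55.6,19,15.1,201,196,67.3,61.1,63.8,16.5,14.5,12.0,14.4
13,3,66,91.1,82.9,56.2,51.0,54.1,20,12.0,189,190,70.9,70.6,67.8,16.2,14.0,12.1,14.1
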