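variable,mean,sd
age_years,24.8,2.7
height_cm,184,6.0
mass_kg,79.3,5.2
bmi_kg_m2,23.4,1.0
vo2max_ml_min_kg,69.5,3.6
vo2max_ml_min,5505,364
hrmax_bpm,193.5,7.0
skinfold_arm_mm,6.6,1.8
skinfold_leg_mm,7.3,1.3
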